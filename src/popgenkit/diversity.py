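"""Heterozygosities, F_IS permutation tests, Weir-Cockerham F_ST and nested AMOVA.

All statistics operate on alt-allele dosages with missing calls excluded
pairwise per locus.  Multi-locus estimators combine loci as a ratio of
summed variance components (the Weir-Cockerham convention), never as a
mean of per-locus ratios.

The nested AMOVA decomposes allele-level variance over four strata --
within individuals, among individuals within populations, among
populations within clusters, among clusters -- using moment estimators
with the standard unbalanced-design coefficients.  Because every
individual contributes exactly two alleles, the among-individual
coefficient is exactly 2 at every level; the population- and
cluster-level coefficients are data dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, Hierarchy, ValidationError, VariantTable

__all__ = [
    "DiversitySummary",
    "FisTestResult",
    "FstMatrix",
    "AmovaResult",
    "heterozygosities",
    "fis_test",
    "pairwise_fst",
    "global_fst",
    "weir_cockerham_components",
    "nested_amova",
    "NestedAmova",
]


# ----------------------------------------------------------------------
# Shared per-group tallies
# ----------------------------------------------------------------------

def _group_columns(
    table: VariantTable, grouping: Mapping[str, Sequence[str]]
) -> dict[str, np.ndarray]:
    index = {s: i for i, s in enumerate(table.sample_ids)}
    out = {}
    for gid, members in grouping.items():
        unknown = [s for s in members if s not in index]
        if unknown:
            raise ValidationError(f"group {gid!r} has unknown samples: {unknown[:5]}")
        out[gid] = np.array([index[s] for s in members], dtype=int)
    return out


def _tallies(table: VariantTable, cols: np.ndarray):
    """Per-locus (n genotyped, alt count, het count) for one sample set."""
    g = table.genotypes[:, cols]
    ok = g != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, g, 0).sum(axis=1)
    het = (g == 1).sum(axis=1)
    return n, alt, het


def _expected_het(n: np.ndarray, alt: np.ndarray, corrected: bool = True) -> np.ndarray:
    """Per-locus expected heterozygosity 1 - p^2 - q^2, optionally with the
    small-sample factor 2n/(2n-1)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        he = 2.0 * p * (1.0 - p)
        if corrected:
            he = he * np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1), np.nan)
    return he


# ----------------------------------------------------------------------
# Heterozygosities
# ----------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Observed and expected heterozygosity per group and pooled overall."""

    per_group: pd.DataFrame  # index group, columns n, h_obs, h_exp
    overall_h_obs: float
    overall_h_exp: float
    n_loci: int
    corrected: bool

    def summary(self) -> str:
        lines = ["Genetic diversity (mean over loci)", "=" * 40]
        lines.append(f"{'group':<16}{'n':>5}{'H_O':>9}{'H_E':>9}")
        for gid, row in self.per_group.iterrows():
            lines.append(
                f"{gid:<16}{int(row['n']):>5}{row['h_obs']:>9.3f}{row['h_exp']:>9.3f}"
            )
        lines.append(
            f"{'overall':<16}{int(self.per_group['n'].sum()):>5}"
            f"{self.overall_h_obs:>9.3f}{self.overall_h_exp:>9.3f}"
        )
        return "\n".join(lines)


def heterozygosities(
    table: VariantTable,
    grouping: Mapping[str, Sequence[str]],
    corrected: bool = True,
) -> DiversitySummary:
    """Observed (H_O) and expected (H_E) heterozygosity per group.

    H_O is the fraction of heterozygotes among genotyped individuals; H_E is
    ``2pq`` with, by default, the sample-size factor ``2n/(2n-1)``.  Group
    values average per-locus values over loci with data; the overall row
    pools all samples before averaging.
    """
    cols = _group_columns(table, grouping)
    rows = []
    for gid, c in cols.items():
        n, alt, het = _tallies(table, c)
        with np.errstate(invalid="ignore"):
            ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        he = _expected_het(n, alt, corrected)
        rows.append((gid, len(c), np.nanmean(ho), np.nanmean(he)))
    per_group = pd.DataFrame(
        rows, columns=["group", "n", "h_obs", "h_exp"]
    ).set_index("group")

    all_cols = np.concatenate(list(cols.values()))
    n, alt, het = _tallies(table, all_cols)
    with np.errstate(invalid="ignore"):
        ho_all = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    he_all = _expected_het(n, alt, corrected)
    return DiversitySummary(
        per_group=per_group,
        overall_h_obs=float(np.nanmean(ho_all)),
        overall_h_exp=float(np.nanmean(he_all)),
        n_loci=table.n_loci,
        corrected=corrected,
    )


# ----------------------------------------------------------------------
# F_IS with within-group allele permutation
# ----------------------------------------------------------------------

@dataclass
class FisTestResult:
    """Per-locus F_IS with two one-sided permutation p-values.

    ``p_negative`` tests heterozygote excess (the paralog signature),
    ``p_positive`` heterozygote deficit.  ``negative_flag`` marks loci whose
    excess-heterozygosity p-value falls at or below ``alpha``.
    """

    fis: pd.Series
    p_negative: pd.Series
    p_positive: pd.Series
    negative_flag: pd.Series
    alpha: float
    n_perm: int

    def flagged_ids(self) -> list[str]:
        return self.negative_flag.index[self.negative_flag].tolist()


def _permuted_het_counts(
    rng: np.random.Generator, n: np.ndarray, alt: np.ndarray, size: tuple
) -> np.ndarray:
    """Heterozygote counts after re-pairing alleles at random within a group.

    Shuffling the ``2n`` alleles of a group and re-pairing them into
    individuals is equivalent to dropping the ``A`` alt alleles uniformly
    into ``2n`` slots; the resulting heterozygote count needs only two
    hypergeometric draws (alt alleles landing in first-member slots, then
    the overlap producing alt homozygotes), which vectorizes over loci and
    permutation replicates.
    """
    n_b = np.broadcast_to(n, size)
    alt_b = np.broadcast_to(alt, size)
    x = rng.hypergeometric(n_b, n_b, alt_b)  # alt alleles in first slots
    both = rng.hypergeometric(x, n_b - x, alt_b - x)  # alt-homozygote pairs
    return x + (alt_b - x) - 2 * both


def fis_test(
    table: VariantTable,
    grouping: Mapping[str, Sequence[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    batch: int = 500,
) -> FisTestResult:
    """Per-locus F_IS = 1 - H_O/H_E with a within-group allele-permutation null.

    Group-level observed and expected heterozygosities are pooled across
    groups weighted by genotyped sample size before forming the ratio.  The
    null redistributes alleles among individuals within each group, which
    leaves H_E fixed, so the permutation comparison reduces to the total
    heterozygote count.  P-values use (b + 1)/(m + 1) smoothing.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    cols = _group_columns(table, grouping)
    L = table.n_loci
    G = len(cols)
    n = np.zeros((L, G), dtype=np.int64)
    alt = np.zeros((L, G), dtype=np.int64)
    het = np.zeros((L, G), dtype=np.int64)
    for gi, c in enumerate(cols.values()):
        n[:, gi], alt[:, gi], het[:, gi] = _tallies(table, c)

    he = _expected_het(n.T, alt.T).T  # (L, G), NaN where n == 0
    w_he = np.nansum(n * np.nan_to_num(he), axis=1)  # sum_g n_g * H_E_g
    sum_het = het.sum(axis=1)  # sum_g n_g * H_O_g  (= heterozygote count)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(w_he > 0, 1.0 - sum_het / w_he, np.nan)

    # permutation: resample het counts within each group, compare total
    ge = np.zeros(L, dtype=np.int64)  # perms with F_IS <= observed
    le = np.zeros(L, dtype=np.int64)  # perms with F_IS >= observed
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_het = _permuted_het_counts(rng, n, alt, (b, L, G)).sum(axis=2)
        ge += (perm_het >= sum_het).sum(axis=0)  # more het => F_IS lower
        le += (perm_het <= sum_het).sum(axis=0)
        done += b
    p_neg = (ge + 1) / (n_perm + 1)
    p_pos = (le + 1) / (n_perm + 1)

    idx = pd.Index(table.locus_ids, name="locus")
    defined = w_he > 0
    flag = defined & (p_neg <= alpha) & (fis < 0)
    return FisTestResult(
        fis=pd.Series(fis, index=idx, name="fis"),
        p_negative=pd.Series(np.where(defined, p_neg, np.nan), index=idx),
        p_positive=pd.Series(np.where(defined, p_pos, np.nan), index=idx),
        negative_flag=pd.Series(flag, index=idx),
        alpha=alpha,
        n_perm=n_perm,
    )


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def weir_cockerham_components(
    n: np.ndarray, alt: np.ndarray, het: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    Inputs are (loci x populations) arrays of genotyped sample size, alt
    allele count and heterozygote count.  Populations with no data at a
    locus are excluded from that locus; loci with fewer than two informative
    populations, or mean sample size <= 1, return NaN components.
    """
    n = np.asarray(n, dtype=float)
    ok = n > 0
    r = ok.sum(axis=1).astype(float)
    n_safe = np.where(ok, n, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, alt / np.maximum(2 * n_safe, 1), 0.0)
        h = np.where(ok, het / np.maximum(n_safe, 1), 0.0)

        n_tot = n_safe.sum(axis=1)
        nbar = n_tot / r
        nc = (n_tot - (n_safe**2).sum(axis=1) / n_tot) / (r - 1)
        pbar = (n_safe * p).sum(axis=1) / n_tot
        s2 = (n_safe * (p - pbar[:, None]) ** 2 * ok).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_safe * h).sum(axis=1) / n_tot

        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _theta_from_tallies(n, alt, het) -> float:
    a, b, c = weir_cockerham_components(n, alt, het)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else float("nan")


@dataclass
class FstMatrix:
    """Symmetric matrix of multi-locus Weir-Cockerham theta between groups."""

    theta: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.theta.to_numpy(dtype=float)
        if not np.allclose(np.diag(m), 0, equal_nan=True):
            raise ValidationError("F_ST matrix diagonal must be zero")

    def summary(self) -> str:
        return "Pairwise Weir-Cockerham F_ST\n" + self.theta.round(3).to_string()


def pairwise_fst(
    table: VariantTable, grouping: Mapping[str, Sequence[str]]
) -> FstMatrix:
    """Multi-locus Weir-Cockerham theta for every pair of groups.

    Loci are combined as sum(a)/sum(a+b+c); a pair with no jointly typed
    locus gets a NaN entry.
    """
    cols = _group_columns(table, grouping)
    if len(cols) < 2:
        raise ValidationError("pairwise_fst needs >= 2 groups")
    gids = list(cols)
    tall = {gid: _tallies(table, c) for gid, c in cols.items()}
    m = np.zeros((len(gids), len(gids)))
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            n = np.column_stack([tall[gids[i]][0], tall[gids[j]][0]])
            alt = np.column_stack([tall[gids[i]][1], tall[gids[j]][1]])
            het = np.column_stack([tall[gids[i]][2], tall[gids[j]][2]])
            m[i, j] = m[j, i] = _theta_from_tallies(n, alt, het)
    return FstMatrix(pd.DataFrame(m, index=gids, columns=gids))


def global_fst(table: VariantTable, grouping: Mapping[str, Sequence[str]]) -> float:
    """Multi-locus Weir-Cockerham theta over all groups jointly."""
    cols = _group_columns(table, grouping)
    if len(cols) < 2:
        raise ValidationError("global_fst needs >= 2 groups")
    n = np.column_stack([_tallies(table, c)[0] for c in cols.values()])
    alt = np.column_stack([_tallies(table, c)[1] for c in cols.values()])
    het = np.column_stack([_tallies(table, c)[2] for c in cols.values()])
    return _theta_from_tallies(n, alt, het)


# ----------------------------------------------------------------------
# Nested AMOVA
# ----------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Four-stratum variance decomposition with fixation indices.

    ``components`` holds the summed-over-loci variance components for the
    within-individual, among-individual, among-population and among-cluster
    strata; ``percent`` expresses each as a share of their total.  P-values
    come from stratified permutation schemes (alleles among individuals
    within populations for F_IS; individuals among populations within
    clusters for F_SC; whole populations among clusters for F_CT).
    """

    components: pd.Series  # index: within_individual, among_individual, ...
    percent: pd.Series
    f_stats: pd.Series  # F_IS, F_SC, F_CT, F_IT
    p_values: pd.Series  # may hold NaN when permutations were not run
    n_perm: int

    def summary(self) -> str:
        rows = [
            ("Within individual", "within_individual", "F_IT"),
            ("Among individual", "among_individual", "F_IS"),
            ("Among population", "among_population", "F_SC"),
            ("Among cluster", "among_cluster", "F_CT"),
        ]
        lines = ["Nested AMOVA", "=" * 58]
        lines.append(f"{'Source':<20}{'%var':>8}{'F-stat':>8}{'F':>8}{'P':>10}")
        for label, comp, fname in rows:
            p = self.p_values.get(fname, np.nan)
            p_str = f"{p:.4f}" if np.isfinite(p) else "-"
            lines.append(
                f"{label:<20}{self.percent[comp]:>8.1f}{fname:>8}"
                f"{self.f_stats[fname]:>8.2f}{p_str:>10}"
            )
        return "\n".join(lines)


_STRATA = ["within_individual", "among_individual", "among_population", "among_cluster"]


def _amova_components(
    geno: np.ndarray, pop_of: np.ndarray, cluster_of_pop: np.ndarray, n_pops: int, n_clusters: int
) -> np.ndarray:
    """Summed-over-loci variance components (sigma_WI, sigma_AI, sigma_AP, sigma_AG).

    ``geno`` is (loci x samples) dosage with -1 missing, ``pop_of`` maps each
    sample column to a population index, ``cluster_of_pop`` each population
    to a cluster index.
    """
    L, N = geno.shape
    ok = geno != MISSING
    dos = np.where(ok, geno, 0).astype(float)
    het = (geno == 1)

    pop_mat = np.zeros((N, n_pops))
    pop_mat[np.arange(N), pop_of] = 1.0
    clu_mat = np.zeros((n_pops, n_clusters))
    clu_mat[np.arange(n_pops), cluster_of_pop] = 1.0

    n_pop = ok @ pop_mat  # (L, P) genotyped individuals
    s_pop = dos @ pop_mat  # (L, P) summed dosage
    n_clu = n_pop @ clu_mat
    s_clu = s_pop @ clu_mat
    n_tot = n_pop.sum(axis=1)
    s_tot = s_pop.sum(axis=1)

    m_pop = 2.0 * n_pop  # allele counts
    m_clu = 2.0 * n_clu
    m_tot = 2.0 * n_tot

    with np.errstate(divide="ignore", invalid="ignore"):
        # sum over alleles at each level of (level mean)^2 = s^2 / allele count
        ss_pop_level = np.where(m_pop > 0, s_pop**2 / m_pop, 0.0)
        ss_clu_level = np.where(m_clu > 0, s_clu**2 / m_clu, 0.0)
        ss_tot_level = np.where(m_tot > 0, s_tot**2 / m_tot, 0.0)

    sum_sq_ind = (np.where(ok, dos**2, 0.0) / 2.0).sum(axis=1)  # sum 2*ybar_ind^2

    ss_wi = 0.5 * het.sum(axis=1).astype(float)
    ss_ai = sum_sq_ind - ss_pop_level.sum(axis=1)
    ss_ap = ss_pop_level.sum(axis=1) - ss_clu_level.sum(axis=1)
    ss_ag = ss_clu_level.sum(axis=1) - ss_tot_level

    pops_present = n_pop > 0
    clus_present = n_clu > 0
    P_l = pops_present.sum(axis=1).astype(float)
    G_l = clus_present.sum(axis=1).astype(float)
    N_l = n_tot.astype(float)

    df_wi = N_l
    df_ai = N_l - P_l
    df_ap = P_l - G_l
    df_ag = G_l - 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ms_wi = np.where(df_wi > 0, ss_wi / df_wi, np.nan)
        ms_ai = np.where(df_ai > 0, ss_ai / df_ai, np.nan)
        ms_ap = np.where(df_ap > 0, ss_ap / df_ap, np.nan)
        ms_ag = np.where(df_ag > 0, ss_ag / df_ag, np.nan)

        # unbalanced-design coefficients on allele counts
        sum_m2_over_mc = np.where(
            m_clu > 0, (m_pop**2 @ clu_mat) / np.where(m_clu > 0, m_clu, 1), 0.0
        ).sum(axis=1)
        sum_m2_over_m = (m_pop**2).sum(axis=1) / m_tot
        sum_mc2_over_m = (m_clu**2).sum(axis=1) / m_tot

        n1 = np.where(df_ap > 0, (m_tot - sum_m2_over_mc) / np.maximum(df_ap, 1), np.nan)
        n2 = np.where(df_ag > 0, (sum_m2_over_mc - sum_m2_over_m) / np.maximum(df_ag, 1), np.nan)
        n3 = np.where(df_ag > 0, (m_tot - sum_mc2_over_m) / np.maximum(df_ag, 1), np.nan)

        sig_wi = ms_wi
        sig_ai = (ms_ai - sig_wi) / 2.0
        sig_ap = np.where(df_ap > 0, (ms_ap - sig_wi - 2.0 * sig_ai) / n1, 0.0)
        sig_ag = np.where(
            df_ag > 0,
            (ms_ag - sig_wi - 2.0 * sig_ai - n2 * sig_ap) / n3,
            0.0,
        )

    comps = np.vstack([sig_wi, sig_ai, sig_ap, sig_ag])
    return np.nansum(comps, axis=1)


def _f_from_components(c: np.ndarray) -> dict[str, float]:
    sig_wi, sig_ai, sig_ap, sig_ag = c
    tot = c.sum()
    return {
        "F_IS": sig_ai / (sig_ai + sig_wi) if (sig_ai + sig_wi) != 0 else np.nan,
        "F_SC": sig_ap / (tot - sig_ag) if (tot - sig_ag) != 0 else np.nan,
        "F_CT": sig_ag / tot if tot != 0 else np.nan,
        "F_IT": 1.0 - sig_wi / tot if tot != 0 else np.nan,
    }


class NestedAmova:
    """Nested analysis of molecular variance on allele dosages.

    Individuals are treated as pairs of alleles, nested within populations
    (sampling sites), themselves nested within genetic clusters.  ``fit``
    returns an :class:`AmovaResult`; with ``n_perm > 0`` the three fixation
    indices get stratified permutation p-values.
    """

    def __init__(self, table: VariantTable, hierarchy: Hierarchy):
        self.table = table
        self.hierarchy = hierarchy
        index = {s: i for i, s in enumerate(table.sample_ids)}
        pops = list(hierarchy.site_samples)
        clusters = list(hierarchy.cluster_sites)
        cluster_of_pop = np.empty(len(pops), dtype=int)
        pop_of = np.empty(table.n_samples, dtype=int)
        pop_of.fill(-1)
        for ci, cl in enumerate(clusters):
            for site in hierarchy.cluster_sites[cl]:
                cluster_of_pop[pops.index(site)] = ci
        for pi, site in enumerate(pops):
            for s in hierarchy.site_samples[site]:
                if s not in index:
                    raise ValidationError(f"hierarchy sample {s!r} not in table")
                pop_of[index[s]] = pi
        if (pop_of < 0).any():
            keep = pop_of >= 0
            self._cols = np.flatnonzero(keep)
        else:
            self._cols = np.arange(table.n_samples)
        self.pop_of = pop_of[self._cols]
        self.cluster_of_pop = cluster_of_pop
        self.n_pops = len(pops)
        self.n_clusters = len(clusters)
        if self.n_clusters < 2 or self.n_pops < self.n_clusters + 1:
            # degenerate strata are allowed but flagged by zero components
            pass

    def fit(self, n_perm: int = 0, seed: int = 0) -> AmovaResult:
        geno = self.table.genotypes[:, self._cols]
        comps = _amova_components(
            geno, self.pop_of, self.cluster_of_pop, self.n_pops, self.n_clusters
        )
        f_obs = _f_from_components(comps)
        total = comps.sum()
        percent = 100.0 * comps / total if total != 0 else np.full(4, np.nan)

        p = {k: np.nan for k in ("F_IS", "F_SC", "F_CT")}
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            p["F_CT"] = self._perm_ct(geno, n_perm, rng, f_obs["F_CT"])
            p["F_SC"] = self._perm_sc(geno, n_perm, rng, f_obs["F_SC"])
            p["F_IS"] = self._perm_is(geno, n_perm, rng, f_obs["F_IS"])
        p["F_IT"] = np.nan

        return AmovaResult(
            components=pd.Series(comps, index=_STRATA),
            percent=pd.Series(percent, index=_STRATA),
            f_stats=pd.Series(f_obs),
            p_values=pd.Series(p),
            n_perm=n_perm,
        )

    # -- permutation schemes -------------------------------------------
    def _perm_ct(self, geno, n_perm, rng, obs) -> float:
        """Whole populations shuffled among clusters."""
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(self.cluster_of_pop)
            comps = _amova_components(geno, self.pop_of, perm, self.n_pops, self.n_clusters)
            if _f_from_components(comps)["F_CT"] >= obs - 1e-12:
                hits += 1
        return (hits + 1) / (n_perm + 1)

    def _perm_sc(self, geno, n_perm, rng, obs) -> float:
        """Individuals shuffled among populations within their cluster."""
        cluster_of_ind = self.cluster_of_pop[self.pop_of]
        hits = 0
        for _ in range(n_perm):
            pop_perm = self.pop_of.copy()
            for ci in range(self.n_clusters):
                idx = np.flatnonzero(cluster_of_ind == ci)
                pop_perm[idx] = pop_perm[rng.permutation(idx)]
            comps = _amova_components(
                geno, pop_perm, self.cluster_of_pop, self.n_pops, self.n_clusters
            )
            if _f_from_components(comps)["F_SC"] >= obs - 1e-12:
                hits += 1
        return (hits + 1) / (n_perm + 1)

    def _perm_is(self, geno, n_perm, rng, obs) -> float:
        """Alleles re-paired among individuals within populations.

        Re-pairing alleles leaves population allele counts fixed, so the
        permuted components depend on the data only through the per-locus,
        per-population heterozygote counts, resampled with the same
        two-hypergeometric construction as :func:`fis_test`.
        """
        ok = geno != MISSING
        dos = np.where(ok, geno, 0)
        pop_mat = np.zeros((geno.shape[1], self.n_pops))
        pop_mat[np.arange(geno.shape[1]), self.pop_of] = 1.0
        n_pop = (ok @ pop_mat).astype(np.int64)  # (L, P)
        alt_pop = (dos @ pop_mat).astype(np.int64)

        # F_IS depends only on sigma_WI and sigma_AI, i.e. on SS_WI and
        # SS_AI; both are linear in the per-population het counts given the
        # fixed allele counts: SS_WI = h/2, sum(dos^2)/2 = (2A - h)/2.
        P_l = (n_pop > 0).sum(axis=1).astype(float)
        N_l = n_pop.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ss_pop_level = np.where(
                n_pop > 0, alt_pop**2 / np.maximum(2.0 * n_pop, 1), 0.0
            ).sum(axis=1)

        def fis_of(het_tot: np.ndarray) -> float:
            ss_wi = 0.5 * het_tot
            sum_sq_ind = (2.0 * alt_pop.sum(axis=1) - het_tot) / 2.0
            ss_ai = sum_sq_ind - ss_pop_level
            with np.errstate(divide="ignore", invalid="ignore"):
                ms_wi = np.where(N_l > 0, ss_wi / N_l, np.nan)
                ms_ai = np.where(N_l - P_l > 0, ss_ai / (N_l - P_l), np.nan)
            sig_wi = np.nansum(ms_wi)
            sig_ai = np.nansum((ms_ai - ms_wi) / 2.0)
            den = sig_ai + sig_wi
            return sig_ai / den if den != 0 else np.nan

        het_obs = ((geno == 1) @ pop_mat).sum(axis=1)
        obs_val = fis_of(het_obs)
        hits = 0
        for _ in range(n_perm):
            het_perm = _permuted_het_counts(rng, n_pop, alt_pop, n_pop.shape).sum(axis=1)
            if fis_of(het_perm.astype(float)) >= obs_val - 1e-12:
                hits += 1
        return (hits + 1) / (n_perm + 1)


def nested_amova(
    table: VariantTable, hierarchy: Hierarchy, n_perm: int = 0, seed: int = 0
) -> AmovaResult:
    """Functional wrapper over :class:`NestedAmova`."""
    return NestedAmova(table, hierarchy).fit(n_perm=n_perm, seed=seed)
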