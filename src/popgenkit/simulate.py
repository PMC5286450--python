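"""Hierarchical diploid genotype simulator with known F-statistics.

The generative model is a Balding-Nichols Beta hierarchy: an ancestral
allele frequency ``p`` per locus, cluster frequencies drawn from
``Beta(p(1-Fct)/Fct, (1-p)(1-Fct)/Fct)``, site frequencies drawn around
their cluster frequency with dispersion ``Fsc``, and diploid genotypes
drawn with heterozygote deficit ``Fis`` (``P(het) = 2pq(1-Fis)``).  This
yields closed-form fixation-index expectations, so parameter-recovery
tests are exact in expectation without an external simulator.

Beyond neutral loci the generator spikes three artifact classes that the
curation cascade must catch: high-differentiation outlier loci (elevated
cluster-level dispersion), paralog-like loci (forced excess heterozygosity,
the signature of collapsed duplicated regions), and exact linked copies of
neutral template loci on the same contig.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, SampleFrame, VariantTable

#: per-site individual counts for the three-cluster, 17-site, 89-sample
#: study design (clusters of 10, 51 and 28 individuals).
STUDY_SITE_SIZES: tuple[tuple[int, ...], ...] = (
    (5, 5),  # island cluster
    (5, 5, 5, 5, 5, 5, 5, 6, 5, 5),  # ranges cluster
    (5, 5, 8, 5, 5),  # eastern cluster
)

LOCUS_CLASSES = ("neutral", "outlier", "paralog", "ld_copy")


@dataclass
class SimParams:
    """Parameters of the hierarchical genotype simulator.

    ``site_sizes`` gives, per cluster, the number of diploid individuals at
    each site; the default replicates the 3-cluster / 17-site / 89-sample
    sampling design.  F-targets are fractions in [0, 1).  Depth is negative
    binomial with the given mean and dispersion (shape) so that a depth-10
    mask removes a realistic few percent of calls.
    """

    site_sizes: tuple[tuple[int, ...], ...] = STUDY_SITE_SIZES
    n_loci: int = 2000
    f_ct: float = 0.17
    f_sc: float = 0.05
    f_is: float = 0.12
    anc_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.03
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    n_outlier_loci: int = 0
    outlier_f_ct: float = 0.5
    n_paralog_loci: int = 0
    paralog_het_rate: float = 0.9
    n_ld_copies: int = 0
    snps_per_contig: int = 5
    contig_length: int = 2000
    spatial_clustering: bool = True
    coord_origin: tuple[float, float] = (138.0, -36.0)  # lon, lat (deg)
    coord_span: tuple[float, float] = (2.5, 8.0)  # lon, lat extent (deg)
    site_jitter: float = 0.4  # deg, scatter of sites around cluster centres
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_ct", "f_sc", "f_is"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if any(n <= 0 for sizes in self.site_sizes for n in sizes):
            raise ValueError("site sizes must be positive")
        if self.n_ld_copies and self.snps_per_contig < 2:
            raise ValueError("LD copies require >= 2 SNPs per contig")

    @property
    def n_clusters(self) -> int:
        return len(self.site_sizes)

    @property
    def n_sites(self) -> int:
        return sum(len(s) for s in self.site_sizes)

    @property
    def n_individuals(self) -> int:
        return sum(n for sizes in self.site_sizes for n in sizes)

    @property
    def total_loci(self) -> int:
        return (
            self.n_loci + self.n_outlier_loci + self.n_paralog_loci + self.n_ld_copies
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for verifying the pipeline."""

    locus_class: pd.Series  # index locus_id, values in LOCUS_CLASSES
    ancestral_freq: pd.Series
    cluster_freqs: pd.DataFrame  # clusters x loci
    site_freqs: pd.DataFrame  # sites x loci
    params: SimParams

    def class_ids(self, cls: str) -> list[str]:
        if cls not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {cls!r}")
        return self.locus_class.index[self.locus_class == cls].tolist()

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.locus_class == c).sum()) for c in LOCUS_CLASSES}


def expected_fst(params: SimParams) -> dict[str, float]:
    """Closed-form fixation-index expectations implied by the Beta hierarchy.

    Differentiation compounds multiplicatively down the hierarchy, so the
    site-level total is ``1 - (1-Fct)(1-Fsc)`` and the individual-in-total
    index additionally folds in ``Fis``.
    """
    f_ct = params.f_ct if params.n_clusters > 1 else 0.0
    f_sc = params.f_sc
    f_st_site = 1.0 - (1.0 - f_ct) * (1.0 - f_sc)
    f_it = 1.0 - (1.0 - f_ct) * (1.0 - f_sc) * (1.0 - params.f_is)
    return {
        "f_ct": f_ct,
        "f_sc": f_sc,
        "f_is": params.f_is,
        "f_st_site": f_st_site,
        "f_it": f_it,
    }


def _beta_around(rng: np.random.Generator, p: np.ndarray, f: float, size) -> np.ndarray:
    """Draw Beta(p(1-f)/f, (1-p)(1-f)/f); degenerate delta at p when f == 0."""
    p = np.broadcast_to(p, size)
    if f <= 0.0:
        return p.copy()
    lam = (1.0 - f) / f
    a = np.clip(p * lam, 1e-9, None)
    b = np.clip((1.0 - p) * lam, 1e-9, None)
    return rng.beta(a, b)


def _draw_genotypes(
    rng: np.random.Generator, site_freq: np.ndarray, f_is: float
) -> np.ndarray:
    """Dosage draws with inbreeding: P(het) = 2pq(1-Fis)."""
    p = site_freq
    q = 1.0 - p
    p_het = 2.0 * p * q * (1.0 - f_is)
    p_hom_alt = p * p + f_is * p * q
    u = rng.random(p.shape)
    return np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0)).astype(
        np.int8
    )


def simulate_dataset(
    params: SimParams,
) -> tuple[VariantTable, SampleFrame, TruthRecord]:
    """Simulate genotypes, metadata and ground truth under ``params``.

    Deterministic given ``params.seed``: the same parameters yield
    byte-identical VCF output.
    """
    rng = np.random.default_rng(params.seed)
    n_ind = params.n_individuals

    # --- sample layout -------------------------------------------------
    cluster_ids = [f"C{i + 1}" for i in range(params.n_clusters)]
    site_rows = []
    sample_rows = []
    for ci, sizes in enumerate(params.site_sizes):
        for si, n in enumerate(sizes):
            site = f"{cluster_ids[ci]}S{si + 1:02d}"
            site_rows.append((site, cluster_ids[ci], n))
            for k in range(n):
                sample_rows.append((f"{site}i{k + 1:02d}", site, cluster_ids[ci]))
    site_ids = [r[0] for r in site_rows]

    # --- coordinates ---------------------------------------------------
    lon0, lat0 = params.coord_origin
    dlon, dlat = params.coord_span
    if params.spatial_clustering:
        centre_lon = lon0 + rng.random(params.n_clusters) * dlon
        centre_lat = lat0 + np.linspace(0.1, 0.9, params.n_clusters) * dlat
        site_lon, site_lat = [], []
        for site, cl, _n in site_rows:
            ci = cluster_ids.index(cl)
            site_lon.append(centre_lon[ci] + rng.normal(0, params.site_jitter))
            site_lat.append(centre_lat[ci] + rng.normal(0, params.site_jitter))
    else:
        site_lon = (lon0 + rng.random(len(site_rows)) * dlon).tolist()
        site_lat = (lat0 + rng.random(len(site_rows)) * dlat).tolist()
    coords = dict(zip(site_ids, zip(site_lon, site_lat)))

    # --- locus classes and frequencies --------------------------------
    n_base = params.n_loci + params.n_outlier_loci + params.n_paralog_loci
    classes = np.array(
        ["neutral"] * params.n_loci
        + ["outlier"] * params.n_outlier_loci
        + ["paralog"] * params.n_paralog_loci,
        dtype=object,
    )
    rng.shuffle(classes)

    lo, hi = params.anc_freq_range
    p_anc = lo + rng.random(n_base) * (hi - lo)

    n_clusters, n_sites = params.n_clusters, len(site_ids)
    cluster_freq = np.empty((n_clusters, n_base))
    is_outl = classes == "outlier"
    for ci in range(n_clusters):
        if n_clusters == 1:
            cluster_freq[ci] = p_anc
            continue
        row = _beta_around(rng, p_anc, params.f_ct, (n_base,))
        if is_outl.any():
            row[is_outl] = _beta_around(
                rng, p_anc[is_outl], params.outlier_f_ct, (int(is_outl.sum()),)
            )
        cluster_freq[ci] = row
    site_freq = np.empty((n_sites, n_base))
    for si, (site, cl, _n) in enumerate(site_rows):
        ci = cluster_ids.index(cl)
        site_freq[si] = _beta_around(
            rng, cluster_freq[ci], params.f_sc, (n_base,)
        )

    # --- genotypes -----------------------------------------------------
    genotypes = np.empty((n_base, n_ind), dtype=np.int8)
    col = 0
    for si, (site, cl, n) in enumerate(site_rows):
        block = _draw_genotypes(
            rng, np.broadcast_to(site_freq[si][:, None], (n_base, n)), params.f_is
        )
        genotypes[:, col : col + n] = block
        col += n

    # paralog loci: a collapsed duplicate maps reads from both copies, so
    # calls come out heterozygous far more often than HWE allows
    paralog_rows = np.flatnonzero(classes == "paralog")
    for l in paralog_rows:
        forced = rng.random(n_ind) < params.paralog_het_rate
        genotypes[l, forced] = 1

    # --- contig placement ----------------------------------------------
    per_contig = params.snps_per_contig
    n_contigs = int(np.ceil(n_base / per_contig))
    contig_of = np.repeat(np.arange(n_contigs), per_contig)[:n_base]
    positions = np.empty(n_base, dtype=int)
    for c in range(n_contigs):
        rows = np.flatnonzero(contig_of == c)
        pos = np.sort(
            rng.choice(np.arange(1, params.contig_length + 1), size=len(rows), replace=False)
        )
        positions[rows] = pos

    # --- LD copies: exact duplicates of neutral templates, same contig --
    if params.n_ld_copies:
        neutral_rows = np.flatnonzero(classes == "neutral")
        templates = rng.choice(neutral_rows, size=params.n_ld_copies, replace=False)
        extra_geno, extra_contig, extra_pos = [], [], []
        used: dict[int, set[int]] = {}
        for t in templates:
            c = contig_of[t]
            taken = used.setdefault(
                int(c), set(positions[np.flatnonzero(contig_of == c)].tolist())
            )
            # copies sit downstream of their template so the first-kept-wins
            # LD pass always removes the copy, never the template
            free = np.setdiff1d(
                np.arange(positions[t] + 1, 2 * params.contig_length + 1),
                sorted(taken),
            )
            p = int(rng.choice(free))
            taken.add(p)
            extra_geno.append(genotypes[t].copy())
            extra_contig.append(c)
            extra_pos.append(p)
        genotypes = np.vstack([genotypes, np.array(extra_geno, dtype=np.int8)])
        classes = np.concatenate([classes, np.array(["ld_copy"] * len(templates), dtype=object)])
        contig_of = np.concatenate([contig_of, np.array(extra_contig)])
        positions = np.concatenate([positions, np.array(extra_pos)])
        p_anc = np.concatenate([p_anc, p_anc[templates]])
        cluster_freq = np.hstack([cluster_freq, cluster_freq[:, templates]])
        site_freq = np.hstack([site_freq, site_freq[:, templates]])

    # --- missingness and depth -----------------------------------------
    n_total = genotypes.shape[0]
    if params.missing_rate > 0:
        miss = rng.random((n_total, n_ind)) < params.missing_rate
        genotypes[miss] = MISSING
    disp = params.depth_dispersion
    depths = rng.negative_binomial(
        disp, disp / (disp + params.depth_mean), size=(n_total, n_ind)
    ).astype(np.int32)

    # --- assemble, sorted by (contig, pos) ------------------------------
    contig_names = np.array([f"contig{c + 1:05d}" for c in range(n_contigs)])
    order = np.lexsort((positions, contig_of))
    ref = np.array(["A"] * n_total)
    alt = np.array(["G"] * n_total)
    loci = pd.DataFrame(
        {
            "contig": contig_names[contig_of[order]],
            "pos": positions[order],
            "ref": ref,
            "alt": alt,
        }
    )
    sample_ids = [r[0] for r in sample_rows]
    table = VariantTable(
        loci=loci,
        genotypes=genotypes[order],
        sample_ids=sample_ids,
        depths=depths[order],
    )

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "site_id": [r[1] for r in sample_rows],
            "longitude": [coords[r[1]][0] for r in sample_rows],
            "latitude": [coords[r[1]][1] for r in sample_rows],
            "cluster_id": [r[2] for r in sample_rows],
        }
    )
    frame = SampleFrame(meta)

    locus_ids = table.locus_ids
    truth = TruthRecord(
        locus_class=pd.Series(classes[order], index=locus_ids, name="locus_class"),
        ancestral_freq=pd.Series(p_anc[order], index=locus_ids, name="ancestral_freq"),
        cluster_freqs=pd.DataFrame(
            cluster_freq[:, order], index=cluster_ids, columns=locus_ids
        ),
        site_freqs=pd.DataFrame(site_freq[:, order], index=site_ids, columns=locus_ids),
        params=params,
    )
    return table, frame, truth
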