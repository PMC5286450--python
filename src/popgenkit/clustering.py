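"""Genetic-cluster inference: DAPC and an admixture-model Gibbs sampler.

DAPC (discriminant analysis of principal components) is the non-model
route: genotype dosages are mean-imputed and centered, reduced by PCA,
scanned over K with k-means scored by BIC, and the chosen partition is
described by a linear discriminant analysis whose discriminant-space
Gaussian model yields membership probabilities.

The model-based route is an admixture model: each individual's two allele
copies at each locus draw their cluster of origin from individual-specific
admixture proportions Q, and the allele itself from the origin cluster's
allele frequency.  A Gibbs sampler alternates allele-origin assignments,
Beta updates of cluster frequencies and Dirichlet updates of Q.  Replicate
runs are aligned by an optimal label permutation before averaging, and the
Evanno second-difference statistic of the replicate mean log-likelihoods
(delta-K) scores the number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import MISSING, ValidationError, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "DapcResult",
    "AdmixtureResult",
    "Dapc",
    "dapc_find_clusters",
    "dapc_fit",
    "AdmixtureModel",
    "admixture_fit",
    "align_q_matrices",
    "evanno_delta_k",
]

_W_FLOOR = 1e-12  # within-cluster SS floor guarding BIC at degenerate K


def _dosage_matrix(table: VariantTable) -> np.ndarray:
    """Samples x loci float dosage with missing entries mean-imputed.

    Imputation happens here only -- diversity statistics never impute.
    """
    g = table.genotypes.T.astype(float)  # (N, L)
    miss = g == MISSING
    g[miss] = np.nan
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    g = np.where(np.isnan(g), mu[None, :], g)
    return g - mu[None, :]


def _pca_scores(table: VariantTable, n_pcs: int) -> np.ndarray:
    x = _dosage_matrix(table)
    n, l = x.shape
    max_pcs = min(n - 1, l)
    if n_pcs > max_pcs:
        raise ValidationError(f"n_pcs={n_pcs} exceeds min(samples-1, loci)={max_pcs}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


@dataclass
class DapcResult:
    """DAPC fit: cluster assignments with discriminant-space memberships."""

    k: int
    n_pcs: int
    n_discriminants: int
    assignment: pd.Series  # sample -> cluster index
    memberships: pd.DataFrame  # samples x clusters, rows sum to 1
    var_explained: np.ndarray  # per discriminant function
    bic: pd.Series | None = None  # K -> BIC when a scan was run

    def __post_init__(self) -> None:
        rs = self.memberships.to_numpy().sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise ValidationError("membership rows must sum to 1")

    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        lines = [
            f"DAPC: K={self.k}, {self.n_pcs} PCs retained, "
            f"{self.n_discriminants} discriminant function(s)",
            "variance explained by discriminant functions: "
            + ", ".join(f"{v:.1%}" for v in self.var_explained),
            "cluster sizes: " + ", ".join(f"{c}:{n}" for c, n in sizes.items()),
        ]
        if self.bic is not None:
            best = int(self.bic.idxmin())
            lines.append(f"BIC scan: lowest at K={best}")
        return "\n".join(lines)


class Dapc:
    """DAPC estimator: ``find_clusters`` scans K by BIC, ``fit`` runs the
    discriminant step for a chosen K."""

    def __init__(self, table: VariantTable, n_pcs: int = 40, seed: int = 0):
        self.table = table
        max_pcs = min(table.n_samples - 1, table.n_loci)
        self.n_pcs = min(n_pcs, max_pcs)
        if self.n_pcs < n_pcs:
            logger.info("retaining %d PCs (requested %d)", self.n_pcs, n_pcs)
        self.seed = seed
        self._scores = _pca_scores(table, self.n_pcs)

    def find_clusters(self, k_range: Sequence[int] = range(1, 11)) -> pd.Series:
        """BIC(K) = n ln(W_K / n) + K ln(n) over a k-means scan.

        W_K is the within-cluster sum of squares in PC space (20 restarts
        per K, ties broken by the lowest W); K above the sample count is
        skipped with a warning.
        """
        from sklearn.cluster import KMeans

        n = self.table.n_samples
        bic = {}
        for k in k_range:
            if k > n:
                logger.warning("skipping K=%d > %d samples", k, n)
                continue
            if k == 1:
                w = float(((self._scores - self._scores.mean(axis=0)) ** 2).sum())
            else:
                km = KMeans(n_clusters=k, n_init=20, random_state=self.seed + k)
                km.fit(self._scores)
                w = float(km.inertia_)
            bic[k] = n * np.log(max(w, _W_FLOOR) / n) + k * np.log(n)
        if not bic:
            raise ValidationError("no feasible K in k_range")
        return pd.Series(bic, name="BIC").sort_index()

    def fit(self, k: int, bic: pd.Series | None = None) -> DapcResult:
        from sklearn.cluster import KMeans
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        if k < 2:
            raise ValidationError("dapc fit needs k >= 2")
        km = KMeans(n_clusters=k, n_init=20, random_state=self.seed + k)
        labels = km.fit_predict(self._scores)
        present = np.unique(labels)
        try:
            lda = LinearDiscriminantAnalysis(solver="svd")
            lda.fit(self._scores, labels)
        except np.linalg.LinAlgError:
            # singular within-class scatter: fall back to a ridge-regularized solver
            logger.warning("singular scatter in LDA; using shrinkage solver")
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
            lda.fit(self._scores, labels)
        probs = lda.predict_proba(self._scores)
        ratios = np.asarray(lda.explained_variance_ratio_)
        n_df = min(k - 1, self.n_pcs, len(ratios))
        assign = pd.Series(
            probs.argmax(axis=1), index=self.table.sample_ids, name="cluster"
        )
        memberships = pd.DataFrame(
            probs, index=self.table.sample_ids, columns=list(present)
        )
        return DapcResult(
            k=k,
            n_pcs=self.n_pcs,
            n_discriminants=n_df,
            assignment=assign,
            memberships=memberships,
            var_explained=ratios[:n_df],
            bic=bic,
        )


def dapc_find_clusters(
    table: VariantTable,
    k_range: Sequence[int] = range(1, 11),
    n_pcs: int = 40,
    seed: int = 0,
) -> pd.Series:
    """BIC per K for the k-means cluster scan (see :class:`Dapc`)."""
    return Dapc(table, n_pcs=n_pcs, seed=seed).find_clusters(k_range)


def dapc_fit(table: VariantTable, k: int, n_pcs: int = 40, seed: int = 0) -> DapcResult:
    """Fit DAPC at a chosen K (see :class:`Dapc`)."""
    return Dapc(table, n_pcs=n_pcs, seed=seed).fit(k)


# ----------------------------------------------------------------------
# Admixture model
# ----------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    """Admixture-model fit at one K over replicate chains."""

    k: int
    loglik: list[float]  # per-replicate mean data log-likelihood
    loglik_traces: list[np.ndarray]  # thinned post-burn-in traces
    q_replicates: list[pd.DataFrame]  # per-replicate posterior-mean Q
    q_consensus: pd.DataFrame  # label-aligned average of replicates

    def __post_init__(self) -> None:
        rs = self.q_consensus.to_numpy().sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise ValidationError("consensus Q rows must sum to 1")

    def summary(self) -> str:
        ll = np.array(self.loglik)
        return (
            f"Admixture model K={self.k}: {len(self.loglik)} replicate(s), "
            f"mean lnL {ll.mean():.1f} (sd {ll.std(ddof=1) if len(ll) > 1 else 0:.2f})"
        )


class AdmixtureModel:
    """Gibbs sampler for the admixture model at a fixed number of clusters.

    ``alpha`` is the symmetric Dirichlet parameter on admixture proportions
    (fixed, not sampled).  ``fit`` runs ``n_reps`` independent chains and
    aligns their Q matrices before averaging.
    """

    def __init__(self, table: VariantTable, k: int, alpha: float = 1.0):
        if k < 1:
            raise ValidationError("k must be >= 1")
        self.table = table
        self.k = k
        self.alpha = alpha
        g = table.genotypes.T  # (N, L)
        self.ok = g != MISSING
        self.g = np.where(self.ok, g, 0).astype(np.int8)
        # allele values of the two exchangeable copies per genotype
        self.x_a = (self.g >= 1) & self.ok  # first copy carries an alt if dosage >= 1
        self.x_b = (self.g == 2) & self.ok

    def _loglik(self, q: np.ndarray, p: np.ndarray) -> float:
        """log P(genotypes | Q, P) with allele copies independent given Q."""
        m = np.clip(q @ p, 1e-12, 1 - 1e-12)  # (N, L) marginal alt probability
        g = self.g
        ll = g * np.log(m) + (2 - g) * np.log1p(-m) + np.log(2.0) * (g == 1)
        return float(ll[self.ok].sum())

    def _run_chain(
        self, rng: np.random.Generator, burn_in: int, n_iter: int, thin: int
    ) -> tuple[np.ndarray, np.ndarray, float]:
        n, l, k = self.ok.shape[0], self.ok.shape[1], self.k
        p = rng.uniform(0.2, 0.8, size=(k, l))
        q = rng.dirichlet(np.full(k, self.alpha), size=n)
        q_sum = np.zeros((n, k))
        trace = []
        n_kept = 0
        for sweep in range(burn_in + n_iter):
            if k == 1:
                n_alt = (self.x_a.sum(axis=0) + self.x_b.sum(axis=0)).astype(float)
                n_tot = 2.0 * self.ok.sum(axis=0)
                p = rng.beta(1.0 + n_alt, 1.0 + (n_tot - n_alt))[None, :]
                q = np.ones((n, 1))
            else:
                # origin assignment of each allele copy
                w_alt = q[:, None, :] * p.T[None, :, :]  # (N, L, K)
                w_ref = q[:, None, :] * (1.0 - p.T)[None, :, :]
                za = self._sample_categorical(rng, np.where(self.x_a[..., None], w_alt, w_ref))
                zb = self._sample_categorical(rng, np.where(self.x_b[..., None], w_alt, w_ref))
                n_alt = np.zeros((k, l))
                n_ref = np.zeros((k, l))
                c = np.zeros((n, k))
                for ki in range(k):
                    ma = (za == ki) & self.ok
                    mb = (zb == ki) & self.ok
                    n_alt[ki] = (ma & self.x_a).sum(axis=0) + (mb & self.x_b).sum(axis=0)
                    n_ref[ki] = (ma & ~self.x_a).sum(axis=0) + (mb & ~self.x_b).sum(axis=0)
                    c[:, ki] = ma.sum(axis=1) + mb.sum(axis=1)
                p = rng.beta(1.0 + n_alt, 1.0 + n_ref)
                gam = rng.gamma(self.alpha + c)
                q = gam / gam.sum(axis=1, keepdims=True)
            if sweep >= burn_in and (sweep - burn_in) % thin == 0:
                q_sum += q
                trace.append(self._loglik(q, p))
                n_kept += 1
        return q_sum / n_kept, np.array(trace), float(np.mean(trace))

    @staticmethod
    def _sample_categorical(rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
        """Vectorized categorical draw along the last axis of a weight array."""
        cum = np.cumsum(w, axis=-1)
        tot = cum[..., -1:]
        u = rng.random(w.shape[:-1])[..., None] * tot
        return (u > cum).sum(axis=-1)

    def fit(
        self,
        burn_in: int = 2_000,
        n_iter: int = 10_000,
        n_reps: int = 3,
        seed: int = 0,
        thin: int = 10,
    ) -> AdmixtureResult:
        rng = np.random.default_rng(seed)
        qs, traces, lls = [], [], []
        for _rep in range(n_reps):
            q, trace, ll = self._run_chain(rng, burn_in, n_iter, thin)
            if not np.isfinite(ll):
                raise ValidationError("non-finite data log-likelihood in sampler")
            qs.append(q)
            traces.append(trace)
            lls.append(ll)
        aligned = align_q_matrices(qs)
        consensus = np.mean(aligned, axis=0)
        consensus = consensus / consensus.sum(axis=1, keepdims=True)
        idx = pd.Index(self.table.sample_ids, name="sample")
        cols = [f"cluster_{i + 1}" for i in range(self.k)]
        return AdmixtureResult(
            k=self.k,
            loglik=lls,
            loglik_traces=traces,
            q_replicates=[pd.DataFrame(a, index=idx, columns=cols) for a in aligned],
            q_consensus=pd.DataFrame(consensus, index=idx, columns=cols),
        )


def admixture_fit(
    table: VariantTable,
    k: int,
    burn_in: int = 2_000,
    n_iter: int = 10_000,
    n_reps: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
) -> AdmixtureResult:
    """Functional wrapper over :class:`AdmixtureModel`."""
    return AdmixtureModel(table, k, alpha=alpha).fit(
        burn_in=burn_in, n_iter=n_iter, n_reps=n_reps, seed=seed
    )


def align_q_matrices(qs: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Align replicate Q matrices to the first by optimal label permutation.

    The permutation maximizes the summed column dot products with the
    reference (solved exactly by the Hungarian algorithm), the batch
    equivalent of CLUMPP label matching.  Idempotent: aligning aligned
    matrices is the identity.
    """
    ref = np.asarray(qs[0])
    out = [ref.copy()]
    for q in qs[1:]:
        q = np.asarray(q)
        score = ref.T @ q  # (K, K) column-match scores
        rows, cols = linear_sum_assignment(-score)
        perm = np.empty(ref.shape[1], dtype=int)
        perm[rows] = cols
        out.append(q[:, perm])
    return out


def evanno_delta_k(loglik: Mapping[int, Sequence[float]]) -> pd.Series:
    """Evanno second-difference statistic over a K scan.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined only for interior K of a consecutive scan with >= 2 replicates.
    A zero replicate standard deviation leaves delta-K undefined.
    """
    ks = sorted(loglik)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError("delta-K needs >= 3 consecutive K values")
    means = {k: float(np.mean(loglik[k])) for k in ks}
    out = {}
    for k in ks[1:-1]:
        reps = np.asarray(loglik[k], dtype=float)
        if reps.size < 2:
            raise ValidationError(f"delta-K at K={k} needs >= 2 replicates")
        sd = reps.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"zero replicate sd at K={k}; delta-K undefined")
        out[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd
    return pd.Series(out, name="delta_K")
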