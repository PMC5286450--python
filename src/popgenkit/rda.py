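"""Redundancy analysis of population allele frequencies on spatial polynomials.

The response matrix is populations x loci alt-allele frequencies (one
allele per locus suffices: the complementary allele only flips column
signs, which constrained ordination is blind to).  The explanatory matrix
is an orthogonalized third-degree polynomial basis of the population
coordinates; forward selection admits terms one at a time by permutation
pseudo-F, guarding against overfitting with few populations.

The headline statistic is the constrained proportion of total variance;
multiplied by the overall F_ST it expresses the spatially structured share
of total genetic differentiation on the F_ST scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlleleFreqTable, ValidationError

__all__ = [
    "SpatialTerms",
    "RdaResult",
    "spatial_polynomials",
    "frequency_matrix",
    "Rda",
    "rda_fit",
    "forward_select",
    "explained_fst",
]

_ORTHO_TOL = 1e-8


@dataclass
class SpatialTerms:
    """Orthogonal polynomial spatial predictors, one row per population.

    Columns are unit-norm, mutually orthogonal, and orthogonal to the
    constant; labels follow the monomial they were seeded from
    (x, y, x2, xy, ... y3).
    """

    matrix: pd.DataFrame
    degree: int

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.shape[1]:
            gram = m.T @ m
            if not np.allclose(gram, np.eye(m.shape[1]), atol=1e-6):
                raise ValidationError("spatial terms must be orthonormal")
            if not np.allclose(m.sum(axis=0), 0.0, atol=1e-6):
                raise ValidationError("spatial terms must be orthogonal to the constant")

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)

    def select(self, labels) -> "SpatialTerms":
        return SpatialTerms(self.matrix[list(labels)], self.degree)


def _monomial_labels(degree: int, two_d: bool) -> list[tuple[str, int, int]]:
    if not two_d:
        return [(f"x{i}" if i > 1 else "x", i, 0) for i in range(1, degree + 1)]
    out = []
    for total in range(1, degree + 1):
        for ix in range(total, -1, -1):
            iy = total - ix
            parts = []
            if ix:
                parts.append("x" if ix == 1 else f"x{ix}")
            if iy:
                parts.append("y" if iy == 1 else f"y{iy}")
            out.append(("".join(parts), ix, iy))
    return out


def spatial_polynomials(coords: pd.DataFrame | np.ndarray, degree: int = 3) -> SpatialTerms:
    """Orthogonal polynomial basis of population coordinates.

    Coordinates (longitude, latitude in decimal degrees, one row per
    population) are standardized, raised to all monomials of total degree
    1..``degree`` in fixed order, then Gram-Schmidt orthogonalized against
    the constant and one another; terms falling inside the span of earlier
    ones (rank limit n-1) are dropped with a warning.  A degenerate
    coordinate (all equal) reduces the basis to the single varying axis.
    """
    if isinstance(coords, pd.DataFrame):
        index = coords.index
        xy = coords.to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
        index = pd.RangeIndex(len(xy))
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValidationError("coords must be (n, 2): longitude, latitude")
    n = xy.shape[0]
    spread = xy.std(axis=0)
    if (spread == 0).all() or n < 2:
        raise ValidationError("all coordinates identical; no spatial signal")
    two_d = bool((spread > 0).all())
    # standardize for conditioning; the polynomial span is affine-invariant
    var_cols = np.flatnonzero(spread > 0)
    z = np.zeros_like(xy)
    z[:, var_cols] = (xy[:, var_cols] - xy[:, var_cols].mean(axis=0)) / spread[var_cols]
    if not two_d:
        x = z[:, var_cols[0]]
        y = np.zeros(n)
    else:
        x, y = z[:, 0], z[:, 1]

    cols, labels = [], []
    basis = [np.ones(n) / np.sqrt(n)]
    for label, ix, iy in _monomial_labels(degree, two_d):
        v = x**ix * y**iy
        norm0 = np.linalg.norm(v)
        for b in basis:
            v = v - (b @ v) * b
        norm = np.linalg.norm(v)
        if norm0 == 0 or norm < _ORTHO_TOL * max(norm0, 1.0) or len(basis) >= n:
            continue
        v = v / norm
        basis.append(v)
        cols.append(v)
        labels.append(label)
    matrix = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n, 0)), index=index, columns=labels
    )
    return SpatialTerms(matrix=matrix, degree=degree)


def frequency_matrix(freqs: AlleleFreqTable) -> pd.DataFrame:
    """Populations x loci alt-allele frequency matrix, column-centered.

    The occasional NaN frequency (no genotyped individual in a population
    at a locus) is replaced by the column mean before centering.
    """
    f = freqs.freqs.copy()
    mu = np.nanmean(f, axis=0)
    ix = np.where(np.isnan(f))
    f[ix] = np.take(mu, ix[1])
    f = f - f.mean(axis=0)[None, :]
    return pd.DataFrame(f, index=freqs.group_ids, columns=freqs.locus_ids)


@dataclass
class RdaResult:
    """Constrained-ordination fit.

    ``constrained_prop`` is trace(Yhat' Yhat)/trace(Y'Y); per-axis
    proportions sum to it.  The pseudo-F compares constrained to residual
    variance on their degrees of freedom and is tested by permuting
    response rows.
    """

    constrained_prop: float
    axis_props: np.ndarray
    pseudo_f: float
    p_value: float
    selected: list[str]
    n_perm: int
    explained_fst_value: float | None = None

    def summary(self) -> str:
        axes = ", ".join(f"{v:.1%}" for v in self.axis_props[:4])
        lines = [
            f"RDA: {self.constrained_prop:.1%} of total variance constrained "
            f"by [{', '.join(self.selected) or 'none'}]",
            f"pseudo-F = {self.pseudo_f:.3f}, P = {self.p_value:.4f} "
            f"({self.n_perm} permutations)",
            f"leading axis proportions: {axes}",
        ]
        if self.explained_fst_value is not None:
            lines.append(
                f"spatially explained differentiation: F_ST equivalent "
                f"{self.explained_fst_value:.3f}"
            )
        return "\n".join(lines)


def _as_matrix(y) -> np.ndarray:
    if isinstance(y, AlleleFreqTable):
        return frequency_matrix(y).to_numpy()
    if isinstance(y, pd.DataFrame):
        return y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float)


def _fit_stats(yc: np.ndarray, x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(SS_fit, SS_total, singular values of Yhat) for centered response."""
    b, *_ = np.linalg.lstsq(x, yc, rcond=None)
    yhat = x @ b
    ss_fit = float((yhat**2).sum())
    ss_tot = float((yc**2).sum())
    s = np.linalg.svd(yhat, compute_uv=False)
    return ss_fit, ss_tot, s


class Rda:
    """Redundancy analysis of a centered response on spatial terms."""

    def __init__(self, y, terms: SpatialTerms):
        yc = _as_matrix(y)
        yc = yc - yc.mean(axis=0)[None, :]
        x = terms.matrix.to_numpy()
        if x.shape[0] != yc.shape[0]:
            raise ValidationError("response and terms have different row counts")
        if x.shape[1] and np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValidationError("spatial terms not full column rank")
        self.y = yc
        self.x = x
        self.terms = terms

    def fit(self, n_perm: int = 999, seed: int = 0) -> RdaResult:
        n, q = self.x.shape
        if q == 0:
            return RdaResult(0.0, np.array([]), np.nan, np.nan, [], 0)
        if q >= n - 1:
            raise ValidationError(f"saturated model: {q} terms for {n} populations")
        ss_fit, ss_tot, s = _fit_stats(self.y, self.x)
        prop = ss_fit / ss_tot if ss_tot > 0 else np.nan
        resid = ss_tot - ss_fit
        f_obs = (ss_fit / q) / (resid / (n - q - 1)) if resid > 0 else np.inf
        axis_props = (s**2) / ss_tot if ss_tot > 0 else s * np.nan

        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            yp = self.y[rng.permutation(n)]
            sf, st, _sv = _fit_stats(yp, self.x)
            fp = (sf / q) / ((st - sf) / (n - q - 1)) if st > sf else np.inf
            if fp >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        return RdaResult(
            constrained_prop=prop,
            axis_props=axis_props[: min(q, len(axis_props))],
            pseudo_f=f_obs,
            p_value=p,
            selected=self.terms.labels,
            n_perm=n_perm,
        )


def rda_fit(y, terms: SpatialTerms, n_perm: int = 999, seed: int = 0) -> RdaResult:
    """Functional wrapper over :class:`Rda`."""
    return Rda(y, terms).fit(n_perm=n_perm, seed=seed)


def forward_select(
    y,
    terms: SpatialTerms,
    alpha_enter: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> SpatialTerms:
    """Stepwise forward selection of spatial terms by permutation pseudo-F.

    At each step the candidate with the largest partial F (given the terms
    already in the model) is admitted if a row-permutation p-value is below
    ``alpha_enter``; selection stops when no candidate qualifies or the
    residual is numerically exhausted.  Because the tested statistic is the
    maximum over candidates, the permutation null is the permuted maximum
    as well -- without that correction, picking the best of q candidates
    and testing it alone would enter a spurious term with probability near
    1-(1-alpha)^q under the null.  The empty selection is a legitimate
    outcome.
    """
    yc = _as_matrix(y)
    yc = yc - yc.mean(axis=0)[None, :]
    n = yc.shape[0]
    ss_tot_full = float((yc**2).sum())
    rng = np.random.default_rng(seed)
    remaining = list(terms.labels)
    selected: list[str] = []

    def partial_f(ym: np.ndarray, labels_in: list[str], cand: str) -> float:
        x_new = terms.matrix[labels_in + [cand]].to_numpy()
        q_new = x_new.shape[1]
        if q_new >= n - 1:
            return -np.inf
        ss_cur = (
            _fit_stats(ym, terms.matrix[labels_in].to_numpy())[0] if labels_in else 0.0
        )
        ss_new, ss_tot, _ = _fit_stats(ym, x_new)
        resid = ss_tot - ss_new
        if resid <= 1e-12 * max(ss_tot, 1.0):
            return np.inf
        return (ss_new - ss_cur) / (resid / (n - q_new - 1))

    def best_f(ym: np.ndarray, labels_in: list[str], cands: list[str]):
        f_vals = {c: partial_f(ym, labels_in, c) for c in cands}
        best = max(f_vals, key=f_vals.get)
        return best, f_vals[best]

    while remaining:
        # residual numerically exhausted: nothing left to explain
        ss_explained = (
            _fit_stats(yc, terms.matrix[selected].to_numpy())[0] if selected else 0.0
        )
        if ss_tot_full - ss_explained <= 1e-10 * max(ss_tot_full, 1.0):
            break
        best, f_best = best_f(yc, selected, remaining)
        if not np.isfinite(f_best) and f_best < 0:
            break
        hits = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            _, f_perm = best_f(yp, selected, remaining)
            if f_perm >= f_best - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        if p < alpha_enter:
            selected.append(best)
            remaining.remove(best)
        else:
            break
    return terms.select(selected)


def explained_fst(constrained_prop: float, overall_fst: float) -> float:
    """Spatially explained differentiation on the F_ST scale.

    The product of the constrained-variance proportion and the overall
    F_ST, reported to three decimals.
    """
    if not (0.0 <= constrained_prop <= 1.0 and 0.0 <= overall_fst <= 1.0):
        raise ValidationError("both arguments must be fractions in [0, 1]")
    return round(constrained_prop * overall_fst, 3)
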