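"""Bayesian F_ST-outlier detection on a beta-binomial island model.

Population alt-allele counts are modelled as beta-binomial draws around a
per-locus ancestral frequency ``p_l``, with the beta dispersion set by a
locus-by-population differentiation coefficient on the logistic scale:

    logit(F_lj) = alpha_l * gamma_l + beta_j

``beta_j`` captures the population-specific drift intensity, ``alpha_l`` a
locus-specific departure (selection); ``gamma_l`` is a binary inclusion
indicator toggled by reversible-jump moves with prior inclusion odds
``1 : prior_odds``.  Loci under divergent selection acquire a positive
``alpha``; the posterior inclusion probability feeds a q-value (minimum
false discovery rate) per locus.

This is a biallelic specialization (beta-binomial rather than the general
multinomial-Dirichlet) -- every locus reaching this stage of the cascade
is biallelic.  Priors: ``p_l ~ U(0,1)``, ``beta_j ~ N(-1, 1)``,
``alpha_l ~ N(0, 1)`` when included.  Random-walk proposal widths are
adapted during burn-in by short pilot rounds targeting 25-45% acceptance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .core import AlleleFreqTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["OutlierResult", "OutlierScan", "fit_outlier_model", "qvalues"]

_ALPHA_PRIOR_SD = 1.0
_BETA_PRIOR_MEAN = -1.0
_BETA_PRIOR_SD = 1.0
_PILOT_ROUNDS = 10
_PILOT_SWEEPS = 50
_ACC_LOW, _ACC_HIGH = 0.25, 0.45
_THIN = 10


@dataclass
class OutlierResult:
    """Posterior summaries of the outlier scan.

    ``posterior_prob`` is the posterior probability that the locus-specific
    effect is included (i.e. that the locus departs from the genome-wide
    differentiation pattern); ``alpha`` its posterior mean (zero while
    excluded); ``qvalue`` the minimum FDR at which the locus would be
    flagged.  Monomorphic loci are excluded from the fit and carry NaN.
    """

    table: pd.DataFrame  # index locus; columns alpha, posterior_prob, qvalue, flag
    beta: pd.Series  # per-population effect, posterior mean
    fdr: float
    n_iter: int
    burn_in: int

    @property
    def posterior_prob(self) -> pd.Series:
        return self.table["posterior_prob"]

    @property
    def alpha(self) -> pd.Series:
        return self.table["alpha"]

    @property
    def qvalue(self) -> pd.Series:
        return self.table["qvalue"]

    @property
    def flag(self) -> pd.Series:
        return self.table["flag"]

    def outlier_ids(self) -> list[str]:
        return self.table.index[self.table["flag"]].tolist()

    def summary(self) -> str:
        n = len(self.table)
        n_fit = int(self.table["posterior_prob"].notna().sum())
        n_flag = int(self.table["flag"].sum())
        lines = [
            "F_ST outlier scan (RJ-MCMC, beta-binomial island model)",
            f"loci: {n} ({n - n_fit} monomorphic, excluded)",
            f"flagged at q <= {self.fdr}: {n_flag}",
            "population effects (beta, posterior mean):",
            self.beta.round(3).to_string(),
        ]
        return "\n".join(lines)


def qvalues(posterior_probs: np.ndarray) -> np.ndarray:
    """Q-values from posterior inclusion probabilities.

    Rank loci by descending posterior probability; the FDR of calling the
    top-j loci is the mean of their (1 - posterior); the q-value of the
    locus at rank k is the minimum of that FDR over all j >= k.  NaN
    probabilities (unfitted loci) yield NaN q-values.
    """
    p = np.asarray(posterior_probs, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.flatnonzero(~np.isnan(p))
    if ok.size == 0:
        return q
    order = ok[np.argsort(-p[ok], kind="stable")]
    fdr_topj = np.cumsum(1.0 - p[order]) / np.arange(1, order.size + 1)
    q_sorted = np.minimum.accumulate(fdr_topj[::-1])[::-1]
    q[order] = q_sorted
    return q


class OutlierScan:
    """Estimator object for the RJ-MCMC outlier scan; ``fit`` returns
    :class:`OutlierResult`."""

    def __init__(self, counts: AlleleFreqTable, prior_odds: float = 10.0):
        if counts.n_groups < 2:
            raise ValidationError("outlier scan needs >= 2 populations")
        if counts.n_loci < 1:
            raise ValidationError("outlier scan needs >= 1 locus")
        alt = counts.alt_counts
        if not np.issubdtype(alt.dtype, np.integer):
            if not np.allclose(alt, np.round(alt)):
                raise ValidationError("allele counts must be integers")
            alt = np.round(alt).astype(np.int64)
        self.alt = alt  # (P, L)
        self.m = counts.counts.astype(np.int64)
        self.locus_ids = np.asarray(counts.locus_ids)
        self.group_ids = list(counts.group_ids)
        self.prior_odds = float(prior_odds)
        # loci monomorphic across all populations carry no signal
        tot_alt = alt.sum(axis=0)
        tot_m = self.m.sum(axis=0)
        self.fit_mask = (tot_alt > 0) & (tot_alt < tot_m) & (tot_m > 0)
        n_mono = int((~self.fit_mask).sum())
        if n_mono:
            logger.warning("outlier scan: excluding %d monomorphic loci", n_mono)

    # -- likelihood -----------------------------------------------------
    @staticmethod
    def _ll_matrix(a, m, p, f):
        """Per-(population, locus) beta-binomial log likelihood (no binomial
        coefficient; it cancels in every MCMC ratio)."""
        f = np.clip(f, 1e-10, 1.0 - 1e-10)
        theta = (1.0 - f) / f
        a1 = p * theta
        b1 = (1.0 - p) * theta
        return betaln(a + a1, m - a + b1) - betaln(a1, b1)

    def fit(
        self,
        n_iter: int = 50_000,
        burn_in: int = 5_000,
        seed: int = 0,
        fdr: float = 0.05,
    ) -> OutlierResult:
        rng = np.random.default_rng(seed)
        a = self.alt[:, self.fit_mask].astype(float)
        m = self.m[:, self.fit_mask].astype(float)
        P, L = a.shape
        pi_incl = 1.0 / (1.0 + self.prior_odds)
        log_odds_prior = np.log(pi_incl) - np.log1p(-pi_incl)

        # initial state: moment estimates
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.clip(a.sum(axis=0) / m.sum(axis=0), 0.01, 0.99)
        beta = np.full(P, _BETA_PRIOR_MEAN)
        alpha = np.zeros(L)
        gamma = np.zeros(L, dtype=bool)

        s_p = np.full(L, 0.5)  # proposal widths (logit scale)
        s_a = np.full(L, 0.7)
        s_b = np.full(P, 0.3)

        def f_current():
            return expit(alpha * gamma + beta[:, None])

        ll = self._ll_matrix(a, m, p, f_current())  # (P, L)

        n_samples = 0
        sum_gamma = np.zeros(L)
        sum_alpha = np.zeros(L)
        sum_beta = np.zeros(P)

        acc_p = np.zeros(L)
        acc_a = np.zeros(L)
        try_a = np.zeros(L)
        acc_b = np.zeros(P)
        pilot_end = _PILOT_ROUNDS * _PILOT_SWEEPS

        total = burn_in + n_iter
        for sweep in range(total):
            # --- ancestral frequencies p (logit random walk) ----------
            lp = logit(p)
            p_new = expit(lp + rng.normal(0, s_p, L))
            ll_new = self._ll_matrix(a, m, p_new, f_current())
            log_r = (
                ll_new.sum(axis=0)
                - ll.sum(axis=0)
                + np.log(p_new * (1 - p_new))
                - np.log(p * (1 - p))
            )
            accept = np.log(rng.random(L)) < log_r
            p = np.where(accept, p_new, p)
            ll[:, accept] = ll_new[:, accept]
            acc_p += accept

            # --- locus effects alpha (included loci only) -------------
            if gamma.any():
                alpha_new = np.where(gamma, alpha + rng.normal(0, s_a, L), alpha)
                f_new = expit(alpha_new * gamma + beta[:, None])
                ll_new = self._ll_matrix(a, m, p, f_new)
                log_r = (
                    ll_new.sum(axis=0)
                    - ll.sum(axis=0)
                    + 0.5 * (alpha**2 - alpha_new**2) / _ALPHA_PRIOR_SD**2
                )
                accept = gamma & (np.log(rng.random(L)) < log_r)
                alpha = np.where(accept, alpha_new, alpha)
                ll[:, accept] = ll_new[:, accept]
                acc_a += accept
                try_a += gamma

            # --- reversible-jump toggle of gamma ----------------------
            # birth draws alpha from its prior, so proposal and prior
            # densities cancel and the ratio is likelihood x prior odds
            alpha_prop = np.where(
                gamma, alpha, rng.normal(0, _ALPHA_PRIOR_SD, L)
            )
            gamma_prop = ~gamma
            f_new = expit(alpha_prop * gamma_prop + beta[:, None])
            ll_new = self._ll_matrix(a, m, p, f_new)
            log_r = ll_new.sum(axis=0) - ll.sum(axis=0) + np.where(
                gamma_prop, log_odds_prior, -log_odds_prior
            )
            accept = np.log(rng.random(L)) < log_r
            gamma = np.where(accept, gamma_prop, gamma)
            alpha = np.where(accept & gamma, alpha_prop, np.where(gamma, alpha, 0.0))
            ll[:, accept] = ll_new[:, accept]

            # --- population effects beta (rows are independent, so all
            # populations can be proposed and accepted jointly) ---------
            b_new = beta + rng.normal(0, s_b, P)
            f_new = expit(alpha * gamma + b_new[:, None])
            ll_new = self._ll_matrix(a, m, p, f_new)
            log_r = (
                ll_new.sum(axis=1)
                - ll.sum(axis=1)
                + 0.5
                * ((beta - _BETA_PRIOR_MEAN) ** 2 - (b_new - _BETA_PRIOR_MEAN) ** 2)
                / _BETA_PRIOR_SD**2
            )
            accept_b = np.log(rng.random(P)) < log_r
            beta = np.where(accept_b, b_new, beta)
            ll[accept_b] = ll_new[accept_b]
            acc_b += accept_b

            # --- pilot adaptation during early burn-in ----------------
            if sweep < pilot_end and (sweep + 1) % _PILOT_SWEEPS == 0:
                rate_p = acc_p / _PILOT_SWEEPS
                s_p *= np.where(rate_p > _ACC_HIGH, 1.25, np.where(rate_p < _ACC_LOW, 0.8, 1.0))
                with np.errstate(invalid="ignore"):
                    rate_a = np.where(try_a > 0, acc_a / np.maximum(try_a, 1), 0.35)
                s_a *= np.where(rate_a > _ACC_HIGH, 1.25, np.where(rate_a < _ACC_LOW, 0.8, 1.0))
                rate_b = acc_b / _PILOT_SWEEPS
                s_b *= np.where(rate_b > _ACC_HIGH, 1.25, np.where(rate_b < _ACC_LOW, 0.8, 1.0))
                s_p = np.clip(s_p, 0.05, 3.0)
                s_a = np.clip(s_a, 0.05, 3.0)
                s_b = np.clip(s_b, 0.02, 2.0)
                acc_p[:] = 0
                acc_a[:] = 0
                try_a[:] = 0
                acc_b[:] = 0

            # --- collect ----------------------------------------------
            if sweep >= burn_in and (sweep - burn_in) % _THIN == 0:
                n_samples += 1
                sum_gamma += gamma
                sum_alpha += alpha * gamma
                sum_beta += beta

        post_prob = sum_gamma / n_samples
        alpha_mean = sum_alpha / n_samples
        beta_mean = sum_beta / n_samples

        L_all = self.locus_ids.size
        full_prob = np.full(L_all, np.nan)
        full_alpha = np.full(L_all, np.nan)
        full_prob[self.fit_mask] = post_prob
        full_alpha[self.fit_mask] = alpha_mean
        q = qvalues(full_prob)
        flag = np.where(np.isnan(q), False, q <= fdr)

        table = pd.DataFrame(
            {
                "alpha": full_alpha,
                "posterior_prob": full_prob,
                "qvalue": q,
                "flag": flag.astype(bool),
            },
            index=pd.Index(self.locus_ids, name="locus"),
        )
        return OutlierResult(
            table=table,
            beta=pd.Series(beta_mean, index=self.group_ids, name="beta"),
            fdr=fdr,
            n_iter=n_iter,
            burn_in=burn_in,
        )


def fit_outlier_model(
    counts: AlleleFreqTable,
    prior_odds: float = 10.0,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
    fdr: float = 0.05,
) -> OutlierResult:
    """Functional wrapper over :class:`OutlierScan`."""
    return OutlierScan(counts, prior_odds=prior_odds).fit(
        n_iter=n_iter, burn_in=burn_in, seed=seed, fdr=fdr
    )
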