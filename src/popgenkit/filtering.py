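"""The ordered SNP curation cascade, each stage individually callable.

Stage order follows the curation narrative for target-capture SNP panels:
per-genotype depth masking, site-quality removal (minor allele frequency
and per-SNP missingness), contig SNP-density control, within-contig LD
pruning, minimum inter-SNP spacing, Bayesian F_ST-outlier exclusion, and
removal of loci with significantly negative F_IS (the paralog screen).
Every stage records its input/removed/output locus counts in a
:class:`FilterReport`, so the audit trail chains exactly.

Boundary conventions: a call with depth >= min_depth is kept; a locus
passes the MAF filter only if MAF is strictly greater than the threshold
(">10%"); it passes the missingness filter only if its missing fraction is
strictly below the threshold; two SNPs exactly min_spacing apart both
survive ("at least 100 bp between each SNP").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    MISSING,
    ConfigurationError,
    SampleFrame,
    ValidationError,
    VariantTable,
    allele_frequencies,
)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "mask_low_depth",
    "filter_site_quality",
    "filter_contig_density",
    "ld_prune",
    "spacing_filter",
    "drop_loci",
    "run_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds of the curation cascade.

    Defaults mirror a stringent target-capture curation: depth >= 10 reads
    per call, MAF > 10%, missingness < 25%, contigs with < 10 bp per SNP
    dropped, r^2 > 0.5 pruned, >= 100 bp between SNPs, outlier FDR 0.05 and
    paralog-screen alpha 0.05.
    """

    min_depth: int = 10
    min_maf: float = 0.10
    max_missing: float = 0.25
    min_bp_per_snp: float = 10.0
    ld_r2_max: float = 0.5
    min_spacing: int = 100
    outlier_fdr: float = 0.05
    fis_alpha: float = 0.05
    # stage toggles and sampler scale for the two statistical stages
    scan_outliers: bool = True
    screen_paralogs: bool = True
    outlier_prior_odds: float = 10.0
    outlier_burn_in: int = 2_000
    outlier_n_iter: int = 10_000
    fis_n_perm: int = 1_000

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing", "outlier_fdr", "fis_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.min_depth < 0 or self.min_spacing < 0:
            raise ValidationError("min_depth and min_spacing must be >= 0")


@dataclass
class FilterReport:
    """Ordered per-stage locus counts and removed-locus ids."""

    stages: list[dict] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)

    def append(
        self, stage: str, n_in: int, removed_ids: Sequence[str], n_out: int, **extra
    ) -> None:
        if n_in - len(removed_ids) != n_out:
            raise ValidationError(
                f"stage {stage!r}: {n_in} in - {len(removed_ids)} removed != {n_out} out"
            )
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValidationError(
                f"stage {stage!r}: n_in {n_in} does not chain from previous n_out "
                f"{self.stages[-1]['n_out']}"
            )
        row = {"stage": stage, "n_in": n_in, "n_removed": len(removed_ids), "n_out": n_out}
        row.update(extra)
        self.stages.append(row)
        self.removed[stage] = list(removed_ids)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "removed": self.removed}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = ["Filter cascade", "=" * 46]
        lines.append(f"{'stage':<22}{'in':>8}{'removed':>8}{'out':>8}")
        for s in self.stages:
            lines.append(
                f"{s['stage']:<22}{s['n_in']:>8}{s['n_removed']:>8}{s['n_out']:>8}"
            )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Individual stages
# ----------------------------------------------------------------------

def mask_low_depth(table: VariantTable, min_depth: int) -> VariantTable:
    """Set genotypes with read depth below ``min_depth`` to missing.

    Acts per call, never per locus; loci removed here: none.  A call with
    depth exactly ``min_depth`` is retained.
    """
    if table.depths is None:
        raise ConfigurationError("depth mask requested but table has no depths")
    out = table.copy()
    out.genotypes[out.depths < min_depth] = MISSING
    return out


def filter_site_quality(
    table: VariantTable, min_maf: float, max_missing: float
) -> tuple[VariantTable, list[str]]:
    """Remove loci with MAF <= min_maf or missing fraction >= max_missing.

    MAF is computed over non-missing genotypes only.
    """
    g = table.genotypes
    ok = g != MISSING
    n = ok.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, np.where(ok, g, 0).sum(axis=1) / np.maximum(2 * n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    miss_frac = 1.0 - n / table.n_samples
    keep = (maf > min_maf) & (miss_frac < max_missing)
    removed = table.locus_ids[~keep].tolist()
    return table.subset_loci(keep), removed


def filter_contig_density(
    table: VariantTable, min_bp_per_snp: float
) -> tuple[VariantTable, list[str]]:
    """Drop whole contigs whose mean inter-SNP gap is below ``min_bp_per_snp``.

    For a contig with k >= 2 SNPs the density is span/(k-1); single-SNP
    contigs are always retained.  Returns the filtered table and the ids of
    removed contigs.
    """
    if table.n_loci < 1:
        raise ValidationError("empty table")
    keep = np.ones(table.n_loci, dtype=bool)
    removed_contigs: list[str] = []
    for contig, sub in table.loci.groupby("contig", sort=False):
        if len(sub) < 2:
            continue
        pos = sub["pos"].to_numpy()
        density = (pos.max() - pos.min()) / (len(pos) - 1)
        if density < min_bp_per_snp:
            keep[sub.index.to_numpy()] = False
            removed_contigs.append(contig)
    return table.subset_loci(keep), removed_contigs


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing samples; zero-variance or n < 2 overlaps give 0."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return min(float(r * r), 1.0)


def ld_prune(table: VariantTable, r2_max: float) -> tuple[VariantTable, list[str]]:
    """Greedy within-contig LD pruning on genotype-dosage r^2.

    Loci are scanned in table order; a locus is removed if its r^2 with any
    already-retained locus on the same contig exceeds ``r2_max``.  The
    first member of a correlated pair therefore always survives, making the
    pass deterministic given input order.
    """
    keep = np.ones(table.n_loci, dtype=bool)
    g = table.genotypes
    for contig, sub in table.loci.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        retained: list[int] = []
        for i in idx:
            if any(_r2(g[i], g[j]) > r2_max for j in retained):
                keep[i] = False
            else:
                retained.append(i)
    removed = table.locus_ids[~keep].tolist()
    return table.subset_loci(keep), removed


def spacing_filter(table: VariantTable, min_spacing: int) -> tuple[VariantTable, list[str]]:
    """Enforce a minimum distance between retained SNPs on each contig.

    Left-to-right sweep in position order: a locus closer than
    ``min_spacing`` bp to the last retained locus is removed; a gap of
    exactly ``min_spacing`` satisfies the requirement.
    """
    keep = np.ones(table.n_loci, dtype=bool)
    for contig, sub in table.loci.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        last = None
        for i, p in zip(idx, pos):
            if last is not None and p - last < min_spacing:
                keep[i] = False
            else:
                last = p
    removed = table.locus_ids[~keep].tolist()
    return table.subset_loci(keep), removed


def drop_loci(
    table: VariantTable,
    ids: Sequence[str],
    stage_name: str,
    report: FilterReport | None = None,
) -> VariantTable:
    """Remove an explicit locus-id set (outlier or paralog exclusions)."""
    ids = list(ids)
    locus_ids = table.locus_ids
    known = set(locus_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise ValidationError(f"unknown locus ids: {unknown[:5]}")
    drop = np.isin(locus_ids, ids)
    out = table.subset_loci(~drop)
    if report is not None:
        report.append(stage_name, table.n_loci, ids, out.n_loci)
    return out


# ----------------------------------------------------------------------
# Full cascade
# ----------------------------------------------------------------------

def run_cascade(
    table: VariantTable,
    frame: SampleFrame,
    config: FilterConfig | None = None,
    seed: int = 0,
) -> tuple[VariantTable, FilterReport]:
    """Run the full curation cascade in its canonical order.

    depth mask -> site quality -> contig density -> LD prune -> spacing ->
    F_ST-outlier exclusion -> negative-F_IS (paralog) exclusion.  The two
    statistical stages group samples by sampling site and use ``seed`` for
    their MCMC / permutation randomness.  Pure function of its inputs: the
    same arguments always yield the same :class:`FilterReport`.
    """
    from .diversity import fis_test
    from .outliers import fit_outlier_model

    config = config or FilterConfig()
    frame.cross_check(table)
    report = FilterReport()

    t = table
    if t.depths is not None:
        masked_before = int((t.genotypes == MISSING).sum())
        t = mask_low_depth(t, config.min_depth)
        masked = int((t.genotypes == MISSING).sum()) - masked_before
        report.append("depth_mask", t.n_loci, [], t.n_loci, masked_calls=masked)

    n_in = t.n_loci
    t, removed = filter_site_quality(t, config.min_maf, config.max_missing)
    report.append("site_quality", n_in, removed, t.n_loci)

    n_in = t.n_loci
    before_ids = t.locus_ids
    t, removed_contigs = filter_contig_density(t, config.min_bp_per_snp)
    t_ids = set(t.locus_ids)
    report.append(
        "contig_density",
        n_in,
        [i for i in before_ids if i not in t_ids],
        t.n_loci,
        removed_contigs=removed_contigs,
    )

    n_in = t.n_loci
    t, removed = ld_prune(t, config.ld_r2_max)
    report.append("ld_prune", n_in, removed, t.n_loci)

    n_in = t.n_loci
    t, removed = spacing_filter(t, config.min_spacing)
    report.append("spacing", n_in, removed, t.n_loci)

    if config.scan_outliers and t.n_loci > 0:
        counts = allele_frequencies(t, frame.sites())
        res = fit_outlier_model(
            counts,
            prior_odds=config.outlier_prior_odds,
            n_iter=config.outlier_n_iter,
            burn_in=config.outlier_burn_in,
            seed=seed,
            fdr=config.outlier_fdr,
        )
        t = drop_loci(t, res.outlier_ids(), "outlier_scan", report)

    if config.screen_paralogs and t.n_loci > 0:
        fis = fis_test(
            t,
            frame.sites(),
            n_perm=max(config.fis_n_perm, 100),
            seed=seed + 1,
            alpha=config.fis_alpha,
        )
        t = drop_loci(t, fis.flagged_ids(), "negative_fis", report)

    return t, report
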