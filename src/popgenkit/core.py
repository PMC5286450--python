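"""Genotype/metadata data model and standard-format I/O.

The central container is :class:`VariantTable`, a biallelic-locus x sample
matrix of diploid genotype calls stored as alt-allele dosages (0, 1, 2;
``-1`` for missing), with optional per-call read depths and 1-based locus
coordinates.  Sample metadata (site membership, coordinates, optional
cluster labels) lives in :class:`SampleFrame`; the nesting used by AMOVA,
F-statistics and RDA is a :class:`Hierarchy`.

Genotypes discard phase: every downstream statistic in this package is a
function of allele counts or dosage, never of haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file."""


class EmptyInputError(ValueError):
    """Input contains no usable records."""


class ValidationError(ValueError):
    """Inconsistent data passed to an operation."""


class ConfigurationError(ValueError):
    """Operation invoked without a required field (e.g. depths)."""


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a panel of diploid samples.

    Parameters
    ----------
    loci
        DataFrame with columns ``contig`` (str), ``pos`` (1-based int bp),
        ``ref``, ``alt`` (single characters).  Row order defines locus order;
        positions must be strictly increasing within a contig.
    genotypes
        ``(n_loci, n_samples)`` int8 array of alt-allele dosages; ``-1``
        marks a missing call.
    sample_ids
        Ordered sample identifiers, one per genotype column.
    depths
        Optional ``(n_loci, n_samples)`` array of non-negative read depths.
    """

    loci: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: list[str]
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_loci, n_samples = self.genotypes.shape
        if len(self.loci) != n_loci:
            raise ValidationError(
                f"{len(self.loci)} locus records but genotype matrix has {n_loci} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but genotype matrix has {n_samples} columns"
            )
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("sample ids are not unique")
        g = self.genotypes
        if not np.isin(g, (MISSING, 0, 1, 2)).all():
            raise ValidationError("genotype entries must be in {-1, 0, 1, 2}")
        if self.depths is not None:
            if self.depths.shape != g.shape:
                raise ValidationError("depth matrix shape differs from genotype matrix")
            if (self.depths < 0).any():
                raise ValidationError("negative read depth")
        for contig, sub in self.loci.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on contig {contig!r}"
                )

    # -- basic accessors ------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        """``contig:pos`` identifiers, the locus key throughout the package."""
        return (
            self.loci["contig"].astype(str) + ":" + self.loci["pos"].astype(str)
        ).to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset_loci(self, keep: np.ndarray) -> "VariantTable":
        """Return a new table restricted to loci selected by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return VariantTable(
            loci=self.loci.iloc[idx],
            genotypes=self.genotypes[idx],
            sample_ids=self.sample_ids,
            depths=None if self.depths is None else self.depths[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "VariantTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        cols = np.array([index[s] for s in sample_ids])
        return VariantTable(
            loci=self.loci,
            genotypes=self.genotypes[:, cols],
            sample_ids=list(sample_ids),
            depths=None if self.depths is None else self.depths[:, cols],
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            loci=self.loci.copy(),
            genotypes=self.genotypes.copy(),
            sample_ids=list(self.sample_ids),
            depths=None if self.depths is None else self.depths.copy(),
        )


@dataclass
class SampleFrame:
    """Per-sample metadata: sampling site, coordinates, optional cluster label."""

    frame: pd.DataFrame  # columns: sample_id, site_id, longitude, latitude[, cluster_id]

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        required = ["sample_id", "site_id", "longitude", "latitude"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
        if "cluster_id" not in df.columns:
            df["cluster_id"] = None
        df["longitude"] = df["longitude"].astype(float)
        df["latitude"] = df["latitude"].astype(float)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.frame["site_id"].unique().tolist())

    def sites(self) -> dict[str, list[str]]:
        """Mapping site_id -> sample ids, sites in sorted order."""
        return {
            site: sub["sample_id"].tolist()
            for site, sub in self.frame.groupby("site_id", sort=True)
        }

    def clusters(self) -> dict[str, list[str]]:
        """Mapping cluster_id -> sample ids; requires cluster labels to be set."""
        if self.frame["cluster_id"].isna().any():
            raise ValidationError("cluster_id not set for all samples")
        return {
            cl: sub["sample_id"].tolist()
            for cl, sub in self.frame.groupby("cluster_id", sort=True)
        }

    def site_coordinates(self) -> pd.DataFrame:
        """One row per site with its (longitude, latitude); sites in sorted order."""
        return (
            self.frame.groupby("site_id", sort=True)[["longitude", "latitude"]]
            .mean()
        )

    def with_clusters(self, assignment: Mapping[str, str]) -> "SampleFrame":
        """Return a copy with cluster_id set from a sample_id -> cluster mapping."""
        df = self.frame.copy()
        df["cluster_id"] = df["sample_id"].map(dict(assignment))
        return SampleFrame(df)

    def hierarchy(self) -> "Hierarchy":
        return Hierarchy.from_frame(self)

    def cross_check(self, table: VariantTable) -> None:
        """Raise unless the metadata covers exactly the table's samples."""
        meta = set(self.sample_ids)
        vcf = set(table.sample_ids)
        if meta != vcf:
            raise ValidationError(
                f"sample sets differ: {len(vcf - meta)} in VCF only, "
                f"{len(meta - vcf)} in metadata only"
            )


@dataclass
class Hierarchy:
    """Nesting of samples in sites and sites in genetic clusters.

    The two mappings must be disjoint partitions that jointly cover every
    sample: each site belongs to exactly one cluster and each sample to
    exactly one site.
    """

    cluster_sites: dict[str, list[str]]
    site_samples: dict[str, list[str]]

    def __post_init__(self) -> None:
        sites_in_clusters = [s for ss in self.cluster_sites.values() for s in ss]
        if len(sites_in_clusters) != len(set(sites_in_clusters)):
            raise ValidationError("a site appears in more than one cluster")
        if set(sites_in_clusters) != set(self.site_samples):
            raise ValidationError("cluster->site and site->sample mappings disagree")
        samples = [s for ss in self.site_samples.values() for s in ss]
        if len(samples) != len(set(samples)):
            raise ValidationError("a sample appears in more than one site")

    @classmethod
    def from_frame(cls, frame: SampleFrame) -> "Hierarchy":
        df = frame.frame
        if df["cluster_id"].isna().any():
            raise ValidationError("hierarchy requires cluster_id for every sample")
        pairs = df[["site_id", "cluster_id"]].drop_duplicates()
        if pairs["site_id"].duplicated().any():
            raise ValidationError("a site is assigned to more than one cluster")
        cluster_sites = {
            cl: sorted(sub["site_id"].tolist())
            for cl, sub in pairs.groupby("cluster_id", sort=True)
        }
        return cls(cluster_sites=cluster_sites, site_samples=frame.sites())

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.cluster_sites)

    def cluster_samples(self) -> dict[str, list[str]]:
        return {
            cl: [s for site in sites for s in self.site_samples[site]]
            for cl, sites in self.cluster_sites.items()
        }

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.site_samples.values())


@dataclass
class AlleleFreqTable:
    """Per-group alt-allele frequencies with the allele counts behind them.

    ``freqs[g, l]`` is NaN exactly where ``counts[g, l] == 0`` (no genotyped
    individual in group *g* at locus *l*); ``counts`` are allele counts,
    i.e. twice the number of genotyped diploids.  ``alt_counts`` are the
    integer alt-allele tallies, kept exact for count-based models.
    """

    freqs: np.ndarray
    counts: np.ndarray
    alt_counts: np.ndarray
    group_ids: list[str]
    locus_ids: np.ndarray

    def __post_init__(self) -> None:
        f, c = self.freqs, self.counts
        if f.shape != c.shape or f.shape != self.alt_counts.shape:
            raise ValidationError("frequency/count matrices differ in shape")
        with np.errstate(invalid="ignore"):
            bad = (~np.isnan(f)) & ((f < 0) | (f > 1))
        if bad.any():
            raise ValidationError("allele frequency outside [0, 1]")
        if (np.isnan(f) != (c == 0)).any():
            raise ValidationError("frequency missing iff allele count is zero")

    @property
    def n_groups(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------

def read_vcf(path: str | Path) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Only biallelic SNP records are kept; multiallelic or non-SNP records are
    skipped and counted in a log message.  Genotypes are encoded as alt
    dosage, phase ignored; per-genotype DP is loaded when the FORMAT carries
    it.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    contigs: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    have_depth = True
    n_skipped = 0

    for var in vcf:
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.REF.upper() not in _BASES
            or var.ALT[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        geno_rows.append(g)
        contigs.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF.upper())
        alts.append(var.ALT[0].upper())
        if have_depth:
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                have_depth = False
            else:
                dp = dp.astype(np.int32).reshape(-1)
                dp[dp < 0] = 0  # cyvcf2 encodes missing DP as negative sentinel
                depth_rows.append(dp)

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not geno_rows:
        raise EmptyInputError(f"no biallelic SNP records in {path}")

    loci = pd.DataFrame(
        {"contig": contigs, "pos": positions, "ref": refs, "alt": alts}
    )
    depths = np.vstack(depth_rows) if have_depth and depth_rows else None
    if depths is not None and depths.shape[0] != len(geno_rows):
        depths = None  # DP present on some records only: treat as absent
    return VariantTable(
        loci=loci,
        genotypes=np.vstack(geno_rows),
        sample_ids=sample_ids,
        depths=depths,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str | Path) -> Path:
    """Write a :class:`VariantTable` as an uncompressed VCF 4.2 file.

    The FORMAT carries GT, plus DP when the table has depths.  Round trip
    with :func:`read_vcf` reproduces genotypes, depths and coordinates
    exactly.
    """
    path = Path(path)
    has_dp = table.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=popgenkit",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for contig in table.loci["contig"].unique():
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.sample_ids)
    )
    loci = table.loci
    for i in range(table.n_loci):
        row = loci.iloc[i]
        calls = []
        for j in range(table.n_samples):
            gt = _GT_STRINGS[int(table.genotypes[i, j])]
            if has_dp:
                gt = f"{gt}:{int(table.depths[i, j])}"
            calls.append(gt)
        lines.append(
            f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t{fmt}\t"
            + "\t".join(calls)
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write VCF to {path}: {exc}") from exc
    return path


def read_metadata(path: str | Path) -> SampleFrame:
    """Read delimited sample metadata (CSV or TSV, delimiter sniffed).

    Requires columns ``sample_id``, ``site_id``, ``longitude``, ``latitude``;
    ``cluster_id`` is optional.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"sample_id": str, "site_id": str})
    return SampleFrame(df)


def write_metadata(frame: SampleFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.frame.to_csv(path, sep="\t", index=False)
    return path


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------

def allele_frequencies(
    table: VariantTable, grouping: Mapping[str, Sequence[str]]
) -> AlleleFreqTable:
    """Per-group alt-allele frequencies.

    freq(group, locus) = (sum of dosages) / (2 x genotyped individuals);
    a group with no genotyped individual at a locus gets a NaN frequency and
    an allele count of zero, never an exception.
    """
    if not grouping:
        raise ValidationError("grouping is empty")
    index = {s: i for i, s in enumerate(table.sample_ids)}
    group_ids = list(grouping)
    n_groups, n_loci = len(group_ids), table.n_loci
    alt = np.zeros((n_groups, n_loci), dtype=np.int64)
    counts = np.zeros((n_groups, n_loci), dtype=np.int64)
    for gi, gid in enumerate(group_ids):
        members = grouping[gid]
        unknown = [s for s in members if s not in index]
        if unknown:
            raise ValidationError(f"group {gid!r} has unknown samples: {unknown[:5]}")
        cols = np.array([index[s] for s in members], dtype=int)
        g = table.genotypes[:, cols]
        ok = g != MISSING
        alt[gi] = np.where(ok, g, 0).sum(axis=1)
        counts[gi] = 2 * ok.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(counts > 0, alt / np.maximum(counts, 1), np.nan)
    return AlleleFreqTable(
        freqs=freqs,
        counts=counts,
        alt_counts=alt,
        group_ids=group_ids,
        locus_ids=table.locus_ids,
    )
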