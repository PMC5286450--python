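"""Replication checks against an externally curated neutral SNP panel.

Given a final curated call set (a multi-sample VCF of neutral biallelic
SNPs), recompute the headline panel statistics: dimensions, overall and
per-cluster heterozygosities, pairwise cluster F_ST and the among-cluster
AMOVA share.  When no metadata accompanies the VCF, genetic clusters are
recovered from the genotypes themselves with DAPC at K = 3 and each
cluster doubles as its own population stratum (which collapses the
population-in-cluster level of the AMOVA but leaves the among-cluster
share comparable).
"""

from __future__ import annotations

from pathlib import Path

from .clustering import Dapc
from .core import Hierarchy, read_metadata, read_vcf
from .diversity import heterozygosities, nested_amova, pairwise_fst


def validate_neutral_snp_set(
    vcf_path: str | Path,
    metadata_path: str | Path | None = None,
    n_clusters: int = 3,
    seed: int = 0,
) -> dict:
    """Summary statistics of a curated neutral SNP panel.

    Returns a dict with keys ``n_loci``, ``n_samples``, ``overall_h_obs``,
    ``overall_h_exp``, ``cluster_h_exp`` (per recovered cluster),
    ``pairwise_fst`` (cluster-pair theta) and ``amova_among_cluster_pct``.
    """
    table = read_vcf(vcf_path)
    out: dict = {"n_loci": table.n_loci, "n_samples": table.n_samples}

    if metadata_path is not None:
        frame = read_metadata(metadata_path)
        frame.cross_check(table)
        clusters = frame.clusters()
        hierarchy = frame.hierarchy()
    else:
        dapc = Dapc(table, n_pcs=min(40, table.n_samples - 1), seed=seed)
        fit = dapc.fit(n_clusters)
        clusters = {}
        for sample, label in fit.assignment.items():
            clusters.setdefault(f"cluster_{label + 1}", []).append(sample)
        # without site metadata each cluster is its own population stratum
        hierarchy = Hierarchy(
            cluster_sites={c: [c] for c in clusters},
            site_samples=dict(clusters),
        )

    div = heterozygosities(table, clusters)
    out["overall_h_obs"] = div.overall_h_obs
    out["overall_h_exp"] = div.overall_h_exp
    out["cluster_sizes"] = {c: len(s) for c, s in clusters.items()}
    out["cluster_h_exp"] = div.per_group["h_exp"].to_dict()
    out["cluster_h_obs"] = div.per_group["h_obs"].to_dict()
    fst = pairwise_fst(table, clusters)
    out["pairwise_fst"] = fst.theta.to_dict()
    amova = nested_amova(table, hierarchy)
    out["amova_among_cluster_pct"] = float(amova.percent["among_cluster"])
    out["amova_f_ct"] = float(amova.f_stats["F_CT"])
    return out
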