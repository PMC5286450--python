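"""End-to-end orchestration: filter -> outliers -> diversity -> structure -> RDA.

``run_pipeline`` executes the stages in their canonical order on a VCF +
metadata pair (or a freshly simulated dataset), collecting every stage's
output and the fully resolved configuration -- seeds included -- into one
JSON-serializable report, so a rerun with the same config reproduces the
report byte for byte (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import Dapc, admixture_fit, evanno_delta_k
from .core import SampleFrame, VariantTable, allele_frequencies, read_metadata, read_vcf
from .diversity import global_fst, heterozygosities, nested_amova, pairwise_fst
from .filtering import FilterConfig, run_cascade
from .rda import Rda, explained_fst, forward_select, frequency_matrix, spatial_polynomials

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    vcf: str | None = None
    metadata: str | None = None
    output_dir: str = "popgenkit_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0
    # analysis toggles / parameters
    run_dapc: bool = True
    run_admixture: bool = True
    run_rda: bool = True
    amova_permutations: int = 199
    k_range: tuple[int, int] = (1, 6)
    n_pcs: int = 40
    admixture_burn_in: int = 500
    admixture_iter: int = 2_000
    admixture_reps: int = 3
    rda_degree: int = 3
    rda_permutations: int = 999

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filters", {}))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(filters=filt, **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(
    config: PipelineConfig,
    table: VariantTable | None = None,
    frame: SampleFrame | None = None,
) -> dict:
    """Run every enabled stage and return the consolidated report dict.

    ``table``/``frame`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.  On a stage failure
    the report carries an ``errors`` section and the partial results.
    """
    report: dict = {"config": _jsonable(config.to_dict()), "errors": {}}
    t0 = time.time()
    if table is None:
        table = read_vcf(config.vcf)
    if frame is None:
        frame = read_metadata(config.metadata)
    frame.cross_check(table)
    sites = frame.sites()

    def stage(name, fn):
        t = time.time()
        try:
            out = fn()
            logger.info("stage %-14s %.1fs", name, time.time() - t)
            return out
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("stage %s failed", name)
            report["errors"][name] = str(exc)
            return None

    # --- curation cascade ---------------------------------------------
    filtered_report = stage(
        "filter", lambda: run_cascade(table, frame, config.filters, seed=config.seed)
    )
    if filtered_report is None:
        report["exit_code"] = 1
        return report
    filtered, filt_report = filtered_report
    report["filter"] = filt_report.to_dict()

    # --- diversity ------------------------------------------------------
    def diversity_stage():
        div = heterozygosities(filtered, sites)
        out = {
            "per_site": div.per_group.reset_index().to_dict(orient="records"),
            "overall": {"h_obs": div.overall_h_obs, "h_exp": div.overall_h_exp},
        }
        try:
            clusters = frame.clusters()
            hierarchy = frame.hierarchy()
        except Exception:
            clusters = hierarchy = None
        if clusters is not None:
            amova = nested_amova(
                filtered, hierarchy, n_perm=config.amova_permutations, seed=config.seed
            )
            out["amova"] = {
                "percent": amova.percent.to_dict(),
                "f_stats": amova.f_stats.to_dict(),
                "p_values": amova.p_values.to_dict(),
            }
            out["pairwise_fst_clusters"] = pairwise_fst(filtered, clusters).theta.to_dict()
            div_cl = heterozygosities(filtered, clusters)
            out["per_cluster"] = div_cl.per_group.reset_index().to_dict(orient="records")
        return out

    div_out = stage("diversity", diversity_stage)
    if div_out:
        report["diversity"] = _jsonable(div_out)

    # --- structure ------------------------------------------------------
    if config.run_dapc:
        def dapc_stage():
            dapc = Dapc(filtered, n_pcs=config.n_pcs, seed=config.seed)
            k_lo, k_hi = config.k_range
            bic = dapc.find_clusters(range(k_lo, k_hi + 1))
            k_best = max(int(bic.idxmin()), 2)
            fit = dapc.fit(k_best, bic=bic)
            return {
                "bic": {int(k): float(v) for k, v in bic.items()},
                "chosen_k": int(bic.idxmin()),
                "cluster_sizes": fit.cluster_sizes().to_dict(),
                "var_explained": fit.var_explained.tolist(),
                "assignment": fit.assignment.to_dict(),
            }

        out = stage("dapc", dapc_stage)
        if out:
            report["dapc"] = _jsonable(out)

    if config.run_admixture:
        def admixture_stage():
            k_lo, k_hi = config.k_range
            lls = {}
            qs = {}
            for k in range(k_lo, k_hi + 1):
                res = admixture_fit(
                    filtered,
                    k,
                    burn_in=config.admixture_burn_in,
                    n_iter=config.admixture_iter,
                    n_reps=config.admixture_reps,
                    seed=config.seed + 100 * k,
                )
                lls[k] = res.loglik
                qs[k] = res.q_consensus
            delta = evanno_delta_k(lls) if k_hi - k_lo >= 2 else None
            out = {"loglik": {int(k): v for k, v in lls.items()}}
            if delta is not None:
                out["delta_k"] = {int(k): float(v) for k, v in delta.items()}
                out["best_k_delta"] = int(delta.idxmax())
                out["q_consensus_best_k"] = qs[out["best_k_delta"]].round(4).to_dict(
                    orient="index"
                )
            return out

        out = stage("admixture", admixture_stage)
        if out:
            report["admixture"] = _jsonable(out)

    # --- spatial RDA ----------------------------------------------------
    if config.run_rda:
        def rda_stage():
            freqs = allele_frequencies(filtered, sites)
            y = frequency_matrix(freqs)
            coords = frame.site_coordinates().loc[list(sites)]
            terms = spatial_polynomials(coords, degree=config.rda_degree)
            chosen = forward_select(
                y, terms, n_perm=config.rda_permutations, seed=config.seed
            )
            out = {"terms_available": terms.labels, "terms_selected": chosen.labels}
            if chosen.labels:
                res = Rda(y, chosen).fit(n_perm=config.rda_permutations, seed=config.seed)
                fst = global_fst(filtered, sites)
                out.update(
                    {
                        "constrained_prop": res.constrained_prop,
                        "pseudo_f": res.pseudo_f,
                        "p_value": res.p_value,
                        "overall_fst": fst,
                        "explained_fst": explained_fst(
                            min(max(res.constrained_prop, 0.0), 1.0),
                            min(max(fst, 0.0), 1.0),
                        ),
                    }
                )
            return out

        out = stage("rda", rda_stage)
        if out:
            report["rda"] = _jsonable(out)

    report["n_loci_final"] = filtered.n_loci
    report["runtime_s"] = round(time.time() - t0, 2)
    report["exit_code"] = 1 if report["errors"] else 0
    return report


def write_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
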