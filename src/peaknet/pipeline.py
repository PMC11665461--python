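"""End-to-end orchestration: QC -> network -> hubs -> PCA -> survival -> enrichment.

The network and hub set are built on the full multi-group matrix; the axis,
survival and enrichment stages run on a named cohort subgroup when
``cohort_group`` is set (mirroring a pan-cancer network reused for a
single-cancer cohort). Every stage writes its artifacts into the run
directory together with a machine-readable summary, the resolved config,
its hash, and a log; a failing stage aborts with the stage name and leaves
a resumable state file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import axis as axis_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import network as net_mod
from . import qc as qc_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults match the method's
    standard settings (|r| >= 0.4 edges, top 10% hubs, 5-component PCA,
    component 2 as the axis of interest, 20 pack-year smoking cutoff)."""

    matrix_path: str = ""
    clinical_path: str = ""
    peak_gene_map_path: str = ""
    gmt_path: str = ""
    matrix_format: str = "tsv"
    cohort_group: str | None = None
    r_threshold: float = 0.4
    indirect_depth: int = 1
    hub_fraction: float = 0.10
    max_identical_fraction: float = 0.05
    min_pairs: int = 8
    n_components: int = 5
    component_of_interest: int = 2
    pack_year_cutoff: float = 20.0
    pc_corr_threshold: float = 0.8
    alpha: float = 0.05
    fdr_cutoff: float = 0.05
    covariates: list[str] = field(default_factory=lambda: list(surv_mod.DEFAULT_COVARIATES))
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if not 0 < self.max_identical_fraction < 1:
            raise ValueError("max_identical_fraction must be in (0, 1)")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if not 0 < self.pc_corr_threshold <= 1:
            raise ValueError("pc_corr_threshold must be in (0, 1]")
        if self.component_of_interest < 1 or self.component_of_interest > self.n_components:
            raise ValueError("component_of_interest must be within 1..n_components")
        if self.pack_year_cutoff != io_mod.PACK_YEAR_CUTOFF:
            logger.warning(
                "pack_year_cutoff %.1f differs from the standard %.1f",
                self.pack_year_cutoff, io_mod.PACK_YEAR_CUTOFF,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the run summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    summary: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    state_file = outdir / "state.json"

    def _stage(name):
        def wrap(fn):
            try:
                out = fn()
            except Exception as err:
                state_file.write_text(
                    json.dumps({"failed_stage": name, "error": str(err)}, indent=2)
                )
                raise StageError(name, err) from err
            summary["stages"][name] = out if out is not None else {}
            return out
        return wrap

    # ---- inputs ---------------------------------------------------------
    holder: dict = {}

    @_stage("read_inputs")
    def _read():
        matrix = io_mod.read_peak_matrix(config.matrix_path, config.matrix_format)
        clinical = io_mod.read_clinical(config.clinical_path)
        by_sample = io_mod.clinical_index(clinical)
        if matrix.sample_group is None:
            groups = {
                s: (by_sample[s].cancer_type or "all")
                for s in matrix.sample_ids
                if s in by_sample
            }
            if len(groups) == len(matrix.sample_ids):
                matrix.sample_group = groups
        holder.update(
            matrix=matrix,
            clinical=clinical,
            pgmap=io_mod.read_peak_gene_map(config.peak_gene_map_path),
            gene_sets=io_mod.read_gmt(config.gmt_path),
        )
        return {"n_peaks": matrix.n_peaks, "n_samples": matrix.n_samples}

    @_stage("qc")
    def _qc():
        filtered = qc_mod.filter_low_quality(holder["matrix"], config.max_identical_fraction)
        dropped = sorted(set(holder["matrix"].peak_ids) - set(filtered.peak_ids))
        _write_tsv(pd.DataFrame({"dropped_peak_id": dropped}), outdir / "dropped_peaks.tsv", chash)
        holder["filtered"] = filtered
        holder["mask"] = qc_mod.mask_outliers(filtered)
        return {
            "n_dropped": len(dropped),
            "n_kept": filtered.n_peaks,
            "n_outlier_entries": holder["mask"].n_flagged,
        }

    @_stage("network")
    def _network():
        net = net_mod.network_from_matrix(
            holder["filtered"],
            holder["mask"],
            r_threshold=config.r_threshold,
            min_pairs=config.min_pairs,
            indirect_depth=config.indirect_depth,
        )
        hubs = net_mod.select_hubs(net, config.hub_fraction)
        _write_tsv(
            pd.DataFrame({"peak_id": net.node_ids, "degree": net.degree}),
            outdir / "degree.tsv", chash,
        )
        _write_tsv(pd.DataFrame({"hub_peak_id": hubs}), outdir / "hubs.tsv", chash)
        if net.n_nodes <= 5000:
            edges = [
                {"peak_a": a, "peak_b": b, "edge_type": kind}
                for kind, pairs in (
                    ("direct", net.direct_edges), ("indirect", net.indirect_edges)
                )
                for a, b in sorted(pairs)
            ]
            _write_tsv(pd.DataFrame(edges), outdir / "edges.tsv", chash)
        holder["network"], holder["hubs"] = net, hubs
        return {
            "n_direct_edges": int(sp.triu(net.direct, 1).nnz),
            "n_indirect_edges": int(sp.triu(net.indirect, 1).nnz),
            "n_hubs": len(hubs),
        }

    @_stage("cohort")
    def _cohort():
        matrix = holder["filtered"]
        if config.cohort_group is not None:
            members = [
                s for s in matrix.sample_ids
                if matrix.sample_group and matrix.sample_group[s] == config.cohort_group
            ]
            if not members:
                raise ValueError(f"no samples in cohort group {config.cohort_group!r}")
            matrix = matrix.subset_samples(members)
        holder["cohort"] = matrix
        # outlier fences are recomputed on the analysis cohort; the mask
        # feeds the peak-PC correlations, not the decomposition
        holder["cohort_mask"] = qc_mod.mask_outliers(matrix)
        return {"n_cohort_samples": matrix.n_samples}

    @_stage("pca")
    def _pca():
        pca = axis_mod.run_pca(
            holder["cohort"], holder["hubs"], n_components=config.n_components,
            mask=holder["cohort_mask"],
        )
        scores = pd.DataFrame(
            pca.scores,
            columns=[f"PC{i + 1}" for i in range(pca.n_components)],
        )
        scores.insert(0, "sample_id", pca.sample_ids)
        _write_tsv(scores, outdir / "pca_scores.tsv", chash)
        _write_tsv(
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(pca.n_components)],
                    "explained_fraction": pca.explained_fraction,
                }
            ),
            outdir / "pca_explained.tsv", chash,
        )
        holder["pca"] = pca
        return {
            "explained_fraction": [round(float(x), 6) for x in pca.explained_fraction],
        }

    @_stage("axis_partition")
    def _partition():
        part = axis_mod.axis_partition(holder["pca"], config.component_of_interest)
        _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": part.sample_ids,
                    "distance": [part.distance[s] for s in part.sample_ids],
                    "group": ["outside" if s in part.outside else "inside"
                              for s in part.sample_ids],
                }
            ),
            outdir / "axis_partition.tsv", chash,
        )
        holder["partition"] = part
        return {
            "border": part.border,
            "n_inside": len(part.inside),
            "n_outside": len(part.outside),
        }

    @_stage("group_comparison")
    def _compare():
        try:
            cmp_res = axis_mod.compare_groups(
                holder["partition"], holder["clinical"], alpha=config.alpha
            )
        except ValueError as err:
            logger.warning("group comparison skipped: %s", err)
            return {"skipped": str(err)}
        holder["comparison"] = cmp_res
        return {
            "t_statistic": cmp_res.t_statistic,
            "p_value": cmp_res.p_value,
            "n_light": len(cmp_res.group_a),
            "n_heavy": len(cmp_res.group_b),
            "n_excluded": len(cmp_res.excluded),
            "significant": cmp_res.significant,
        }

    @_stage("survival")
    def _survival():
        out = {}
        for endpoint in ("OS", "PFS"):
            entry: dict = {}
            try:
                km = surv_mod.km_logrank(holder["partition"], holder["clinical"], endpoint)
                entry["logrank_p"] = km.logrank_p
                entry["n_per_group"] = km.n_per_group
                for gname, curve in km.km_curves.items():
                    _write_tsv(curve, outdir / f"km_{endpoint.lower()}_{gname}.tsv", chash)
            except ValueError as err:
                entry["km_skipped"] = str(err)
            try:
                uni = surv_mod.cox_fit(holder["partition"], holder["clinical"], endpoint)
                entry["cox_univariable"] = dataclasses.asdict(uni.cox_univariable)
            except (surv_mod.CoxFitError, ValueError) as err:
                entry["cox_univariable_skipped"] = str(err)
            try:
                multi = surv_mod.cox_fit(
                    holder["partition"], holder["clinical"], endpoint,
                    covariates=config.covariates,
                )
                entry["cox_multivariable"] = [
                    dataclasses.asdict(c) for c in multi.cox_multivariable
                ]
            except (surv_mod.CoxFitError, ValueError) as err:
                entry["cox_multivariable_skipped"] = str(err)
            out[endpoint] = entry
        rows = []
        for endpoint, entry in out.items():
            if "cox_univariable" in entry:
                rows.append({"endpoint": endpoint, "model": "univariable",
                             **entry["cox_univariable"]})
            for c in entry.get("cox_multivariable", []):
                rows.append({"endpoint": endpoint, "model": "multivariable", **c})
        if rows:
            _write_tsv(pd.DataFrame(rows), outdir / "cox_summary.tsv", chash)
        return out

    @_stage("enrichment")
    def _enrichment():
        pca = holder["pca"]
        peaks = enrich_mod.select_component_peaks(
            pca, config.component_of_interest, config.pc_corr_threshold
        )
        genes = enrich_mod.peaks_to_genes(peaks, holder["pgmap"])
        if not genes:
            return {"skipped": "no genes mapped from component peaks", "n_peaks": len(peaks)}
        universe = holder["pgmap"].all_genes()
        results = enrich_mod.overlap_enrichment(genes, holder["gene_sets"], universe)
        _write_tsv(
            pd.DataFrame(
                {
                    "pathway": [r.set_name for r in results],
                    "fdr_q_value": [r.q_value for r in results],
                    "p_value": [r.p_value for r in results],
                    "overlap": [r.overlap_count for r in results],
                    "set_size": [r.set_size for r in results],
                    "genes": [",".join(r.overlap_genes) for r in results],
                }
            ),
            outdir / "enrichment.tsv", chash,
        )
        significant = [r.set_name for r in results if r.q_value < config.fdr_cutoff]
        return {
            "n_component_peaks": len(peaks),
            "n_query_genes": len(genes),
            "significant_sets": significant,
            "top_set": results[0].set_name if results else None,
        }

    if state_file.exists():
        state_file.unlink()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    logger.info("pipeline complete; artifacts in %s", outdir)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
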