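"""End-to-end pipeline orchestration.

Stages run in the fixed order ingest (or simulate) → per-arm matrix
construction → protein missingness filtering (with optional mask-and-score
cutoff calibration) → log2 normalization → imputation → optional per-sample
z-score standardization → peptide filtering and PTM ratio tables → paired
arm comparison, coverage, PCA and clustering.  Every intermediate matrix
and result is persisted, and a manifest records the seed, a config hash and
the per-stage feature counts (initial identified → retained after cleanup →
shared between arms).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ingest import build_quant_matrix, parse_diann_report, parse_maxquant_evidence
from .imputation import ImputerSpec, get_imputer
from .missingness import (
    MaskingExperiment,
    calibrate_cutoff,
    dataset_missingness,
    filter_peptides,
    filter_proteins,
)
from .ptm import build_ptm_table, class_summary
from .simulate import SimulationConfig, emit_search_report, simulate_bone_proteome
from .stats import (
    compare_groups,
    compare_ptm,
    hclust_order,
    log2_transform,
    pca_embed,
    proteome_coverage,
    zscore_per_sample,
)
from .types import BoneQuantError, QuantMatrix, read_design

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one input source: ``simulation`` (a SimulationConfig) or
    ``report``/``engine``/``design`` paths.  ``cutoff`` is a missingness
    fraction or the string ``"calibrate"``.
    """

    outdir: str = "bonequant_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    engine: str = "diann"
    report: str | None = None
    design: str | None = None
    cutoff: float | str = 0.4
    imputer: ImputerSpec = field(default_factory=ImputerSpec)
    calibration: MaskingExperiment = field(default_factory=MaskingExperiment)
    r_min: float = 0.7
    alpha: float = 0.05
    adjust_pvalues: bool = False
    standardize: bool = False  # per-sample z-scoring (cross-run comparisons)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            for key in ("peptides_per_protein", "groups", "occupancy_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "imputer" in raw:
            raw["imputer"] = ImputerSpec(**raw["imputer"])
        if "calibration" in raw:
            cal = raw["calibration"]
            if "masking_fractions" in cal:
                cal["masking_fractions"] = tuple(cal["masking_fractions"])
            raw["calibration"] = MaskingExperiment(**cal)
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = asdict(self)
        fields.pop("outdir", None)
        blob = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Series):
        return x.to_dict()
    return str(x)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and persists) the run manifest.

    Any stage error aborts the run with the stage name; the partial
    manifest written so far is persisted for post-mortem inspection.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "stages": [],
        "counts": {},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    stage = "setup"
    try:
        # ---- ingest -----------------------------------------------------
        stage = "ingest"
        if config.simulation is not None:
            sim = config.simulation
            sim.seed = config.seed
            truth = simulate_bone_proteome(sim)
            emitted = emit_search_report(truth, config.engine, os.path.join(config.outdir, "simulated"))
            report_path, design = emitted["report"], truth.design
        elif config.report and config.design:
            report_path, design = config.report, read_design(config.design)
        else:
            raise BoneQuantError("config needs either a simulation block or report+design paths")
        parser = parse_diann_report if config.engine == "diann" else parse_maxquant_evidence
        records = parser(report_path, design)
        manifest["stages"].append(stage)
        manifest["counts"]["precursor_records"] = len(records)

        groups = list(dict.fromkeys(design["group"]))
        if len(groups) != 2:
            raise BoneQuantError(f"expected exactly two arms, found {groups}")
        ga, gb = groups
        runs = {g: list(design.loc[design["group"] == g, "run_id"]) for g in groups}

        # ---- matrices ---------------------------------------------------
        stage = "build_matrices"
        prot_all = build_quant_matrix(records, "protein", design)
        mod_all = build_quant_matrix(records, "modified_sequence", design)
        arm = {}
        for g in groups:
            pm = prot_all.subset_samples(runs[g])
            pm = pm.subset_features(list(pm.values.index[~pm.values.isna().all(axis=1)]))
            mm = mod_all.subset_samples(runs[g])
            mm = mm.subset_features(list(mm.values.index[~mm.values.isna().all(axis=1)]))
            arm[g] = {"protein_raw": pm, "modseq_raw": mm}
            pm.to_tsv(os.path.join(config.outdir, f"protein_raw_{g}.tsv"))
            manifest["counts"][f"proteins_initial_{g}"] = pm.n_features
            manifest["counts"][f"missingness_pct_{g}"] = round(100 * dataset_missingness(pm), 2)
        manifest["stages"].append(stage)

        # ---- cutoff -----------------------------------------------------
        stage = "cutoff"
        if config.cutoff == "calibrate":
            log2_all = log2_transform(prot_all.subset_features(
                list(prot_all.values.index[~prot_all.values.isna().all(axis=1)])))
            calib = calibrate_cutoff(log2_all, config.calibration, r_min=config.r_min)
            cutoff = calib.selected_cutoff
            _write_json(os.path.join(config.outdir, "calibration.json"), calib.to_dict())
        else:
            cutoff = float(config.cutoff)
        manifest["counts"]["missingness_cutoff"] = cutoff
        manifest["stages"].append(stage)

        # ---- filter + normalize + impute --------------------------------
        stage = "filter_impute"
        imputer_fn = get_imputer(config.imputer.id)
        for g in groups:
            filtered = filter_proteins(arm[g]["protein_raw"], cutoff)
            manifest["counts"][f"proteins_retained_{g}"] = filtered.n_features
            logged = log2_transform(filtered)
            spec = ImputerSpec(**{**config.imputer.__dict__, "seed": config.seed})
            res = imputer_fn(logged, spec)
            final = zscore_per_sample(res.matrix) if config.standardize else res.matrix
            arm[g]["protein_final"] = final
            final.to_tsv(os.path.join(config.outdir, f"protein_processed_{g}.tsv"))
        manifest["stages"].append(stage)

        # ---- peptides and PTM ratios ------------------------------------
        stage = "ptm"
        ptm_tables = {}
        for g in groups:
            retained = filter_peptides(arm[g]["modseq_raw"], cutoff)
            manifest["counts"][f"peptides_retained_{g}"] = len(retained)
            table = build_ptm_table(arm[g]["modseq_raw"], retained)
            ptm_tables[g] = table
            table.to_tsv(os.path.join(config.outdir, f"ptm_ratios_{g}.tsv"))
        summaries = {
            g: class_summary(ptm_tables[g], design).to_dict(orient="records")
            for g in groups
            if len(ptm_tables[g].ratios)
        }
        _write_json(os.path.join(config.outdir, "ptm_summary.json"), summaries)
        manifest["counts"]["ptm_rows_shared"] = int(
            len(ptm_tables[ga].ratios.index.intersection(ptm_tables[gb].ratios.index))
        )
        manifest["stages"].append(stage)

        # ---- comparison --------------------------------------------------
        stage = "compare"
        report = compare_groups(
            arm[ga]["protein_final"], arm[gb]["protein_final"], design,
            ga, gb, alpha=config.alpha, adjust=config.adjust_pvalues,
        )
        report.per_feature.to_csv(os.path.join(config.outdir, "comparison_proteins.tsv"), sep="\t")
        manifest["counts"]["proteins_shared"] = report.summary["n_shared"]
        manifest["counts"]["proteins_significant"] = report.summary["n_significant"]
        manifest["counts"][f"higher_in_{ga}"] = report.summary["higher_in_a"]
        manifest["counts"][f"higher_in_{gb}"] = report.summary["higher_in_b"]

        ptm_cmp = None
        if len(ptm_tables[ga].ratios) and len(ptm_tables[gb].ratios):
            ptm_cmp = compare_ptm(ptm_tables[ga], ptm_tables[gb], design, ga, gb,
                                  alpha=config.alpha)
            ptm_cmp["per_peptide"].to_csv(
                os.path.join(config.outdir, "comparison_ptm.tsv"), sep="\t", index=False)
        cov = proteome_coverage(arm[ga]["protein_raw"], arm[gb]["protein_raw"],
                                design, ga, gb)
        manifest["counts"]["coverage_p"] = cov["p"]
        manifest["stages"].append(stage)

        # ---- multivariate -----------------------------------------------
        stage = "multivariate"
        shared = report.per_feature.index
        combined = pd.concat(
            [arm[ga]["protein_final"].values.loc[shared],
             arm[gb]["protein_final"].values.loc[shared]], axis=1)
        combined_qm = QuantMatrix(values=combined, level="protein",
                                  scale=arm[ga]["protein_final"].scale)
        pca = pca_embed(combined_qm)
        pca.scores.to_csv(os.path.join(config.outdir, "pca_scores.tsv"), sep="\t")
        manifest["counts"]["pca_var_pc1_pc2_pct"] = round(pca.top2_pct(), 2)
        f_order, s_order = hclust_order(combined_qm)
        _write_json(os.path.join(config.outdir, "hclust_orders.json"),
                    {"features": f_order, "samples": s_order})
        manifest["stages"].append(stage)

        manifest["summary"] = report.summary
        if ptm_cmp is not None:
            manifest["ptm_class_tests"] = ptm_cmp["class_tests"]
        manifest["status"] = "complete"
        _write_json(manifest_path, manifest)
        return manifest
    except Exception as err:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write_json(manifest_path, manifest)
        logger.error("pipeline failed at stage %s: %s", stage, err)
        raise
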