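"""Configurable end-to-end pipeline: simulate -> QC -> LoQ/SNR -> detect ->
filter -> concordance or differential expression.

A run is described by one strictly validated YAML config (unknown keys are
rejected by name); every defaulted parameter is echoed into the run manifest
so each analysis choice is auditable. All outputs are plain TSV/JSON with
fixed float formatting and no timestamps, so rerunning the same config and
seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, StrictInt, ValidationError

from . import __version__
from .datamodel import (
    CountMatrix,
    QcThresholds,
    SpgError,
    qc_filter_aois,
    write_dataset,
    write_matrix,
    write_qc_report,
)
from .diffexp import (
    combined_volcano_table,
    mixed_model_de,
    significant_targets,
    ttest_de,
)
from .filtering import average_replicates, filter_genes, filter_segments
from .concordance import (
    detection_metrics,
    max_r_match,
    pairwise_correlation,
    sensitivity_slope,
)
from .normalize import compute_loq, detect, shift_counts, snr_normalize
from .simulate import GeneratorConfig, TissueConfig, simulate_cpa, simulate_tissue

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class QcBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_raw_reads: float = 1000.0
    min_saturation: float = 0.50
    min_area: float = 1600.0


class LoqBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sd: float = 2.0
    floor: float = 2.0


class SnrThresholds(BaseModel):
    """Inclusive detection thresholds on SNR (protein >= 3, RNA >= 4)."""

    model_config = ConfigDict(extra="forbid")
    protein: float = 3.0
    rna: float = 4.0


class FilterBlock(BaseModel):
    """profile "general": keep genes above LoQ in >15% of AOIs;
    profile "gbm": drop genes below LoQ in >=10% of AOIs."""

    model_config = ConfigDict(extra="forbid")
    profile: Literal["general", "gbm"] = "general"
    min_gene_fraction: float = 0.05
    include_above_fraction: float = 0.15
    exclude_below_fraction: float = 0.10


class DeBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["ttest", "mixed"] = "mixed"
    group_by: str = "segment_label"
    grouping: str = "tissue_id"
    fdr_cut: float = 0.001
    fc_cut: float = 2.0


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["cpa", "tissue"] = "cpa"
    cpa: GeneratorConfig = Field(default_factory=GeneratorConfig)
    tissue: TissueConfig = Field(default_factory=TissueConfig)


class PipelineConfig(BaseModel):
    """Strict schema for one pipeline run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: StrictInt = 0
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    qc: QcBlock = Field(default_factory=QcBlock)
    loq: LoqBlock = Field(default_factory=LoqBlock)
    snr_thresholds: SnrThresholds = Field(default_factory=SnrThresholds)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    de: DeBlock = Field(default_factory=DeBlock)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(raw)
        except ValidationError as err:
            bad = [
                ".".join(str(x) for x in e["loc"])
                for e in err.errors()
                if e["type"] == "extra_forbidden"
            ]
            if bad:
                raise SpgError(f"unknown config key(s): {bad}") from err
            raise


def _stage(manifest: dict, name: str, matrix) -> None:
    manifest["stages"].append(
        {"name": name, "n_targets": int(matrix.n_targets), "n_aois": int(matrix.n_aois)}
    )
    logger.info("stage %-12s %5d targets x %4d AOIs", name, matrix.n_targets, matrix.n_aois)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured pipeline and write all artifacts to outdir.

    Returns the run manifest (also written as manifest.json). On stage
    failure a FAILED marker naming the stage is left next to any partial
    artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "stages": [],
    }
    stage_name = "start"
    try:
        if config.simulate.kind == "cpa":
            stage_name = "simulate"
            _run_cpa(config, outdir, manifest)
        else:
            stage_name = "simulate"
            _run_tissue(config, outdir, manifest)
    except Exception as err:
        failed = [s["name"] for s in manifest["stages"]]
        stage = stage_name if not failed else failed[-1]
        (outdir / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise SpgError(f"pipeline aborted at stage {stage!r}: {err}") from err
    _write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# CPA route: simulate -> qc -> shift -> loq -> snr -> detect -> filter
#            -> concordance metrics against the manifest truth
# ---------------------------------------------------------------------------


def _normalize_chain(
    matrix: CountMatrix, config: PipelineConfig, manifest: dict, label: str, outdir: Path
):
    """qc -> shift -> loq -> snr(+detect) for one condition matrix."""
    qc = QcThresholds(
        min_raw_reads=config.qc.min_raw_reads,
        min_saturation=config.qc.min_saturation,
        min_area=config.qc.min_area,
    )
    matrix, report = qc_filter_aois(matrix, qc)
    write_qc_report(report, outdir / f"{label}_qc_report.json")
    _stage(manifest, f"qc[{label}]", matrix)
    shifted = shift_counts(matrix)
    _stage(manifest, f"shift[{label}]", shifted)

    out = {"counts": shifted}
    if "rna" in shifted.analytes():
        loq = compute_loq(shifted, n_sd=config.loq.n_sd, floor=config.loq.floor)
        loq.loq.to_csv(outdir / f"{label}_loq.tsv", sep="\t", header=["loq"], float_format=FLOAT_FMT)
        out["loq"] = loq
        _stage(manifest, f"loq[{label}]", shifted)
    for analyte in shifted.analytes():
        snr = snr_normalize(shifted, analyte)
        write_matrix(snr, outdir / f"{label}_snr_{analyte}.tsv")
        out[f"snr_{analyte}"] = snr
        _stage(manifest, f"snr[{label}:{analyte}]", snr)
        thr = getattr(config.snr_thresholds, analyte)
        out[f"det_{analyte}"] = detect(snr, "snr_threshold", threshold=thr)
        _stage(manifest, f"detect[{label}:{analyte}]", snr)
    return out


def _apply_rna_filters(chain, config: PipelineConfig, manifest: dict):
    """Segment filter then gene filter on the RNA analyte of one condition."""
    counts, loq = chain["counts"], chain["loq"]
    endo = counts.endogenous_targets("rna")
    det_loq = detect(counts, "above_loq", loq=loq).subset_targets(list(endo))
    kept_aois, seg_report = filter_segments(det_loq, config.filter.min_gene_fraction)
    det_surv = det_loq.subset_aois(kept_aois)
    if config.filter.profile == "general":
        kept_genes, gene_report = filter_genes(
            det_surv, "include_above", config.filter.include_above_fraction
        )
    else:
        kept_genes, gene_report = filter_genes(
            det_surv, "exclude_below", config.filter.exclude_below_fraction
        )
    snr = chain["snr_rna"].subset_aois(kept_aois)
    keep = list(kept_genes) + list(counts.control_targets("rna"))
    snr = snr.subset_targets(keep)
    _stage(manifest, "filter[rna]", snr)
    return snr, seg_report, gene_report


def _run_cpa(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    gen = config.simulate.cpa.model_copy(update={"seed": config.seed})
    ctrl_rna, ctrl_prot, spg, truth = simulate_cpa(gen)
    for label, m in (("ctrl_rna", ctrl_rna), ("ctrl_protein", ctrl_prot), ("spg", spg)):
        write_dataset(m, outdir, prefix=f"{label}_")
    truth.save(outdir / "truth_manifest.json")
    _stage(manifest, "simulate", spg)

    chains = {
        "ctrl_rna": _normalize_chain(ctrl_rna, config, manifest, "ctrl_rna", outdir),
        "ctrl_protein": _normalize_chain(ctrl_prot, config, manifest, "ctrl_protein", outdir),
        "spg": _normalize_chain(spg, config, manifest, "spg", outdir),
    }
    snr_rna_spg, seg_rep, gene_rep = _apply_rna_filters(chains["spg"], config, manifest)
    _write_json(
        {"segment": seg_rep.to_dict(), "gene": gene_rep.to_dict()},
        outdir / "filter_report.json",
    )

    # replicate averaging: one profile per cell line per condition
    def averaged(chain, analyte):
        snr = chain[f"snr_{analyte}"]
        grouping = snr.aois["tissue_id"].to_dict()
        return average_replicates(snr, grouping, method="geometric")

    metrics: dict = {}
    # protein concordance + identity matching (mask: detected in reference)
    ref_p = averaged(chains["ctrl_protein"], "protein")
    test_p = averaged(chains["spg"], "protein")
    mask = detect(ref_p, "snr_threshold", threshold=config.snr_thresholds.protein)
    corr = pairwise_correlation(test_p, ref_p, unit_kind="cell_line", detection_mask=mask)
    corr.r.to_csv(outdir / "correlation_protein.tsv", sep="\t", float_format=FLOAT_FMT)
    identity = {u: u for u in corr.r.index}
    _, accuracy, ties = max_r_match(corr, identity)
    metrics["max_r_match_accuracy_protein"] = accuracy
    metrics["max_r_ties"] = len(ties)
    metrics["mean_matched_r_protein"] = float(np.nanmean(np.diag(corr.r.to_numpy())))

    # sensitivity slopes per analyte
    ref_r = averaged(chains["ctrl_rna"], "rna")
    test_r = averaged(chains["spg"], "rna")
    sens_p = sensitivity_slope(test_p.endogenous(), ref_p.endogenous())
    sens_r = sensitivity_slope(test_r.endogenous(), ref_r.endogenous())
    metrics["sensitivity_percent_change_protein"] = sens_p.percent_change
    metrics["sensitivity_percent_change_rna"] = sens_r.percent_change

    # detection TPR/FPR per cell line against the truth set (averaged RNA SNR)
    det_rna = detect(
        test_r.endogenous(), "snr_threshold", threshold=config.snr_thresholds.rna
    )
    tprs, fprs = [], []
    assessed = set(det_rna.values.index)
    for line in det_rna.values.columns:
        col = det_rna.values[line]
        dm = detection_metrics(
            set(col.index[col]), truth.truth_set, line, assessed
        )
        tprs.append(dm.tpr)
        fprs.append(dm.fpr)
    metrics["mean_tpr_rna"] = float(np.mean(tprs))
    metrics["mean_fpr_rna"] = float(np.mean(fprs))
    _write_json(metrics, outdir / "metrics.json")
    _stage(manifest, "concordance", test_p)


# ---------------------------------------------------------------------------
# Tissue route: simulate -> qc -> shift -> loq -> snr -> detect -> filter -> DE
# ---------------------------------------------------------------------------


def _run_tissue(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    tis = config.simulate.tissue.model_copy(update={"seed": config.seed})
    base = config.simulate.cpa.model_copy(update={"seed": config.seed})
    spg, _, truth = simulate_tissue(tis, base)
    write_dataset(spg, outdir, prefix="spg_")
    truth.save(outdir / "truth_manifest.json")
    _stage(manifest, "simulate", spg)

    chain = _normalize_chain(spg, config, manifest, "spg", outdir)
    snr_rna, seg_rep, gene_rep = _apply_rna_filters(chain, config, manifest)
    _write_json(
        {"segment": seg_rep.to_dict(), "gene": gene_rep.to_dict()},
        outdir / "filter_report.json",
    )
    snr_prot = chain["snr_protein"].subset_aois(list(snr_rna.values.columns))

    segs = sorted(set(spg.aois["segment_label"]))
    contrast = (segs[1], segs[0])
    tables = []
    for snr in (snr_rna.endogenous(), snr_prot.endogenous()):
        if config.de.method == "mixed":
            de = mixed_model_de(
                snr, config.de.group_by, config.de.grouping, contrast=contrast
            )
        else:
            groups = {
                a: 1 if spg.aois.loc[a, config.de.group_by] == contrast[0] else 2
                for a in snr.values.columns
            }
            de = ttest_de(snr, groups)
        tables.append(de)
    de_rna, de_prot = tables
    volcano = combined_volcano_table(de_rna, de_prot)
    volcano.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    _stage(manifest, "de", snr_rna)

    sig = significant_targets(volcano, config.de.fdr_cut, config.de.fc_cut)
    sig_by_analyte = volcano.set_index("target_id").loc[sig, "analyte"] if sig else pd.Series(dtype=object)
    metrics = {
        "contrast": list(contrast),
        "n_significant_rna": int((sig_by_analyte == "rna").sum()),
        "n_significant_protein": int((sig_by_analyte == "protein").sum()),
        "fdr_cut": config.de.fdr_cut,
        "fc_cut": config.de.fc_cut,
    }
    _write_json(metrics, outdir / "metrics.json")
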