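"""Synthetic dual-analyte count data with a complete planted-truth manifest.

Two study designs are emulated:

* cell-pellet arrays (:func:`simulate_cpa`) — homogeneous FFPE cell lines
  profiled with replicate AOIs under three conditions: a single-analyte RNA
  control, a single-analyte protein control, and the dual-analyte condition
  whose sensitivity is attenuated by a known multiplicative factor per
  analyte. A TPM-like reference expression matrix (the truth set, expressed
  defined as reference > 1) drives the counts.
* segmented tissue (:func:`simulate_tissue`) — tissues sampled by several
  ROIs, each split into marker-defined segments (immune vs tumor/astrocyte),
  with planted log2 fold changes on a subset of targets and a per-tissue
  random intercept on the log2 scale, matching the repeated-sampling design a
  mixed model is meant to absorb.

Counts are negative binomial (mean/size parameterization): the platform
publishes no generative law, and the NB is the standard
overdispersed model for probe counts. The mean of an endogenous target is
``background_mean + capture_scale * attenuation * reference``; control probes
(negative ISH probes, IgG isotype controls) have mean ``background_mean``
independent of expression.

Randomness comes from one master seed; independent sub-streams are derived
per component through fixed ``spawn_key`` offsets of numpy's SeedSequence, so
identical configs reproduce identical datasets bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, StrictInt

from .datamodel import CountMatrix


class GeneratorConfig(BaseModel):
    """Cell-pellet-array generator settings (defaults are the study design:
    45 cell lines, 2 replicate AOIs each, three IgG controls, and the
    observed dual-analyte sensitivity attenuations of 15% for RNA and 11%
    for protein)."""

    model_config = ConfigDict(extra="forbid")

    n_cell_lines: int = Field(45, ge=1)
    n_genes: int = Field(500, ge=1)
    n_negprobes: int = Field(30, ge=2)
    n_proteins: int = Field(56, ge=1)
    n_igg: int = Field(3, ge=1)
    tpm_lognormal_mu: float = 2.0
    tpm_lognormal_sigma: float = Field(1.5, gt=0)
    expressed_fraction: float = Field(0.5, ge=0.0, le=1.0)
    background_mean: float = Field(10.0, ge=0.0)
    dispersion: float = Field(8.0, gt=0)
    capture_scale: float = Field(5.0, gt=0)
    attenuation_rna: float = Field(0.85, gt=0.0, le=1.0)
    attenuation_protein: float = Field(0.89, gt=0.0, le=1.0)
    replicates_per_line: int = Field(2, ge=1)
    seed: StrictInt = 0


class TissueConfig(BaseModel):
    """Segmented-tissue generator settings (defaults: 6 tissues, 4 ROIs per
    tissue split into immune CD45 and tumor/astrocyte GFAP segments, 20% of
    targets carrying planted effects)."""

    model_config = ConfigDict(extra="forbid")

    n_tissues: int = Field(6, ge=2)
    rois_per_tissue: int = Field(4, ge=1)
    segments: tuple[str, ...] = ("CD45", "GFAP")
    de_fraction: float = Field(0.2, ge=0.0, le=1.0)
    de_log2fc_mean: float = 1.0
    de_log2fc_sd: float = Field(0.5, ge=0.0)
    tissue_re_sd: float = Field(0.3, ge=0.0)
    cells_per_aoi: int = Field(100, ge=1)
    seed: StrictInt = 0


@dataclass
class TruthSet:
    """Reference expression per (cell line, gene) on a TPM-like scale.

    ``expressed`` is exactly the > 1 thresholding of ``reference_expression``.
    """

    reference_expression: pd.DataFrame  # cell line x gene

    @property
    def expressed(self) -> pd.DataFrame:
        return self.reference_expression.gt(1.0)

    def expressed_genes(self, cell_line: str) -> set[str]:
        row = self.expressed.loc[cell_line]
        return set(row.index[row])


@dataclass
class SyntheticTruth:
    """Generator manifest: everything planted, sufficient to regenerate the
    dataset bit-for-bit from the echoed config and seed."""

    truth_set: TruthSet
    protein_reference: pd.DataFrame | None
    attenuation_rna: float
    attenuation_protein: float
    de_effects: dict[str, float]
    tissue_effects: dict[str, dict[str, float]]
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "reference_expression": {
                "index": list(self.truth_set.reference_expression.index),
                "columns": list(self.truth_set.reference_expression.columns),
                "values": self.truth_set.reference_expression.to_numpy().tolist(),
            },
            "protein_reference": None
            if self.protein_reference is None
            else {
                "index": list(self.protein_reference.index),
                "columns": list(self.protein_reference.columns),
                "values": self.protein_reference.to_numpy().tolist(),
            },
            "attenuation_rna": self.attenuation_rna,
            "attenuation_protein": self.attenuation_protein,
            "de_effects": self.de_effects,
            "tissue_effects": self.tissue_effects,
            "config": self.config,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        ref = pd.DataFrame(
            d["reference_expression"]["values"],
            index=d["reference_expression"]["index"],
            columns=d["reference_expression"]["columns"],
        )
        prot = None
        if d["protein_reference"] is not None:
            prot = pd.DataFrame(
                d["protein_reference"]["values"],
                index=d["protein_reference"]["index"],
                columns=d["protein_reference"]["columns"],
            )
        return cls(
            truth_set=TruthSet(ref),
            protein_reference=prot,
            attenuation_rna=d["attenuation_rna"],
            attenuation_protein=d["attenuation_protein"],
            de_effects=d["de_effects"],
            tissue_effects=d["tissue_effects"],
            config=d["config"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------

_STREAMS = {
    "reference_rna": 0,
    "reference_protein": 1,
    "counts_control_rna": 2,
    "counts_control_protein": 3,
    "counts_spg": 4,
    "aoi_meta": 5,
    "tissue_baseline": 10,
    "tissue_de": 11,
    "tissue_re": 12,
    "tissue_counts": 13,
    "tissue_meta": 14,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Sub-stream generator: master seed + fixed per-component spawn key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with mean `mean` and size (dispersion) `size_param`."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=mean.shape).astype(float)


def _reference_matrix(
    rng: np.random.Generator,
    units: list[str],
    targets: list[str],
    cfg: GeneratorConfig,
) -> pd.DataFrame:
    """TPM-like reference: lognormal shifted above 1 for the expressed
    fraction, a point mass at 0.1 for the rest, so the > 1 rule partitions
    cleanly."""
    shape = (len(units), len(targets))
    expressed = rng.random(shape) < cfg.expressed_fraction
    vals = np.full(shape, 0.1)
    vals[expressed] = 1.0 + rng.lognormal(
        cfg.tpm_lognormal_mu, cfg.tpm_lognormal_sigma, size=int(expressed.sum())
    )
    return pd.DataFrame(vals, index=units, columns=targets)


def _panel(cfg: GeneratorConfig, rna: bool = True, protein: bool = True) -> pd.DataFrame:
    rows = []
    if rna:
        rows += [
            (f"GENE{i:04d}", "rna", "endogenous", f"GENE{i:04d}", "WTA")
            for i in range(1, cfg.n_genes + 1)
        ]
        rows += [
            (f"NegProbe{i:02d}", "rna", "negative", f"NegProbe{i:02d}", "WTA")
            for i in range(1, cfg.n_negprobes + 1)
        ]
    if protein:
        rows += [
            (f"PROT{i:03d}", "protein", "endogenous", f"PROT{i:03d}", "ProteinPanel")
            for i in range(1, cfg.n_proteins + 1)
        ]
        igg_names = ["IgG1_mouse", "IgG2a_mouse", "IgG_rabbit"]
        rows += [
            (
                igg_names[i] if i < 3 else f"IgG_extra{i - 2}",
                "protein",
                "igg_control",
                "IgG",
                "ProteinPanel",
            )
            for i in range(cfg.n_igg)
        ]
    df = pd.DataFrame(rows, columns=["target_id", "analyte", "probe_class", "symbol", "panel"])
    return df.set_index("target_id")


def _cpa_aois(cfg: GeneratorConfig, condition: str, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    diameter = 200.0
    area = round(math.pi * (diameter / 2.0) ** 2, 2)
    for li in range(1, cfg.n_cell_lines + 1):
        line = f"CL{li:02d}"
        for r in range(1, cfg.replicates_per_line + 1):
            rows.append(
                {
                    "aoi_id": f"{line}_rep{r}_{condition}",
                    "roi_id": f"{line}_roi{r}",
                    "slide_id": f"slide_{condition}",
                    "tissue_id": line,
                    "segment_label": "geometric",
                    "roi_diameter": diameter,
                    "area": area,
                    "raw_reads": 0.0,  # filled from the drawn counts
                    "sequencing_saturation": round(float(rng.uniform(0.7, 0.95)), 4),
                }
            )
    return pd.DataFrame(rows).set_index("aoi_id")


def _expand_means(
    ref: pd.DataFrame, targets: list[str], aois: pd.DataFrame, signal_scale: float,
    background: float,
) -> np.ndarray:
    """Per-(target, AOI) NB means for endogenous targets, replicating the
    per-line reference across that line's replicate AOIs."""
    lines = aois["tissue_id"].to_numpy()
    per_line = background + signal_scale * ref[targets].to_numpy()  # line x target
    line_index = {line: i for i, line in enumerate(ref.index)}
    rows = np.array([line_index[x] for x in lines])
    return per_line[rows].T  # target x AOI


def _assemble(
    counts: np.ndarray, targets: pd.DataFrame, aois: pd.DataFrame
) -> CountMatrix:
    aois = aois.copy()
    aois["raw_reads"] = counts.sum(axis=0)
    values = pd.DataFrame(counts, index=targets.index, columns=aois.index)
    return CountMatrix(values, targets, aois)


def simulate_cpa(
    config: GeneratorConfig,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, SyntheticTruth]:
    """Simulate the paired cell-pellet-array experiment.

    Returns (control_rna, control_protein, spg, truth). The two control
    matrices are single-analyte (attenuation 1); the dual-analyte matrix
    carries both analytes' targets with their configured attenuations.
    """
    cfg = config
    if cfg.expressed_fraction == 0 and cfg.background_mean == 0:
        import warnings

        warnings.warn("degenerate config: no expression and no background")
    lines = [f"CL{i:02d}" for i in range(1, cfg.n_cell_lines + 1)]
    gene_ids = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    prot_ids = [f"PROT{i:03d}" for i in range(1, cfg.n_proteins + 1)]

    rna_ref = _reference_matrix(_rng(cfg.seed, "reference_rna"), lines, gene_ids, cfg)
    prot_ref = _reference_matrix(
        _rng(cfg.seed, "reference_protein"), lines, prot_ids, cfg
    )

    meta_rng = _rng(cfg.seed, "aoi_meta")
    panels = {
        "ctrl_rna": _panel(cfg, rna=True, protein=False),
        "ctrl_protein": _panel(cfg, rna=False, protein=True),
        "spg": _panel(cfg, rna=True, protein=True),
    }
    aois = {k: _cpa_aois(cfg, k, meta_rng) for k in panels}

    def means_for(panel: pd.DataFrame, aoi: pd.DataFrame, att_rna: float, att_prot: float) -> np.ndarray:
        m = np.empty((len(panel), len(aoi)))
        for i, (tid, row) in enumerate(panel.iterrows()):
            if row["probe_class"] != "endogenous":
                m[i] = cfg.background_mean
        endo_rna = [t for t in panel.index if panel.loc[t, "probe_class"] == "endogenous" and panel.loc[t, "analyte"] == "rna"]
        endo_prot = [t for t in panel.index if panel.loc[t, "probe_class"] == "endogenous" and panel.loc[t, "analyte"] == "protein"]
        pos = {t: i for i, t in enumerate(panel.index)}
        if endo_rna:
            block = _expand_means(rna_ref, endo_rna, aoi, cfg.capture_scale * att_rna, cfg.background_mean)
            m[[pos[t] for t in endo_rna]] = block
        if endo_prot:
            block = _expand_means(prot_ref, endo_prot, aoi, cfg.capture_scale * att_prot, cfg.background_mean)
            m[[pos[t] for t in endo_prot]] = block
        return m

    out = {}
    draws = {
        "ctrl_rna": ("counts_control_rna", 1.0, 1.0),
        "ctrl_protein": ("counts_control_protein", 1.0, 1.0),
        "spg": ("counts_spg", cfg.attenuation_rna, cfg.attenuation_protein),
    }
    for cond, (stream, a_rna, a_prot) in draws.items():
        m = means_for(panels[cond], aois[cond], a_rna, a_prot)
        counts = _nb_draw(_rng(cfg.seed, stream), m, cfg.dispersion)
        out[cond] = _assemble(counts, panels[cond], aois[cond])

    truth = SyntheticTruth(
        truth_set=TruthSet(rna_ref),
        protein_reference=prot_ref,
        attenuation_rna=cfg.attenuation_rna,
        attenuation_protein=cfg.attenuation_protein,
        de_effects={},
        tissue_effects={},
        config=cfg.model_dump(),
        seed=cfg.seed,
    )
    return out["ctrl_rna"], out["ctrl_protein"], out["spg"], truth


def simulate_tissue(
    config: TissueConfig, base: GeneratorConfig
) -> tuple[CountMatrix, CountMatrix | None, SyntheticTruth]:
    """Simulate a segmented-tissue dual-analyte study.

    Per-target log2 signal = baseline + segment effect (planted log2FC for DE
    targets on the second segment label, 0 otherwise) + per-(tissue, target)
    random intercept ~ Normal(0, tissue_re_sd^2). Counts are negative
    binomial; AOI annotation carries tissue_id / roi_id / segment_label so the
    mixed model's grouping factors are available.

    Returns (spg, None, truth); the second slot keeps the CPA return shape.
    """
    if len(config.segments) < 2:
        raise ValueError("need >= 2 segment labels (differential expression undefined)")
    cfg, base_cfg = config, base

    panel = _panel(base_cfg, rna=True, protein=True)
    endo = [t for t in panel.index if panel.loc[t, "probe_class"] == "endogenous"]

    # one TPM-like baseline vector across all endogenous targets
    base_rng = _rng(cfg.seed, "tissue_baseline")
    baseline = _reference_matrix(base_rng, ["baseline"], endo, base_cfg)

    de_rng = _rng(cfg.seed, "tissue_de")
    n_de = int(round(cfg.de_fraction * len(endo)))
    de_targets = sorted(de_rng.choice(endo, size=n_de, replace=False).tolist())
    effects = de_rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, size=n_de)
    de_effects = {t: 0.0 for t in endo}
    for t, e in zip(de_targets, effects):
        de_effects[t] = float(e)

    tissues = [f"T{i:02d}" for i in range(1, cfg.n_tissues + 1)]
    re_rng = _rng(cfg.seed, "tissue_re")
    u = re_rng.normal(0.0, cfg.tissue_re_sd, size=(len(tissues), len(endo)))
    tissue_effects = {
        tis: {t: float(u[i, j]) for j, t in enumerate(endo)}
        for i, tis in enumerate(tissues)
    }

    meta_rng = _rng(cfg.seed, "tissue_meta")
    diameter = 300.0
    area = round(math.pi * (diameter / 2.0) ** 2 / len(cfg.segments), 2)
    rows = []
    for tis in tissues:
        for r in range(1, cfg.rois_per_tissue + 1):
            for seg in cfg.segments:
                rows.append(
                    {
                        "aoi_id": f"{tis}_R{r}_{seg}",
                        "roi_id": f"{tis}_R{r}",
                        "slide_id": "slide_spg",
                        "tissue_id": tis,
                        "segment_label": seg,
                        "roi_diameter": diameter,
                        "area": area,
                        "raw_reads": 0.0,
                        "sequencing_saturation": round(float(meta_rng.uniform(0.7, 0.95)), 4),
                    }
                )
    aois = pd.DataFrame(rows).set_index("aoi_id")

    # log2 signal per (endogenous target, AOI)
    att = {
        "rna": base_cfg.attenuation_rna,
        "protein": base_cfg.attenuation_protein,
    }
    cell_scale = cfg.cells_per_aoi / 100.0  # reference ROI carries ~100 cells
    tissue_index = {t: i for i, t in enumerate(tissues)}
    endo_pos = {t: j for j, t in enumerate(endo)}
    log2_base = np.log2(
        base_cfg.capture_scale
        * cell_scale
        * np.array([att[panel.loc[t, "analyte"]] for t in endo])
        * baseline.loc["baseline", endo].to_numpy()
    )
    seg_eff = np.array([de_effects[t] for t in endo])

    mean = np.empty((len(panel), len(aois)))
    pos = {t: i for i, t in enumerate(panel.index)}
    for j, (aoi_id, arow) in enumerate(aois.iterrows()):
        ti = tissue_index[arow["tissue_id"]]
        is_second = arow["segment_label"] == cfg.segments[1]
        log2_sig = log2_base + u[ti] + (seg_eff if is_second else 0.0)
        col = np.full(len(panel), base_cfg.background_mean)
        col[[pos[t] for t in endo]] = base_cfg.background_mean + 2.0**log2_sig
        mean[:, j] = col

    counts = _nb_draw(_rng(cfg.seed, "tissue_counts"), mean, base_cfg.dispersion)
    spg = _assemble(counts, panel, aois)

    truth = SyntheticTruth(
        truth_set=TruthSet(baseline),
        protein_reference=None,
        attenuation_rna=base_cfg.attenuation_rna,
        attenuation_protein=base_cfg.attenuation_protein,
        de_effects=de_effects,
        tissue_effects=tissue_effects,
        config={"tissue": cfg.model_dump(), "base": base_cfg.model_dump()},
        seed=cfg.seed,
    )
    return spg, None, truth


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

#: tabulated (diameter in um, approximate cells captured)
_ROI_CELL_ANCHORS = [(50.0, 15.0), (100.0, 100.0), (200.0, 100.0), (250.0, 250.0), (400.0, 480.0)]


def roi_cells(diameter: float) -> float:
    """Approximate cells captured by a circular ROI of the given diameter.

    Exact at the tabulated anchors (50 um -> 15 cells, 100-200 um -> 100,
    250 -> 250, 400 -> 480); linear interpolation between anchors.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    xs = np.array([a[0] for a in _ROI_CELL_ANCHORS])
    ys = np.array([a[1] for a in _ROI_CELL_ANCHORS])
    if diameter < xs[0] or diameter > xs[-1]:
        raise ValueError(f"diameter {diameter} outside tabulated range [50, 400] um")
    return float(np.interp(diameter, xs, ys))
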