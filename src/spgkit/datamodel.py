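"""Core data model and tabular I/O for barcode-count spatial profiling data.

The sample unit is the AOI (area of interest): the illuminated sub-region of
an ROI from which barcodes are collected. A :class:`CountMatrix` holds raw
target x AOI counts together with two annotation tables — one describing the
targets (analyte, probe class, panel) and one describing the AOIs (ROI/slide/
tissue identifiers, segment label, geometry, sequencing QC fields).

Each analyte carries its own control probe class: RNA panels include negative
ISH probes ("NegProbe"), protein panels include IgG isotype controls. Those
control classes drive every downstream background statistic (LoQ, SNR).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANALYTES = ("rna", "protein")
PROBE_CLASSES = ("endogenous", "negative", "igg_control")

#: control probe class used as the background estimator, per analyte
CONTROL_CLASS = {"rna": "negative", "protein": "igg_control"}

TARGET_COLUMNS = ("target_id", "analyte", "probe_class", "symbol", "panel")
AOI_COLUMNS = (
    "aoi_id",
    "roi_id",
    "slide_id",
    "tissue_id",
    "segment_label",
    "roi_diameter",
    "area",
    "raw_reads",
    "sequencing_saturation",
)
#: AOI columns that are required structurally; QC fields may be absent
AOI_REQUIRED = ("aoi_id", "roi_id", "slide_id", "tissue_id", "segment_label")


class SpgError(Exception):
    """Base class for data-model errors."""


class FormatError(SpgError):
    """A file or table does not have the expected columns/layout."""


class ConsistencyError(SpgError):
    """Counts and annotation tables disagree about targets or AOIs."""


@dataclass(frozen=True)
class QcThresholds:
    """Sequencing-level AOI QC cut-offs.

    An AOI passes a criterion if its metric is >= the threshold; "low"
    AOIs (strictly below) are removed. The underlying criteria (reads,
    saturation, area) are fixed; the numeric values are configurable.
    """

    min_raw_reads: float = 1000.0
    min_saturation: float = 0.50
    min_area: float = 1600.0

    def __post_init__(self) -> None:
        for name in ("min_raw_reads", "min_saturation", "min_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CountMatrix:
    """Raw target x AOI counts plus the two annotation tables.

    ``values`` is indexed by target_id (rows) and aoi_id (columns);
    ``targets`` and ``aois`` are indexed by target_id / aoi_id and hold the
    annotation fields. Construction validates the invariants.
    """

    values: pd.DataFrame
    targets: pd.DataFrame
    aois: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if list(self.values.index) != list(self.targets.index):
            miss_v = [t for t in self.values.index if t not in set(self.targets.index)]
            miss_a = [t for t in self.targets.index if t not in set(self.values.index)]
            raise ConsistencyError(
                f"target index mismatch; in counts only: {miss_v}; "
                f"in annotation only: {miss_a}"
            )
        if list(self.values.columns) != list(self.aois.index):
            miss_v = [a for a in self.values.columns if a not in set(self.aois.index)]
            miss_a = [a for a in self.aois.index if a not in set(self.values.columns)]
            raise ConsistencyError(
                f"AOI index mismatch; in counts only: {miss_v}; "
                f"in annotation only: {miss_a}"
            )
        if self.targets.index.has_duplicates:
            raise ConsistencyError("duplicated target_id in target annotation")
        if self.aois.index.has_duplicates:
            raise ConsistencyError("duplicated aoi_id in AOI annotation")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                "negative count at "
                f"({self.values.index[r]}, {self.values.columns[c]})"
            )
        bad_analyte = set(self.targets["analyte"]) - set(ANALYTES)
        if bad_analyte:
            raise FormatError(f"unknown analyte value(s): {sorted(bad_analyte)}")
        bad_class = set(self.targets["probe_class"]) - set(PROBE_CLASSES)
        if bad_class:
            raise FormatError(f"unknown probe_class value(s): {sorted(bad_class)}")
        igg = self.targets["probe_class"] == "igg_control"
        if (self.targets.loc[igg, "analyte"] != "protein").any():
            raise ConsistencyError("igg_control targets must have analyte=protein")
        neg = self.targets["probe_class"] == "negative"
        if (self.targets.loc[neg, "analyte"] != "rna").any():
            raise ConsistencyError("negative targets must have analyte=rna")
        for analyte in self.analytes():
            if self.control_targets(analyte).empty:
                raise ConsistencyError(
                    f"analyte {analyte!r} present without any "
                    f"{CONTROL_CLASS[analyte]} control targets"
                )

    # -- accessors -------------------------------------------------------

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_aois(self) -> int:
        return self.values.shape[1]

    def analytes(self) -> list[str]:
        present = set(self.targets["analyte"])
        return [a for a in ANALYTES if a in present]

    def control_targets(self, analyte: str) -> pd.Index:
        """target_ids of the control probe class for ``analyte``."""
        cls = CONTROL_CLASS[analyte]
        mask = (self.targets["analyte"] == analyte) & (
            self.targets["probe_class"] == cls
        )
        return self.targets.index[mask]

    def endogenous_targets(self, analyte: str | None = None) -> pd.Index:
        mask = self.targets["probe_class"] == "endogenous"
        if analyte is not None:
            mask &= self.targets["analyte"] == analyte
        return self.targets.index[mask]

    def subset_targets(self, target_ids: Sequence[str]) -> "CountMatrix":
        ids = [t for t in self.values.index if t in set(target_ids)]
        return CountMatrix(
            self.values.loc[ids], self.targets.loc[ids], self.aois.copy()
        )

    def subset_aois(self, aoi_ids: Sequence[str]) -> "CountMatrix":
        ids = [a for a in self.values.columns if a in set(aoi_ids)]
        return CountMatrix(
            self.values[ids], self.targets.copy(), self.aois.loc[ids]
        )

    def for_analyte(self, analyte: str) -> "CountMatrix":
        """Counts restricted to one analyte's targets (incl. its controls)."""
        if analyte not in self.analytes():
            raise SpgError(f"analyte {analyte!r} absent from matrix")
        ids = self.targets.index[self.targets["analyte"] == analyte]
        return self.subset_targets(list(ids))

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.targets.copy(), self.aois.copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    """Auto-detect tab vs comma delimiter from the header line."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"  # single-column table; delimiter irrelevant


def _read_table(path: Path, index_col: str, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    return df.set_index(index_col)


def read_count_matrix(
    counts_path: str | Path,
    target_annotation_path: str | Path,
    aoi_annotation_path: str | Path,
) -> CountMatrix:
    """Read a counts table plus its two annotation tables into a CountMatrix.

    The counts file has a ``target_id`` first column and one column per AOI.
    Row/column order is normalised to annotation order. Mismatched identifier
    sets raise :class:`ConsistencyError` listing the offenders; a negative
    cell raises ``ValueError`` with its coordinates.
    """
    targets = _read_table(Path(target_annotation_path), "target_id", TARGET_COLUMNS)
    aois = _read_table(Path(aoi_annotation_path), "aoi_id", AOI_REQUIRED)
    counts = _read_table(Path(counts_path), "target_id", ("target_id",))

    t_counts, t_ann = set(counts.index), set(targets.index)
    if t_counts != t_ann:
        raise ConsistencyError(
            f"targets in counts only: {sorted(t_counts - t_ann)}; "
            f"targets in annotation only: {sorted(t_ann - t_counts)}"
        )
    a_counts, a_ann = set(counts.columns), set(aois.index)
    if a_counts != a_ann:
        raise ConsistencyError(
            f"AOIs in counts only: {sorted(a_counts - a_ann)}; "
            f"AOIs in annotation only: {sorted(a_ann - a_counts)}"
        )
    values = counts.loc[targets.index, aois.index].astype(float)
    values.columns.name = None
    matrix = CountMatrix(values, targets, aois)
    by_class = targets["probe_class"].value_counts().to_dict()
    logger.info(
        "read %d targets x %d AOIs (%s)",
        matrix.n_targets,
        matrix.n_aois,
        ", ".join(f"{k}={v}" for k, v in sorted(by_class.items())),
    )
    return matrix


#: printed precision for floating-point matrices; round-trips to ~1e-10 rel.
FLOAT_FORMAT = "%.12g"


def write_matrix(matrix, path: str | Path) -> Path:
    """Write a CountMatrix or SnrMatrix values table as TSV.

    Output is always tab-delimited with a leading ``target_id`` column and is
    readable back by :func:`read_count_matrix` (given the annotation tables)
    or by any generic matrix reader.
    """
    path = Path(path)
    values: pd.DataFrame = matrix.values
    values.to_csv(
        path, sep="\t", index_label="target_id", float_format=FLOAT_FORMAT
    )
    return path


def write_dataset(matrix: CountMatrix, outdir: str | Path, prefix: str = "") -> dict:
    """Write counts.tsv / targets.tsv / aois.tsv for a CountMatrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "targets": outdir / f"{prefix}targets.tsv",
        "aois": outdir / f"{prefix}aois.tsv",
    }
    write_matrix(matrix, paths["counts"])
    matrix.targets.to_csv(paths["targets"], sep="\t", index_label="target_id")
    matrix.aois.to_csv(
        paths["aois"], sep="\t", index_label="aoi_id", float_format=FLOAT_FORMAT
    )
    return {k: str(v) for k, v in paths.items()}


def read_dataset(outdir: str | Path, prefix: str = "") -> CountMatrix:
    outdir = Path(outdir)
    return read_count_matrix(
        outdir / f"{prefix}counts.tsv",
        outdir / f"{prefix}targets.tsv",
        outdir / f"{prefix}aois.tsv",
    )


# ---------------------------------------------------------------------------
# Sequencing-level AOI QC
# ---------------------------------------------------------------------------

_QC_FIELDS = {
    "raw_reads": "min_raw_reads",
    "sequencing_saturation": "min_saturation",
    "area": "min_area",
}


def qc_filter_aois(
    matrix: CountMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[CountMatrix, list[dict]]:
    """Remove AOIs with low reads, low saturation or low area.

    An AOI is kept iff every available metric is >= its threshold. If a QC
    column is absent from the AOI annotation that criterion is skipped with a
    warning. Returns the filtered matrix plus a report listing each removed
    AOI with the criteria it failed. Raises :class:`SpgError` if nothing
    survives.
    """
    report: list[dict] = []
    keep: list[str] = []
    for aoi_id, row in matrix.aois.iterrows():
        failed = []
        for col, thr_name in _QC_FIELDS.items():
            if col not in matrix.aois.columns:
                continue
            if pd.isna(row[col]):
                continue
            if float(row[col]) < getattr(thresholds, thr_name):
                failed.append(col)
        if failed:
            report.append({"aoi_id": aoi_id, "failed": failed})
        else:
            keep.append(aoi_id)
    for col in _QC_FIELDS:
        if col not in matrix.aois.columns:
            logger.warning("QC column %r absent; criterion skipped", col)
    if not keep:
        raise SpgError("QC removed every AOI (empty study)")
    return matrix.subset_aois(keep), report


def write_qc_report(report: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2) + "\n")
    return path
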