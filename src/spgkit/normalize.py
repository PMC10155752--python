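"""Per-AOI background statistics: limit of quantification, signal-to-noise
normalization and detection calls.

Both analytes are normalized against their own control probes. For RNA the
background per AOI is the geometric mean of the negative ISH probes; the
limit of quantification (LoQ) for AOI *i* is

    LoQ_i = geomean(negprobes_i) * geosd(negprobes_i) ** n_sd        (n_sd = 2)

floored at a minimum (default 2). A gene counts as detected in an AOI if its
raw count is strictly above that AOI's LoQ. SNR divides each count by the
per-AOI geometric mean of the analyte's control class (negative probes for
RNA, the IgG isotype controls for protein); detection by SNR uses inclusive
thresholds (protein SNR >= 3, whole-transcriptome RNA SNR >= 4).

Geometric statistics are undefined at zero, so counts are shifted with
:func:`shift_counts` (floor 1) once before any of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CONTROL_CLASS, CountMatrix, SpgError


def _as_positive_array(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{what}: empty input")
    if (arr <= 0).any():
        raise ValueError(
            f"{what}: values must be > 0; shift counts first (shift_counts)"
        )
    return arr


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log values)); requires a nonempty all-positive input."""
    arr = _as_positive_array(values, "geometric_mean")
    return float(stats.gmean(arr))


def geometric_sd(values: Sequence[float]) -> float:
    """exp(sample SD of log values, n-1 denominator); needs length >= 2."""
    arr = _as_positive_array(values, "geometric_sd")
    if arr.size < 2:
        raise ValueError("geometric_sd: need at least two values")
    return float(stats.gstd(arr))  # scipy uses ddof=1


def shift_counts(matrix: CountMatrix, floor: float = 1.0) -> CountMatrix:
    """Replace every value v by max(v, floor) so geometric stats are defined."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    return CountMatrix(
        matrix.values.clip(lower=floor), matrix.targets.copy(), matrix.aois.copy()
    )


@dataclass
class LoqVector:
    """Per-AOI limit of quantification derived from the negative probes."""

    loq: pd.Series  # aoi_id -> LoQ
    n_sd: float
    floor: float

    def __post_init__(self) -> None:
        if (self.loq < self.floor).any():
            raise ValueError("LoQ below floor")


def compute_loq(
    matrix: CountMatrix, n_sd: float = 2.0, floor: float = 2.0
) -> LoqVector:
    """LoQ_i = geomean(negprobes in AOI i) * geosd(...)^n_sd, floored.

    Requires at least two RNA negative-control probes and shifted (positive)
    counts.
    """
    neg = matrix.control_targets("rna")
    if len(neg) == 0:
        raise SpgError("no negative-control probes in matrix")
    if len(neg) < 2:
        raise SpgError("LoQ needs >= 2 negative probes (geometric SD undefined)")
    sub = matrix.values.loc[neg]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("counts must be shifted positive before compute_loq")
    logs = np.log(sub.to_numpy())
    gm = np.exp(logs.mean(axis=0))
    gsd = np.exp(logs.std(axis=0, ddof=1))
    loq = np.maximum(gm * gsd**n_sd, floor)
    return LoqVector(pd.Series(loq, index=sub.columns), n_sd=n_sd, floor=floor)


@dataclass
class SnrMatrix:
    """Signal-to-noise normalized expression for one analyte.

    ``values`` holds count / per-AOI geometric mean of the analyte's control
    class; ``denominator`` records that geometric mean per AOI. The target and
    AOI annotation tables ride along so grouping factors (tissue, segment)
    stay available downstream.
    """

    values: pd.DataFrame
    analyte: str
    denominator: pd.Series
    targets: pd.DataFrame
    aois: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("SNR values must be positive (shift counts first)")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_aois(self) -> int:
        return self.values.shape[1]

    def endogenous(self) -> "SnrMatrix":
        ids = self.targets.index[self.targets["probe_class"] == "endogenous"]
        return SnrMatrix(
            self.values.loc[ids],
            self.analyte,
            self.denominator.copy(),
            self.targets.loc[ids],
            self.aois.copy(),
        )

    def subset_targets(self, ids) -> "SnrMatrix":
        keep = [t for t in self.values.index if t in set(ids)]
        return SnrMatrix(
            self.values.loc[keep],
            self.analyte,
            self.denominator.copy(),
            self.targets.loc[keep],
            self.aois.copy(),
        )

    def subset_aois(self, ids) -> "SnrMatrix":
        keep = [a for a in self.values.columns if a in set(ids)]
        return SnrMatrix(
            self.values[keep],
            self.analyte,
            self.denominator.loc[keep],
            self.targets.copy(),
            self.aois.loc[keep],
        )


def snr_normalize(matrix: CountMatrix, analyte: str) -> SnrMatrix:
    """Divide each count by the per-AOI geometric mean of the analyte's
    control-class counts (negative probes for RNA, IgG controls for protein).
    """
    if analyte not in matrix.analytes():
        raise SpgError(f"analyte {analyte!r} absent from matrix")
    sub = matrix.for_analyte(analyte)
    controls = sub.control_targets(analyte)
    if len(controls) == 0:
        raise SpgError(f"no {CONTROL_CLASS[analyte]} targets for {analyte}")
    vals = sub.values
    if (vals.to_numpy() <= 0).any():
        raise ValueError("counts must be shifted positive before snr_normalize")
    denom = pd.Series(
        np.exp(np.log(vals.loc[controls].to_numpy()).mean(axis=0)),
        index=vals.columns,
    )
    return SnrMatrix(vals / denom, analyte, denom, sub.targets, sub.aois)


@dataclass
class DetectionMatrix:
    """Boolean target x AOI detection calls.

    rule "above_loq": count strictly above the AOI's LoQ.
    rule "snr_threshold": SNR >= threshold (inclusive).
    """

    values: pd.DataFrame
    rule: str
    threshold: float | None = None

    def subset_targets(self, ids) -> "DetectionMatrix":
        keep = [t for t in self.values.index if t in set(ids)]
        return DetectionMatrix(self.values.loc[keep], self.rule, self.threshold)

    def subset_aois(self, ids) -> "DetectionMatrix":
        keep = [a for a in self.values.columns if a in set(ids)]
        return DetectionMatrix(self.values[keep], self.rule, self.threshold)


def detect(
    source: CountMatrix | SnrMatrix,
    rule: str,
    loq: LoqVector | None = None,
    threshold: float | None = None,
) -> DetectionMatrix:
    """Detection calls from counts vs LoQ, or from SNR vs threshold."""
    if rule == "above_loq":
        if loq is None:
            raise ValueError("rule 'above_loq' requires a LoqVector")
        vals = source.values
        det = vals.gt(loq.loq.reindex(vals.columns), axis=1)
        return DetectionMatrix(det, rule="above_loq", threshold=None)
    if rule == "snr_threshold":
        if threshold is None:
            raise ValueError("rule 'snr_threshold' requires a threshold")
        det = source.values.ge(threshold)
        return DetectionMatrix(det, rule="snr_threshold", threshold=threshold)
    raise ValueError(f"unknown detection rule {rule!r}")
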