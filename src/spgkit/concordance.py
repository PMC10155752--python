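"""Assay-performance metrics against paired assays and a known truth set.

These are the benchmarking statistics used to compare a dual-analyte run
against its single-analyte controls and against a TPM-style reference:

* Pearson concordance of log2 SNR profiles between units (cell lines, ROIs
  or targets), optionally masked to targets passing a detection threshold in
  the reference assay;
* identity matching by maximum correlation (each test unit assigned the
  reference unit with the highest r);
* detection TPR/FPR against the expressed class of a truth set (expressed
  defined as reference expression > 1);
* sensitivity expressed as the average change in regression-line slope of
  log2 SNR (test on reference), percent change = (1 - mean slope) x 100;
* per-target coefficient of variation and its ranking;
* hierarchical clustering under correlation distance (1 - Pearson r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .normalize import DetectionMatrix, SnrMatrix
from .simulate import TruthSet

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pearson coefficients between unit profiles of two matrices."""

    r: pd.DataFrame  # units of a x units of b
    unit_kind: str
    log2: bool


def pairwise_correlation(
    a: SnrMatrix,
    b: SnrMatrix,
    unit_kind: str = "cell_line",
    log2: bool = True,
    detection_mask: DetectionMatrix | None = None,
    min_shared: int = 3,
) -> CorrelationMatrix:
    """Pearson r between every unit (column) of ``a`` and of ``b``.

    Profiles are taken over the shared target set; when a ``detection_mask``
    over ``b`` (the reference assay) is supplied, each pair is restricted to
    the targets detected in that reference unit. Pairs with fewer than
    ``min_shared`` targets, or a zero-variance profile, are recorded as
    missing (NaN).
    """
    shared = [t for t in a.values.index if t in set(b.values.index)]
    if not shared:
        raise ValueError("no shared targets between matrices")
    av = a.values.loc[shared]
    bv = b.values.loc[shared]
    if log2:
        av, bv = np.log2(av), np.log2(bv)
    mask = None
    if detection_mask is not None:
        mask = detection_mask.values.reindex(index=shared, columns=bv.columns)

    out = np.full((av.shape[1], bv.shape[1]), np.nan)
    a_np, b_np = av.to_numpy(), bv.to_numpy()
    for j, b_unit in enumerate(bv.columns):
        rows = (
            np.ones(len(shared), dtype=bool)
            if mask is None
            else mask[b_unit].fillna(False).to_numpy()
        )
        if rows.sum() < min_shared:
            logger.warning("unit %s: <%d shared targets after masking", b_unit, min_shared)
            continue
        y = b_np[rows, j]
        if np.ptp(y) == 0:
            logger.warning("unit %s: zero-variance reference profile", b_unit)
            continue
        yc = y - y.mean()
        ynorm = np.sqrt((yc**2).sum())
        for i in range(av.shape[1]):
            x = a_np[rows, i]
            if np.ptp(x) == 0:
                continue
            xc = x - x.mean()
            out[i, j] = float((xc * yc).sum() / (np.sqrt((xc**2).sum()) * ynorm))
    return CorrelationMatrix(
        pd.DataFrame(out, index=av.columns, columns=bv.columns),
        unit_kind=unit_kind,
        log2=log2,
    )


def max_r_match(
    corr: CorrelationMatrix, true_identity: dict
) -> tuple[dict, float, list]:
    """Assign each row unit its argmax-r column unit; score against truth.

    Returns (assignment, accuracy, ties). Ties are broken by first column
    index and reported; all-missing rows are left unassigned and excluded
    from the accuracy denominator.
    """
    assignment: dict = {}
    ties: list = []
    n_ok = n_tot = 0
    for unit, row in corr.r.iterrows():
        if row.isna().all():
            warnings.warn(f"unit {unit!r}: no defined correlations; unassigned")
            continue
        best = row.max()
        winners = [c for c in row.index if row[c] == best]
        if len(winners) > 1:
            ties.append({"unit": unit, "tied": winners})
        assignment[unit] = winners[0]
        if unit in true_identity:
            n_tot += 1
            n_ok += assignment[unit] == true_identity[unit]
    accuracy = n_ok / n_tot if n_tot else float("nan")
    return assignment, accuracy, ties


@dataclass
class DetectionMetrics:
    """Detection TPR/FPR of an assay against the expressed truth class."""

    tpr: float
    fpr: float
    n_true: int
    n_false: int
    detected: int


def detection_metrics(
    detected: set, truth: TruthSet, cell_line: str, assessed: set
) -> DetectionMetrics:
    """TPR/FPR of a detected-target set for one cell line.

    TPR = |detected ∩ expressed| / |expressed ∩ assessed|;
    FPR = |detected \\ expressed| / |assessed \\ expressed|.
    ``detected`` must be a subset of ``assessed``, which must lie inside the
    truth set's gene universe.
    """
    universe = set(truth.reference_expression.columns)
    if not assessed <= universe:
        raise ValueError("assessed targets outside the truth set universe")
    if not detected <= assessed:
        raise ValueError("detected targets must be a subset of assessed")
    expressed = truth.expressed_genes(cell_line) & assessed
    not_expressed = assessed - expressed
    if not expressed:
        raise ValueError("no expressed targets among assessed: TPR undefined")
    if not not_expressed:
        raise ValueError("no non-expressed targets among assessed: FPR undefined")
    tp = len(detected & expressed)
    fp = len(detected - expressed)
    return DetectionMetrics(
        tpr=tp / len(expressed),
        fpr=fp / len(not_expressed),
        n_true=len(expressed),
        n_false=len(not_expressed),
        detected=len(detected),
    )


@dataclass
class SensitivityResult:
    """Sensitivity change as the mean regression slope of log2 SNR."""

    slopes: dict
    mean_slope: float
    percent_change: float  # (1 - mean_slope) * 100 by definition


def sensitivity_slope(
    test: SnrMatrix, reference: SnrMatrix, per_unit: dict | None = None
) -> SensitivityResult:
    """OLS slope (with intercept) of log2(test SNR) on log2(reference SNR).

    ``per_unit`` maps the matched column names (shared by both matrices after
    any replicate averaging) to a unit id; per-unit slopes are averaged and
    the percent sensitivity change is (1 - mean slope) x 100, so a slope
    below 1 reads as a sensitivity loss of the test assay. Units with fewer
    than 3 matched targets are skipped with a warning.
    """
    shared_t = [t for t in test.values.index if t in set(reference.values.index)]
    shared_u = [u for u in test.values.columns if u in set(reference.values.columns)]
    if not shared_t or not shared_u:
        raise ValueError("no matched targets/units between matrices")
    if per_unit is None:
        per_unit = {u: u for u in shared_u}
    units: dict[str, list] = {}
    for col in shared_u:
        units.setdefault(per_unit[col], []).append(col)

    slopes: dict = {}
    for unit, cols in units.items():
        x = np.log2(reference.values.loc[shared_t, cols].to_numpy()).ravel()
        y = np.log2(test.values.loc[shared_t, cols].to_numpy()).ravel()
        if x.size < 3:
            warnings.warn(f"unit {unit!r}: <3 matched targets; skipped")
            continue
        slope = np.polyfit(x, y, 1)[0]
        slopes[unit] = float(slope)
    if not slopes:
        raise ValueError("no unit had enough matched targets")
    mean_slope = float(np.mean(list(slopes.values())))
    return SensitivityResult(
        slopes=slopes,
        mean_slope=mean_slope,
        percent_change=(1.0 - mean_slope) * 100.0,
    )


@dataclass
class CvTable:
    """Per-target coefficient of variation (SD/mean) and its ranking."""

    cv: pd.Series
    ranking: list = field(default_factory=list)

    def top(self, n: int) -> list:
        return self.ranking[:n]


def cv_table(snr: SnrMatrix) -> CvTable:
    """CV_g = SD_g / mean_g per target across AOIs (sample SD, n-1)."""
    if snr.n_aois < 2:
        raise ValueError("CV needs >= 2 AOIs")
    vals = snr.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0] = np.nan
    ranking = list(cv.sort_values(ascending=False, kind="stable").index)
    return CvTable(cv=cv, ranking=ranking)


def correlation_cluster(
    values: pd.DataFrame,
    axis: str = "columns",
    linkage: str = "complete",
    scale: bool = True,
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering under correlation distance d = 1 - Pearson r.

    ``values`` is a target x unit table (log2 SNR or log counts); ``axis``
    picks which dimension to cluster. Feature profiles are z-scaled (zero
    mean, unit variance per feature) before the distance, matching the
    heatmap convention. Returns the scipy linkage matrix and the
    deterministic leaf order.
    """
    prof = values.T if axis == "columns" else values
    labels = list(prof.index)
    if len(labels) < 2:
        raise ValueError("need >= 2 units to cluster")
    x = prof.to_numpy(dtype=float)
    sd_units = x.std(axis=1)
    for lab, s in zip(labels, sd_units):
        if s == 0:
            raise ValueError(f"zero-variance unit {lab!r}")
    if scale:
        feat_sd = x.std(axis=0)
        keep = feat_sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / feat_sd[keep]
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return z, order
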