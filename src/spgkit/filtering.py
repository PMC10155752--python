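"""Segment- and gene-level detection filters plus replicate averaging.

The detection-based filters mirror the platform's published workflow: AOIs
(segments) where less than 5% of the endogenous genes are above the LoQ are
removed first; genes are then kept either by an inclusion rule (above the LoQ
in strictly more than 15% of AOIs) or, in the stricter profile used for the
tumor study, by an exclusion rule (dropped when below the LoQ in at least 10%
of AOIs). The two gene rules differ in direction and strictness in the
source workflow and are kept as explicit modes rather than silently
reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import DetectionMatrix, SnrMatrix


@dataclass
class FilterReport:
    """What a filter removed and why, plus the parameters used."""

    removed_aois: list[dict] = field(default_factory=list)
    removed_targets: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_aois": self.removed_aois,
            "removed_targets": self.removed_targets,
            "parameters": self.parameters,
        }


def filter_segments(
    det: DetectionMatrix, min_gene_fraction: float = 0.05
) -> tuple[list[str], FilterReport]:
    """Keep AOIs whose detected-gene fraction is >= ``min_gene_fraction``.

    ``det`` must be an above-LoQ detection matrix over endogenous RNA targets
    only; AOIs with *less than* the cut-off fraction of genes above LoQ are
    removed (strictly-below fails, matching "less than 5% ... were removed").
    """
    if det.values.size == 0:
        raise ValueError("empty detection matrix")
    if not 0 <= min_gene_fraction <= 1:
        raise ValueError("min_gene_fraction must be in [0, 1]")
    frac = det.values.mean(axis=0)  # per AOI
    kept = [a for a in det.values.columns if frac[a] >= min_gene_fraction]
    report = FilterReport(
        removed_aois=[
            {"aoi_id": a, "gene_detection_fraction": float(frac[a])}
            for a in det.values.columns
            if frac[a] < min_gene_fraction
        ],
        parameters={"rule": "segment", "min_gene_fraction": min_gene_fraction},
    )
    return kept, report


def filter_genes(
    det: DetectionMatrix, mode: str, fraction: float | None = None
) -> tuple[list[str], FilterReport]:
    """Gene-level detection filter over the surviving AOIs.

    mode "include_above" (default fraction 0.15): keep a gene iff its
    detection rate is strictly greater than ``fraction``.
    mode "exclude_below" (default fraction 0.10): remove a gene iff its
    non-detection rate is >= ``fraction`` (inclusive "at least").
    """
    if mode not in ("include_above", "exclude_below"):
        raise ValueError(f"unknown mode {mode!r}")
    if fraction is None:
        fraction = 0.15 if mode == "include_above" else 0.10
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if det.values.size == 0:
        raise ValueError("empty detection matrix")
    rate = det.values.mean(axis=1)  # per target detection rate
    if mode == "include_above":
        keep_mask = rate > fraction
    else:
        nondet = (~det.values).mean(axis=1)  # computed directly: exact at boundaries
        keep_mask = nondet < fraction
    kept = [t for t in det.values.index if keep_mask[t]]
    report = FilterReport(
        removed_targets=[
            {"target_id": t, "detection_rate": float(rate[t])}
            for t in det.values.index
            if not keep_mask[t]
        ],
        parameters={"rule": "gene", "mode": mode, "fraction": fraction},
    )
    return kept, report


def average_replicates(
    snr: SnrMatrix, grouping: dict, method: str = "geometric"
) -> SnrMatrix:
    """Average SNR across replicate AOIs within each group.

    ``grouping`` maps every aoi_id to a group id. The default geometric mean
    commutes with the log2 transform used by all downstream concordance;
    arithmetic is available as an alternative. Group annotation is
    synthesized from the first member AOI of each group.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown method {method!r}")
    missing = [a for a in snr.values.columns if a not in grouping]
    if missing:
        raise ValueError(f"AOIs without a group assignment: {missing}")
    groups: dict[str, list[str]] = {}
    for a in snr.values.columns:  # preserve input order of first appearance
        groups.setdefault(grouping[a], []).append(a)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty group {g!r}")

    cols = {}
    denoms = {}
    for g, members in groups.items():
        block = snr.values[members].to_numpy()
        if method == "geometric":
            cols[g] = np.exp(np.log(block).mean(axis=1))
            denoms[g] = float(np.exp(np.log(snr.denominator[members]).mean()))
        else:
            cols[g] = block.mean(axis=1)
            denoms[g] = float(snr.denominator[members].mean())
    values = pd.DataFrame(cols, index=snr.values.index)

    aois = pd.DataFrame(
        [snr.aois.loc[members[0]] for g, members in groups.items()],
        index=pd.Index(list(groups), name="aoi_id"),
    )
    return SnrMatrix(
        values,
        snr.analyte,
        pd.Series(denoms).reindex(values.columns),
        snr.targets.copy(),
        aois,
    )
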