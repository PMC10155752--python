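"""Shared fixtures and small constructors for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from spgkit.datamodel import CountMatrix
from spgkit.normalize import SnrMatrix
from spgkit.simulate import GeneratorConfig, simulate_cpa


def infer_class(target_id: str) -> tuple[str, str]:
    """(analyte, probe_class) from a conventional target name."""
    if target_id.startswith("Neg"):
        return "rna", "negative"
    if target_id.startswith("IgG"):
        return "protein", "igg_control"
    if target_id.startswith("PROT"):
        return "protein", "endogenous"
    return "rna", "endogenous"


def make_aois(aoi_ids, **overrides) -> pd.DataFrame:
    base = {
        "roi_id": [f"roi_{a}" for a in aoi_ids],
        "slide_id": "slide1",
        "tissue_id": [f"tis_{a}" for a in aoi_ids],
        "segment_label": "geometric",
        "roi_diameter": 200.0,
        "area": round(math.pi * 100.0**2, 2),
        "raw_reads": 10000.0,
        "sequencing_saturation": 0.9,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(aoi_ids, name="aoi_id"))


def make_matrix(data: dict, aois: pd.DataFrame | None = None) -> CountMatrix:
    """CountMatrix from {target_id: row of counts}; classes inferred from
    the naming convention (Neg* -> negative, IgG* -> isotype control,
    PROT* -> protein, else endogenous RNA)."""
    values = pd.DataFrame(data).T.astype(float)
    values.index.name = "target_id"
    n_aois = values.shape[1]
    values.columns = [f"A{j + 1}" for j in range(n_aois)] if list(values.columns) == list(range(n_aois)) else values.columns
    targets = pd.DataFrame(
        [
            {
                "target_id": t,
                "analyte": infer_class(t)[0],
                "probe_class": infer_class(t)[1],
                "symbol": t,
                "panel": "test",
            }
            for t in values.index
        ]
    ).set_index("target_id")
    if aois is None:
        aois = make_aois(list(values.columns))
    return CountMatrix(values, targets, aois)


def make_snr(data: dict, analyte: str = "rna", aois: pd.DataFrame | None = None) -> SnrMatrix:
    """SnrMatrix from {target_id: row}; unit denominator, inferred classes."""
    values = pd.DataFrame(data).T.astype(float)
    values.index.name = "target_id"
    values.columns = [f"A{j + 1}" for j in range(values.shape[1])] if list(values.columns) == list(range(values.shape[1])) else values.columns
    targets = pd.DataFrame(
        [
            {
                "target_id": t,
                "analyte": analyte,
                "probe_class": infer_class(t)[1] if infer_class(t)[0] == analyte else "endogenous",
                "symbol": t,
                "panel": "test",
            }
            for t in values.index
        ]
    ).set_index("target_id")
    if aois is None:
        aois = make_aois(list(values.columns))
    denom = pd.Series(1.0, index=values.columns)
    return SnrMatrix(values, analyte, denom, targets, aois)


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    return make_matrix(
        {
            "GENE1": [20, 8],
            "GENE2": [4, 2],
            "NegA": [2, 1],
            "NegB": [8, 4],
        }
    )


@pytest.fixture(scope="session")
def cpa_small():
    """A small paired cell-pellet-array simulation shared across tests."""
    cfg = GeneratorConfig(
        n_cell_lines=8,
        n_genes=60,
        n_proteins=24,
        n_negprobes=15,
        replicates_per_line=2,
        seed=101,
    )
    return simulate_cpa(cfg)
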