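"""Differential expression: Welch t-test, BH adjustment, mixed model,
significance tiers and the combined volcano table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spgkit.diffexp import (
    assign_tier,
    bh_adjust,
    combined_volcano_table,
    mixed_model_de,
    significant_targets,
    ttest_de,
)
from spgkit.normalize import snr_normalize, shift_counts
from spgkit.simulate import GeneratorConfig, TissueConfig, simulate_tissue

from conftest import make_aois, make_snr


def two_group_snr(rows: dict, n1: int, n2: int):
    snr = make_snr(rows)
    groups = {f"A{j + 1}": (1 if j < n1 else 2) for j in range(n1 + n2)}
    return snr, groups


class TestTtest:
    def test_identical_groups_null(self):
        snr, groups = two_group_snr({"GENE1": [1, 2, 3, 1, 2, 3]}, 3, 3)
        de = ttest_de(snr, groups)
        assert de.loc[0, "log2fc"] == 0.0
        assert de.loc[0, "p"] == pytest.approx(1.0)

    def test_fourfold_ratio_gives_log2fc_2(self):
        base = [1.0, 2.0, 3.0]
        snr, groups = two_group_snr({"GENE1": [4 * b for b in base] + base}, 3, 3)
        de = ttest_de(snr, groups)
        assert de.loc[0, "log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_welch_statistic_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0, 4.0]), np.array([3.0, 4.0, 5.0, 6.0])
        snr, groups = two_group_snr({"GENE1": list(2.0**a) + list(2.0**b)}, 4, 4)
        de = ttest_de(snr, groups)
        v1, v2 = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 3 + v2**2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert de.loc[0, "p"] == pytest.approx(p, abs=1e-12)
        assert de.loc[0, "log2fc"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_swapping_groups_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(12)
        rows = {f"GENE{i}": rng.lognormal(0, 1, 10) for i in range(20)}
        snr, groups = two_group_snr(rows, 5, 5)
        swapped = {a: 3 - g for a, g in groups.items()}
        d1, d2 = ttest_de(snr, groups), ttest_de(snr, swapped)
        assert np.allclose(d1["log2fc"], -d2["log2fc"], atol=1e-12)
        assert np.allclose(d1["p"], d2["p"], atol=1e-12)

    def test_small_group_is_error(self):
        snr, _ = two_group_snr({"GENE1": [1, 2, 3]}, 2, 1)
        with pytest.raises(ValueError, match=">= 2"):
            ttest_de(snr, {"A1": 1, "A2": 1, "A3": 2})


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005], [0.005]),
            ([0.01, 0.5], [0.02, 0.5]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            adj = bh_adjust(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                oracle[i] = running
            assert np.allclose(adj, oracle, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTiers:
    @pytest.mark.parametrize(
        "p,fdr,tier",
        [
            (0.2, 0.4, "ns"),
            (0.01, 0.2, "p05"),
            (0.01, 0.04, "fdr05"),
            (0.0001, 0.0005, "fdr001"),
        ],
    )
    def test_pure_function_of_p_and_fdr(self, p, fdr, tier):
        assert assign_tier(p, fdr) == tier

    def test_table_rows_satisfy_tier_invariant(self):
        rng = np.random.default_rng(5)
        rows = {f"GENE{i}": rng.lognormal(0, 1, 8) for i in range(50)}
        snr, groups = two_group_snr(rows, 4, 4)
        de = ttest_de(snr, groups)
        for _, row in de.iterrows():
            assert row["tier"] == assign_tier(row["p"], row["fdr"])
            assert row["fdr"] >= row["p"] - 1e-15


class TestSignificantTargets:
    def test_fc_cut_is_strict(self):
        de = pd.DataFrame(
            {
                "target_id": ["a", "b", "c"],
                "log2fc": [1.5, 1.0, -1.5],
                "fdr": [0.0005, 0.0005, 0.0005],
            }
        )
        assert significant_targets(de) == ["a", "c"]  # |FC|=2 exactly is excluded

    def test_empty_table(self):
        assert significant_targets(pd.DataFrame()) == []


class TestCombinedVolcano:
    def test_concatenation_and_tiers(self):
        rng = np.random.default_rng(3)
        rna_rows = {f"GENE{i}": rng.lognormal(0, 1, 8) for i in range(88)}
        prot_rows = {f"PROT{i}": rng.lognormal(0, 1, 8) for i in range(25)}
        snr_r, groups = two_group_snr(rna_rows, 4, 4)
        snr_p, _ = two_group_snr(prot_rows, 4, 4)
        snr_p.analyte = "protein"
        snr_p.targets["analyte"] = "protein"
        table = combined_volcano_table(ttest_de(snr_r, groups), ttest_de(snr_p, groups))
        assert len(table) == 113
        assert set(table["analyte"]) == {"rna", "protein"}
        assert np.allclose(table["neg_log10_p"], -np.log10(table["p"]))

    def test_duplicate_pairs_rejected(self):
        rng = np.random.default_rng(4)
        rows = {f"GENE{i}": rng.lognormal(0, 1, 8) for i in range(5)}
        snr, groups = two_group_snr(rows, 4, 4)
        de = ttest_de(snr, groups)
        with pytest.raises(ValueError, match="duplicated"):
            combined_volcano_table(de, de)


def calibration_base(**kw) -> GeneratorConfig:
    """High-signal configuration for inference checks: abundant expressed
    targets and a precisely estimated SNR denominator (many negative probes),
    so planted effects pass through normalization undistorted."""
    base = dict(
        n_genes=40,
        n_proteins=1,
        n_negprobes=120,
        expressed_fraction=1.0,
        capture_scale=200.0,
        background_mean=50.0,
        dispersion=16.0,
        seed=0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestMixedModel:
    def test_zero_random_variance_limit_agrees_with_ttest(self):
        spg, _, _ = simulate_tissue(
            TissueConfig(n_tissues=6, rois_per_tissue=4, de_fraction=0.3, tissue_re_sd=0.0, seed=43),
            calibration_base(seed=43),
        )
        snr = snr_normalize(shift_counts(spg), "rna").endogenous()
        dm = mixed_model_de(snr, "segment_label", "tissue_id").set_index("target_id")
        groups = {
            a: 1 if snr.aois.loc[a, "segment_label"] == "GFAP" else 2
            for a in snr.values.columns
        }
        dt = ttest_de(snr, groups).set_index("target_id")
        assert (dm["log2fc"] - dt["log2fc"]).abs().max() < 0.05

    def test_recovers_planted_unit_log2fc(self):
        ests = []
        for seed in range(3):
            spg, _, truth = simulate_tissue(
                TissueConfig(
                    n_tissues=6, rois_per_tissue=4, de_fraction=1.0,
                    de_log2fc_mean=1.0, de_log2fc_sd=0.0, tissue_re_sd=0.3, seed=seed,
                ),
                calibration_base(seed=seed),
            )
            snr = snr_normalize(shift_counts(spg), "rna").endogenous()
            de = mixed_model_de(snr, "segment_label", "tissue_id")
            ests.append(float(de["log2fc"].mean()))
        assert np.abs(np.array(ests) - 1.0).mean() < 0.1

    def test_zero_re_simulation_estimates_small_variance(self):
        """With tissue_re_sd = 0 the between-tissue variance component is
        estimated near zero relative to the residual variance."""
        spg, _, _ = simulate_tissue(
            TissueConfig(n_tissues=6, rois_per_tissue=4, de_fraction=0.0, tissue_re_sd=0.0, seed=11),
            calibration_base(n_genes=30, seed=11),
        )
        snr = snr_normalize(shift_counts(spg), "rna").endogenous()
        de = mixed_model_de(snr, "segment_label", "tissue_id")
        fitted = de[de["flag"] == ""]
        assert (de["flag"] == "fixed_only").any() or (fitted["re_var"] == 0).any()
        ratio = (fitted["re_var"] / fitted["resid_var"]).median()
        assert ratio < 0.2

    def test_contrast_direction(self):
        spg, _, truth = simulate_tissue(
            TissueConfig(n_tissues=6, rois_per_tissue=4, de_fraction=1.0,
                         de_log2fc_mean=2.0, de_log2fc_sd=0.0, tissue_re_sd=0.1, seed=21),
            calibration_base(n_genes=10, seed=21),
        )
        snr = snr_normalize(shift_counts(spg), "rna").endogenous()
        fwd = mixed_model_de(snr, "segment_label", "tissue_id", contrast=("GFAP", "CD45"))
        rev = mixed_model_de(snr, "segment_label", "tissue_id", contrast=("CD45", "GFAP"))
        assert fwd["log2fc"].mean() == pytest.approx(-rev["log2fc"].mean(), abs=1e-9)
        assert fwd["log2fc"].mean() > 1.0  # planted +2 on the GFAP segment
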