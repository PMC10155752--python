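"""Assay-performance metrics: correlation, identity matching, TPR/FPR,
sensitivity slopes, CV and correlation-distance clustering."""

import numpy as np
import pandas as pd
import pytest

from spgkit.concordance import (
    correlation_cluster,
    cv_table,
    detection_metrics,
    max_r_match,
    pairwise_correlation,
    sensitivity_slope,
)
from spgkit.filtering import average_replicates
from spgkit.normalize import detect, shift_counts, snr_normalize
from spgkit.simulate import TruthSet

from conftest import make_snr


def snr_from_array(arr, prefix="GENE"):
    return make_snr({f"{prefix}{i}": row for i, row in enumerate(np.asarray(arr, float))})


class TestPairwiseCorrelation:
    def test_self_correlation_is_one_and_negation_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1, 1, size=(20, 1))
        a = snr_from_array(x)
        b = snr_from_array(1.0 / x)  # negation in log2 space
        r_self = pairwise_correlation(a, a).r.iloc[0, 0]
        r_neg = pairwise_correlation(a, b).r.iloc[0, 0]
        assert r_self == pytest.approx(1.0, abs=1e-12)
        assert r_neg == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.lognormal(0, 1, size=(20, 3))
            y = rng.lognormal(0, 1, size=(20, 2))
            r = pairwise_correlation(snr_from_array(x), snr_from_array(y)).r
            lx, ly = np.log2(x), np.log2(y)
            for i in range(3):
                for j in range(2):
                    a, b = lx[:, i], ly[:, j]
                    oracle = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
                        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
                    )
                    assert abs(r.iloc[i, j] - oracle) <= 1e-12

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = snr_from_array(rng.lognormal(0, 1, size=(15, 3)))
        b = snr_from_array(rng.lognormal(0, 1, size=(15, 4)))
        rab = pairwise_correlation(a, b).r
        rba = pairwise_correlation(b, a).r
        assert np.allclose(rab.to_numpy(), rba.to_numpy().T, atol=1e-12)

    def test_too_few_shared_targets_is_missing(self):
        a = snr_from_array(np.ones((2, 1)) * [[1.0], [2.0]])
        b = snr_from_array([[2.0], [4.0]])
        r = pairwise_correlation(a, b, min_shared=3).r
        assert r.isna().all().all()


class TestMaxRMatch:
    def test_identity_matrix_perfect_accuracy(self):
        from spgkit.concordance import CorrelationMatrix

        r = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        _, acc, ties = max_r_match(CorrelationMatrix(r, "cell_line", True), {u: u for u in "abcd"})
        assert acc == 1.0 and ties == []

    def test_recovers_known_permutation(self):
        from spgkit.concordance import CorrelationMatrix

        rng = np.random.default_rng(8)
        base = rng.random((5, 5)) * 0.3
        perm = [2, 0, 4, 1, 3]
        for i, j in enumerate(perm):
            base[i, j] = 0.95
        r = pd.DataFrame(base, index=[f"u{i}" for i in range(5)], columns=[f"v{j}" for j in range(5)])
        assignment, acc, _ = max_r_match(
            CorrelationMatrix(r, "cell_line", True),
            {f"u{i}": f"v{j}" for i, j in enumerate(perm)},
        )
        assert acc == 1.0
        assert assignment == {f"u{i}": f"v{j}" for i, j in enumerate(perm)}

    def test_simulated_cpa_lines_match_themselves(self, cpa_small):
        _, ctrl_prot, spg, _ = cpa_small
        ref = snr_normalize(shift_counts(ctrl_prot), "protein")
        test = snr_normalize(shift_counts(spg), "protein")
        ref_avg = average_replicates(ref, ref.aois["tissue_id"].to_dict())
        test_avg = average_replicates(test, test.aois["tissue_id"].to_dict())
        mask = detect(ref_avg, "snr_threshold", threshold=3.0)
        corr = pairwise_correlation(test_avg, ref_avg, detection_mask=mask)
        _, acc, _ = max_r_match(corr, {u: u for u in corr.r.index})
        assert acc == 1.0


class TestDetectionMetrics:
    def make_truth(self, n_expressed=80, n_total=100):
        vals = np.full((1, n_total), 0.5)
        vals[0, :n_expressed] = 10.0
        return TruthSet(pd.DataFrame(vals, index=["CL1"], columns=[f"G{i}" for i in range(n_total)]))

    def test_counting_example(self):
        truth = self.make_truth()
        assessed = {f"G{i}" for i in range(100)}
        detected = {f"G{i}" for i in range(66)} | {f"G{i}" for i in range(80, 84)}
        m = detection_metrics(detected, truth, "CL1", assessed)
        assert m.tpr == pytest.approx(66 / 80) == pytest.approx(0.825)
        assert m.fpr == pytest.approx(4 / 20) == pytest.approx(0.20)

    def test_perfect_and_empty_detection(self):
        truth = self.make_truth()
        assessed = {f"G{i}" for i in range(100)}
        expressed = {f"G{i}" for i in range(80)}
        perfect = detection_metrics(expressed, truth, "CL1", assessed)
        empty = detection_metrics(set(), truth, "CL1", assessed)
        assert (perfect.tpr, perfect.fpr) == (1.0, 0.0)
        assert (empty.tpr, empty.fpr) == (0.0, 0.0)

    def test_degenerate_truth_classes_error(self):
        truth = self.make_truth(n_expressed=100)
        with pytest.raises(ValueError, match="FPR undefined"):
            detection_metrics(set(), truth, "CL1", {f"G{i}" for i in range(100)})


class TestSensitivitySlope:
    def test_identity_gives_slope_one(self):
        rng = np.random.default_rng(2)
        ref = snr_from_array(rng.lognormal(1, 1, size=(30, 2)))
        res = sensitivity_slope(ref, ref)
        assert res.mean_slope == pytest.approx(1.0, abs=1e-12)
        assert res.percent_change == pytest.approx(0.0, abs=1e-10)

    def test_constructed_slope_0p9_gives_10_percent(self):
        rng = np.random.default_rng(3)
        ref_vals = rng.lognormal(1, 1, size=(30, 2))
        test_vals = 2.0 ** (0.9 * np.log2(ref_vals))
        res = sensitivity_slope(snr_from_array(test_vals), snr_from_array(ref_vals))
        assert res.mean_slope == pytest.approx(0.9, abs=1e-10)
        assert res.percent_change == pytest.approx(10.0, abs=1e-8)
        # invariant: percent_change is exactly 100*(1 - mean_slope)
        assert res.percent_change == (1.0 - res.mean_slope) * 100.0


class TestCvTable:
    def test_formula_and_ranking(self):
        snr = make_snr({"GENE1": [5.0, 5.0, 5.0], "GENE2": [2.0, 4.0, 3.0], "GENE3": [1.0, 10.0, 1.0]})
        table = cv_table(snr)
        assert table.cv["GENE1"] == 0.0
        assert table.cv["GENE2"] == pytest.approx(1.0 / 3.0)
        assert table.ranking[0] == "GENE3" and table.ranking[-1] == "GENE1"
        assert table.top(1) == ["GENE3"]

    def test_two_point_example(self):
        snr = make_snr({"GENE1": [2.0, 4.0]})
        assert cv_table(snr).cv["GENE1"] == pytest.approx(np.sqrt(2.0) / 3.0, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(0, 1, size=(5, 8))
        base = cv_table(snr_from_array(vals)).cv
        scaled = cv_table(snr_from_array(vals * 37.0)).cv
        assert np.allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-12)


class TestCorrelationCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(20, 4))
        x[:, 1] = x[:, 0]
        df = pd.DataFrame(x, columns=list("abcd"))
        z, order = correlation_cluster(df, scale=False)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(z[0, :2]) == [0, 1]  # a and b merged first

    def test_anticorrelated_distance_two(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": -x, "c": x * 2})
        z, _ = correlation_cluster(df, scale=False)
        assert z[-1, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_agglomeration(self):
        """Complete-linkage merge tree equals an exhaustive naive oracle."""
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(0, 1, size=(25, 5)), columns=list("abcde"))
        z, _ = correlation_cluster(df, scale=False)

        x = df.to_numpy().T
        r = np.corrcoef(x)
        d = 1.0 - r
        clusters = {i: {i} for i in range(5)}
        merges = []
        next_id = 5
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i >= j:
                        continue
                    dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                    if best is None or dist < best[0]:
                        best = (dist, i, j)
            dist, i, j = best
            merges.append((frozenset(clusters[i] | clusters[j]), dist))
            clusters[next_id] = clusters.pop(i) | clusters.pop(j)
            next_id += 1

        members = {i: {i} for i in range(5)}
        for row, (oracle_set, oracle_dist) in zip(z, merges):
            merged = members[int(row[0])] | members[int(row[1])]
            members[len(members)] = merged
            assert frozenset(merged) == oracle_set
            assert row[2] == pytest.approx(oracle_dist, abs=1e-12)

    def test_zero_variance_unit_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="'b'"):
            correlation_cluster(df, scale=False)
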