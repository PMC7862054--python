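import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytoprof.differential import (
    GroupComparison,
    bootstrap_adjust_pvalues,
    build_mmi_table,
    mean_marker_intensity,
    paired_fold_change,
    positivity_fraction,
    quadrant_fractions,
    run_group_comparison,
    subset_ratio,
    welch_t_test,
    welch_t_vectorized,
)


class TestMmi:
    def test_simple_means(self):
        assert mean_marker_intensity([1, 2, 3]) == 2
        assert mean_marker_intensity([0.7]) == pytest.approx(0.7)

    def test_empty_unit_is_undefined(self):
        with pytest.raises(ValueError):
            mean_marker_intensity([])

    def test_concatenation_is_weighted_mean(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=70)
        whole = mean_marker_intensity(np.concatenate([a, b]))
        parts = (30 * mean_marker_intensity(a) + 70 * mean_marker_intensity(b)) / 100
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_table_layout(self, rng):
        samples = {"s1": rng.normal(size=(40, 2))}
        labels = {"s1": np.array(["u1"] * 25 + ["u2"] * 15)}
        t = build_mmi_table(samples, ["m1", "m2"], labels)
        assert set(t["unit"]) == {"u1", "u2"}
        assert len(t) == 4
        sub = t[(t.unit == "u1") & (t.marker == "m1")]
        assert sub["mmi"].iloc[0] == pytest.approx(
            samples["s1"][:25, 0].mean()
        )


class TestWelch:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0 and p == 1

    def test_strong_shift(self):
        t, _, p = welch_t_test([1, 2, 3, 4], [11, 12, 13, 14])
        assert p < 0.001 and t < 0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        ta, _, pa = welch_t_test(a, b)
        tb, _, pb = welch_t_test(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_zero_variance_conventions(self):
        t, _, p = welch_t_test([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t_test([2.0, 2.0], [1.0, 1.0])
        assert p == 0.0 and t == np.inf

    def test_vectorized_matches_scipy(self, rng):
        a = rng.normal(size=(20, 8))
        b = rng.normal(0.5, 2.0, size=(20, 11))
        t_vec = welch_t_vectorized(a, b)
        for i in range(20):
            t_ref = stats.ttest_ind(a[i], b[i], equal_var=False).statistic
            assert t_vec[i] == pytest.approx(t_ref, rel=1e-10)

    def test_null_pvalues_are_uniform(self):
        """KS check of Welch p-values against U(0,1) under the null."""
        r = np.random.default_rng(7)
        a = r.normal(size=(1000, 15))
        b = r.normal(size=(1000, 15))
        pvals = np.array([welch_t_test(a[i], b[i])[2] for i in range(1000)])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPairedFoldChange:
    @staticmethod
    def _mmi(rows):
        return pd.DataFrame(rows, columns=["sample_id", "unit", "marker", "mmi"])

    @staticmethod
    def _meta(rows):
        return pd.DataFrame(rows, columns=["sample_id", "patient_id",
                                           "timepoint"])

    def test_identical_timepoints_zero(self):
        mmi = self._mmi([("p1B", "u", "m", 1.5), ("p1T", "u", "m", 1.5),
                         ("p2B", "u", "m", 2.0), ("p2T", "u", "m", 2.0)])
        meta = self._meta([("p1B", "p1", "baseline"),
                           ("p1T", "p1", "on_treatment"),
                           ("p2B", "p2", "baseline"),
                           ("p2T", "p2", "on_treatment")])
        fc = paired_fold_change(mmi, meta)
        assert np.allclose(fc["fold_change"], 0)

    def test_constant_shift(self):
        mmi = self._mmi([(f"p{i}{tp}", "u", "m", 1.0 + (0.5 if tp == "T" else 0))
                         for i in range(4) for tp in "BT"])
        meta = self._meta([(f"p{i}{tp}", f"p{i}",
                            "baseline" if tp == "B" else "on_treatment")
                           for i in range(4) for tp in "BT"])
        fc = paired_fold_change(mmi, meta)
        assert fc["fold_change"].mean() == pytest.approx(0.5)

    def test_differs_from_pooled_difference_when_unbalanced(self):
        # patient p1 has extreme baseline; pooled means would be distorted
        mmi = self._mmi([("p1B", "u", "m", 10.0), ("p1T", "u", "m", 10.5),
                         ("p2B", "u", "m", 0.0), ("p2T", "u", "m", 0.5),
                         ("p3B", "u", "m", 0.0), ("p3T", "u", "m", 0.5),
                         ("orphanB", "u", "m", 99.0)])
        meta = self._meta([("p1B", "p1", "baseline"),
                           ("p1T", "p1", "on_treatment"),
                           ("p2B", "p2", "baseline"),
                           ("p2T", "p2", "on_treatment"),
                           ("p3B", "p3", "baseline"),
                           ("p3T", "p3", "on_treatment"),
                           ("orphanB", "orphan", "baseline")])
        fc = paired_fold_change(mmi, meta)
        assert set(fc["patient_id"]) == {"p1", "p2", "p3"}  # orphan excluded
        per_patient_mean = fc["fold_change"].mean()
        pooled = (10.5 + 0.5 + 0.5) / 3 - (10.0 + 0.0 + 0.0 + 99.0) / 4
        assert per_patient_mean == pytest.approx(0.5)
        assert abs(per_patient_mean - pooled) > 1


class TestMaxT:
    def test_single_hypothesis_close_to_raw_bootstrap(self, rng):
        a = rng.normal(1.0, 1, size=(1, 12))
        b = rng.normal(0.0, 1, size=(1, 12))
        t, raw, adj = bootstrap_adjust_pvalues(a, b, B=500, rng=0)
        assert adj[0] >= 1 / 501
        assert adj.shape == (1,)

    def test_adjusted_dominates_raw(self, rng):
        a = rng.normal(size=(20, 10)) + np.linspace(0, 1, 20)[:, None]
        b = rng.normal(size=(20, 10))
        _, raw, adj = bootstrap_adjust_pvalues(a, b, B=200, rng=0)
        assert (adj >= raw - 1e-12).all()
        assert ((0 <= adj) & (adj <= 1)).all()

    def test_order_invariance(self, rng):
        a = rng.normal(size=(10, 8))
        b = rng.normal(size=(10, 8)) + 0.4
        _, _, adj = bootstrap_adjust_pvalues(a, b, B=200, rng=3)
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        _, _, adj_p = bootstrap_adjust_pvalues(a[perm], b[perm], B=200, rng=3)
        assert np.allclose(adj[perm], adj_p)

    def test_monotone_in_t(self, rng):
        a = rng.normal(size=(15, 9)) + np.linspace(0, 2, 15)[:, None]
        b = rng.normal(size=(15, 9))
        t, _, adj = bootstrap_adjust_pvalues(a, b, B=200, rng=0)
        order = np.argsort(-np.abs(t))
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_small_b(self, rng):
        with pytest.raises(ValueError):
            bootstrap_adjust_pvalues(np.zeros((1, 5)), np.zeros((1, 5)), B=10)


class TestThresholdReadouts:
    def test_positivity(self):
        assert positivity_fraction([0.1, 0.3, 0.5], 0.25) == pytest.approx(2 / 3)
        assert positivity_fraction([0.1, 0.2], 0.25) == 0.0
        assert positivity_fraction([0.1, 0.2], -np.inf) == 1.0

    def test_subset_ratio(self):
        assert subset_ratio(90, 10) == 9
        assert subset_ratio(5, 5) == 1
        assert np.isnan(subset_ratio(5, 0))

    def test_quadrants(self):
        q = quadrant_fractions(np.array([[2.0, 2.0]]), 1.0, 1.0)
        assert q == {"--": 0, "+-": 0, "-+": 0, "++": 1}

    def test_quadrants_partition(self, rng):
        xy = rng.normal(1, 1, size=(500, 2))
        q = quadrant_fractions(xy, 1.0, 1.2)
        assert sum(q.values()) == pytest.approx(1.0)


class TestGroupComparison:
    def test_spiked_units_detected_and_sorted(self, rng):
        samples = [f"s{i}" for i in range(16)]
        rows = []
        for i, s in enumerate(samples):
            group_shift = 1.5 if i < 8 else 0.0
            rows.append((s, "hot", "CD38", rng.normal(group_shift, 0.1)))
            rows.append((s, "cold", "CD38", rng.normal(0, 0.1)))
        mmi = pd.DataFrame(rows, columns=["sample_id", "unit", "marker", "mmi"])
        cmp = GroupComparison(samples[:8], samples[8:])
        res = run_group_comparison(mmi, cmp, B=200, rng=0)
        res = res.set_index("unit")
        assert res.loc["hot", "adj_p"] < 0.05
        assert res.loc["cold", "adj_p"] > 0.05
        assert res.loc["hot", "fold_change"] > 0

    def test_incomplete_units_dropped(self, rng):
        rows = [(f"s{i}", "full", "m", rng.normal()) for i in range(8)]
        rows += [(f"s{i}", "partial", "m", rng.normal()) for i in range(7)]
        mmi = pd.DataFrame(rows, columns=["sample_id", "unit", "marker", "mmi"])
        cmp = GroupComparison([f"s{i}" for i in range(4)],
                              [f"s{i}" for i in range(4, 8)])
        res = run_group_comparison(mmi, cmp, B=200, rng=0)
        assert set(res["unit"]) == {"full"}

    def test_outlier_patient_exclusion_hook(self, rng):
        rows = [(f"s{i}", "u", "m", rng.normal()) for i in range(10)]
        mmi = pd.DataFrame(rows, columns=["sample_id", "unit", "marker", "mmi"])
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)],
                             "patient_id": [f"p{i % 5}" for i in range(10)]})
        cmp = GroupComparison([f"s{i}" for i in range(5)],
                              [f"s{i}" for i in range(5, 10)])
        res = run_group_comparison(mmi, cmp, B=200, rng=0,
                                   exclude_patients={"p0"}, metadata=meta)
        assert res["n_a"].iloc[0] == 4  # s0 and s5 dropped
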