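"""Evaluation protocol: aggregation arithmetic, CV, generalization, statistics."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from enoseopt.evaluate import (
    ablation_frame,
    build_ablation_table,
    cv_5x2,
    leave_one_temperature_out,
    macro_accuracy,
    paired_compare,
    redundancy_reduction,
    round_half_up,
)

# Published per-temperature accuracies of the four selection models,
# used as inputs to the aggregation arithmetic.
PUBLISHED_ROWS = {
    "RFA": {"acc": (97.4, 97.0, 99.3, 98.3), "kept": 6},
    "SA": {"acc": (99.8, 100.0, 99.5, 99.6), "kept": 4},
    "GA-QPSO": {"acc": (99.7, 97.8, 97.8, 99.0), "kept": 5},
    "Tri": {"acc": (99.6, 99.8, 99.5, 99.4), "kept": 5},
}


class TestAggregation:
    def test_macro_accuracy_of_published_rows(self):
        assert macro_accuracy(PUBLISHED_ROWS["RFA"]["acc"]) == pytest.approx(98.0)
        assert round_half_up(macro_accuracy(PUBLISHED_ROWS["Tri"]["acc"])) == 99.6
        assert macro_accuracy(PUBLISHED_ROWS["Tri"]["acc"]) == pytest.approx(99.575)

    def test_macro_accuracy_of_equal_values(self):
        assert macro_accuracy([97.0] * 4) == 97.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            macro_accuracy([])

    @pytest.mark.parametrize("kept,expected", [(6, 40.0), (5, 50.0), (10, 0.0)])
    def test_redundancy_reduction_formula(self, kept, expected):
        assert redundancy_reduction(kept) == expected

    def test_redundancy_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            redundancy_reduction(0)
        with pytest.raises(ValueError):
            redundancy_reduction(11)

    def test_round_half_up_at_ties(self):
        assert round_half_up(1.65) == 1.7
        assert round_half_up(0.575) == 0.6  # beyond float representation issues
        assert round_half_up(-1.65) == -1.7


class TestCv5x2:
    def test_separable_data_scores_100_with_zero_sd(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 20)
        X = y[:, None] * 5.0 + rng.normal(0, 0.05, (60, 1))
        mean, sd, accs = cv_5x2(X, y, lambda: KNeighborsClassifier(3), seed=0)
        assert mean == 100.0 and sd == 0.0 and len(accs) == 10

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(90, 4))
        y = rng.integers(0, 3, 90)
        mean, _, _ = cv_5x2(X, y, lambda: KNeighborsClassifier(5), seed=1)
        assert abs(mean - 100 / 3) < 3 * 100 * np.sqrt((1 / 3) * (2 / 3) / 45)

    def test_same_seed_identical_folds(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        r1 = cv_5x2(X, y, lambda: KNeighborsClassifier(3), seed=7)
        r2 = cv_5x2(X, y, lambda: KNeighborsClassifier(3), seed=7)
        assert np.array_equal(r1[2], r2[2])

    def test_single_sample_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array([0, 0, 1])
        with pytest.raises(ValueError):
            cv_5x2(X, y, lambda: KNeighborsClassifier(1))


class TestLeaveOneTemperatureOut:
    def _data(self, confounded):
        rng = np.random.default_rng(3)
        temps = np.repeat([4.0, 12.0, 20.0, 28.0], 30)
        y = np.tile(np.repeat([0, 1, 2], 10), 4)
        X = y[:, None] * 3.0 + rng.normal(0, 0.1, (120, 2))
        if confounded:
            # per-temperature feature shift of one class width: class y at
            # temperature index i aliases class y+1 at index i-1
            shift = (temps / 8.0).astype(int)
            X = X + shift[:, None] * 3.0
        return X, y, temps

    def test_four_splits_produced(self):
        X, y, temps = self._data(False)
        out = leave_one_temperature_out(X, y, temps, lambda: KNeighborsClassifier(3))
        assert set(out) == {4.0, 12.0, 20.0, 28.0}

    def test_temperature_invariant_signal_generalizes(self):
        X, y, temps = self._data(False)
        out = leave_one_temperature_out(X, y, temps, lambda: KNeighborsClassifier(3))
        assert all(mean > 95 for mean, _ in out.values())

    def test_confounded_signal_fails_to_generalize(self):
        X, y, temps = self._data(True)
        out = leave_one_temperature_out(X, y, temps, lambda: KNeighborsClassifier(3))
        held_out = np.mean([mean for mean, _ in out.values()])
        assert held_out < 60  # far below the in-temperature regime


class TestPairedCompare:
    def test_identical_series_zero_effect(self):
        a = np.array([95.0, 96.0, 97.0])
        p, d = paired_compare(a, a)
        assert d == 0.0 and p == 1.0

    def test_constant_shift_effect_size_definition(self):
        rng = np.random.default_rng(4)
        b = rng.normal(90, 2, 12)
        noise = rng.normal(0, 1, 12)
        a = b + 2.0 + noise
        _, d = paired_compare(a, b)
        diff = a - b
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_t_test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        b = rng.normal(90, 3, 10)
        a = b + rng.normal(1.5, 1.0, 10)
        p_t, _ = paired_compare(a, b, method="t")
        # sign-flip permutation test on paired differences
        diff = a - b
        obs = abs(diff.mean())
        count = 0
        n_perm = 4000
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            signs = prng.choice([-1, 1], size=diff.size)
            count += abs((diff * signs).mean()) >= obs - 1e-12
        p_perm = count / n_perm
        assert abs(p_t - p_perm) < 0.02

    def test_zero_variance_nonzero_shift_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            p, d = paired_compare(a + 1.0, a)
        assert np.isnan(p) and np.isinf(d) and d > 0

    def test_sign_convention_a_minus_b(self):
        rng = np.random.default_rng(6)
        b = rng.normal(size=20)
        a = b + 1.0 + rng.normal(0, 0.5, 20)
        _, d_ab = paired_compare(a, b)
        _, d_ba = paired_compare(b, a)
        assert d_ab > 0 and d_ba == pytest.approx(-d_ab)


class TestAblationTable:
    def _rows(self):
        return {
            name: {"accuracy_by_temperature": dict(zip((4.0, 12.0, 20.0, 28.0), r["acc"])),
                   "sensors_kept": r["kept"]}
            for name, r in PUBLISHED_ROWS.items()
        }

    def test_published_rows_reproduce_macro_and_gains(self):
        results = {r.model: r for r in build_ablation_table(self._rows(), baseline="RFA")}
        assert round_half_up(results["RFA"].macro_accuracy) == 98.0
        assert round_half_up(results["SA"].macro_accuracy) == 99.7
        assert round_half_up(results["GA-QPSO"].macro_accuracy) == 98.6
        assert round_half_up(results["Tri"].macro_accuracy) == 99.6
        assert round_half_up(results["SA"].relative_gain) == 1.7
        assert round_half_up(results["GA-QPSO"].relative_gain) == 0.6
        assert round_half_up(results["Tri"].relative_gain) == 1.6
        assert results["RFA"].redundancy_reduction == 40.0
        assert results["SA"].redundancy_reduction == 60.0

    def test_model_compared_with_itself_zero_gain(self):
        rows = self._rows()
        results = {r.model: r for r in build_ablation_table(rows, baseline="Tri")}
        assert results["Tri"].relative_gain is None  # baseline row shows no gain
        assert results["SA"].relative_gain == pytest.approx(
            macro_accuracy(PUBLISHED_ROWS["SA"]["acc"])
            - macro_accuracy(PUBLISHED_ROWS["Tri"]["acc"]))

    def test_internal_consistency_asserted(self):
        results = build_ablation_table(self._rows())
        frame = ablation_frame(results, display_rounding=False)
        acc_cols = [c for c in frame.columns if c.startswith("accuracy_")]
        assert np.allclose(frame[acc_cols].mean(axis=1), frame["macro_accuracy"])
        assert np.allclose(frame["redundancy_reduction"],
                           100 * (1 - frame["sensors_kept"] / 10))

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            build_ablation_table(self._rows(), baseline="nope")

    def test_paired_statistics_attached(self):
        rows = self._rows()
        rng = np.random.default_rng(7)
        base = rng.normal(98, 1, 10)
        rows["Tri"]["fold_accuracies"] = base + 1.0 + rng.normal(0, 0.3, 10)
        rows["SA"]["fold_accuracies"] = base
        results = {r.model: r for r in build_ablation_table(
            rows, comparisons={"Tri": ("SA", "t")})}
        assert results["Tri"].p_value < 0.01
        assert results["Tri"].cohens_d > 0
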