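"""Sensor-subset selection: fitness, RFA ranking, SA, GA-QPSO, chains."""

import itertools

import numpy as np
import pandas as pd
import pytest

import enoseopt as eo
from enoseopt.features import FEATURE_NAMES, pivot_features
from enoseopt.select import (
    SelectorConfig,
    SensorSelectionModel,
    SubsetEvaluator,
    accuracy,
    ablation_run,
    gaqpso_select,
    rfa_rank,
    sa_select,
    tri_optimize,
)


def _synth_table(n_samples=60, seed=0, n_sensors=4, informative=("S1",)):
    """Wide feature table where only `informative` sensors carry the labels."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n_samples)
    cols = {}
    for i in range(1, n_sensors + 1):
        s = f"S{i}"
        for feat in FEATURE_NAMES:
            base = rng.normal(size=n_samples)
            if s in informative:
                base = base * 0.05 + y * 2.0
            cols[f"{s}.{feat}"] = base
    X = pd.DataFrame(cols)
    temps = np.where(np.arange(n_samples) % 2 == 0, 4.0, 20.0)
    return X, y, temps


class TestAccuracy:
    @pytest.mark.parametrize("nc,nt,expected", [(95, 100, 95.0), (0, 50, 0.0), (7, 7, 100.0)])
    def test_ratio_formula(self, nc, nt, expected):
        assert accuracy(nc, nt) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            accuracy(1, 0)
        with pytest.raises(ValueError):
            accuracy(5, 4)


class TestSubsetFitness:
    def test_perfectly_separating_sensor_reaches_100_without_penalty(self):
        X, y, temps = _synth_table(seed=1)
        ev = SubsetEvaluator(X, y, temps, SelectorConfig(size_penalty=0.0), seed=1)
        mask = (True, False, False, False)
        assert ev.fitness(mask) == pytest.approx(100.0)

    def test_shuffled_labels_give_chance_level(self):
        X, y, temps = _synth_table(seed=2, n_samples=90)
        rng = np.random.default_rng(0)
        ev = SubsetEvaluator(X, rng.permutation(y), temps,
                             SelectorConfig(size_penalty=0.0), seed=2)
        acc, _ = ev.cv_accuracy((True, True, True, True))
        assert abs(acc - 100 / 3) < 4 * 100 * np.sqrt((1 / 3) * (2 / 3) / 45)

    def test_size_penalty_arithmetic(self):
        X, y, temps = _synth_table(seed=3)
        ev0 = SubsetEvaluator(X, y, temps, SelectorConfig(size_penalty=0.0), seed=3)
        ev1 = SubsetEvaluator(X, y, temps, SelectorConfig(size_penalty=0.5), seed=3)
        mask = (True, True, False, False)
        assert ev1.fitness(mask) == pytest.approx(ev0.fitness(mask) - 0.5 * 2)

    def test_empty_mask_rejected(self):
        X, y, temps = _synth_table()
        ev = SubsetEvaluator(X, y, temps, seed=0)
        with pytest.raises(ValueError, match="no sensors"):
            ev.fitness((False, False, False, False))

    def test_fitness_deterministic_and_recomputable(self, evaluator):
        mask = tuple(i < 3 for i in range(10))
        f1 = evaluator.fitness(mask)
        evaluator._cache.clear()
        evaluator._acc_cache.clear()
        assert evaluator.fitness(mask) == f1


class TestRfaRank:
    def test_signal_sensor_outranks_pure_noise(self):
        X, y, temps = _synth_table(seed=4, informative=("S2",))
        ev = SubsetEvaluator(X, y, temps, seed=4)
        rk = rfa_rank(ev, seed=4)
        assert rk.sensors[int(np.argmax(rk.importances))] == "S2"
        assert rk.per_sensor_accuracy["S2"] > max(
            v for k, v in rk.per_sensor_accuracy.items() if k != "S2")

    def test_importances_normalized_nonnegative(self, evaluator):
        rk = rfa_rank(evaluator, seed=0)
        assert np.all(rk.importances >= 0)
        assert rk.importances.sum() == pytest.approx(1.0)
        assert 0 <= rk.oob_accuracy <= 100

    def test_duplicated_channels_share_importance(self):
        # paired check: duplicating the informative sensor splits its
        # importance roughly evenly between the two copies
        X, y, temps = _synth_table(seed=5, informative=("S1",))
        for feat in FEATURE_NAMES:
            X[f"S2.{feat}"] = X[f"S1.{feat}"] + np.random.default_rng(1).normal(
                0, 1e-6, len(X))
        ev = SubsetEvaluator(X, y, temps, seed=5)
        rk = rfa_rank(ev, seed=5)
        i1 = rk.importances[list(rk.sensors).index("S1")]
        i2 = rk.importances[list(rk.sensors).index("S2")]
        assert abs(i1 - i2) < 0.35 * (i1 + i2)

    def test_single_class_rejected(self):
        X, y, temps = _synth_table(seed=6)
        ev = SubsetEvaluator(X, np.zeros_like(y), temps, seed=6)
        with pytest.raises(ValueError, match="two classes"):
            rfa_rank(ev, seed=6)

    def test_top_k_mask_tie_break_by_sensor_index(self):
        from enoseopt.select import RfaRanking

        rk = RfaRanking(sensors=("S1", "S2", "S3"),
                        importances=np.array([0.4, 0.3, 0.3]),
                        per_sensor_accuracy={}, oob_accuracy=0.0)
        assert rk.top_k_mask(2) == (True, True, False)


def _rugged_fitness(n, seed):
    rng = np.random.default_rng(seed)
    lin = rng.normal(0, 5, n)
    quad = rng.normal(0, 2, (n, n))
    quad = (quad + quad.T) / 2

    def f(mask):
        v = np.array(mask, float)
        return float(lin @ v + v @ quad @ v)

    return f


def _brute_force(f, n):
    return max(f(m) for m in itertools.product([False, True], repeat=n) if any(m))


TOY_CONFIG = SelectorConfig(max_iter=2000, patience=300, pop_size=40,
                            sa_alpha=0.99, sa_t0=5.0)


class TestSimulatedAnnealing:
    def test_matches_exhaustive_search_on_toy_problems(self):
        for seed in range(5):
            n = 6
            f = _rugged_fitness(n, seed)
            _, best, *_ = sa_select(f, n, tuple([True] * n), TOY_CONFIG,
                                    np.random.default_rng(seed + 50))
            assert best == pytest.approx(_brute_force(f, n))

    def test_zero_temperature_is_hill_climbing(self):
        # with T0 = 0 no strictly worse move is ever accepted
        f = _rugged_fitness(6, 3)
        cfg = SelectorConfig(sa_t0=0.0, sa_alpha=0.5, max_iter=200, patience=200)
        mask = tuple([True] * 6)
        cur = f(mask)
        _, best, trace, *_ = sa_select(f, 6, mask, cfg, np.random.default_rng(0))
        assert np.all(np.diff(trace) >= 0)
        assert best >= cur

    def test_fixed_seed_identical_trajectory(self):
        f = _rugged_fitness(8, 1)
        runs = [sa_select(f, 8, tuple([True] * 8), TOY_CONFIG,
                          np.random.default_rng(9)) for _ in range(2)]
        assert runs[0][0] == runs[1][0]
        assert runs[0][2] == runs[1][2]

    def test_never_exceeds_max_iter(self):
        f = _rugged_fitness(6, 2)
        cfg = SelectorConfig(max_iter=30, patience=100)
        *_, n_iter, conv = sa_select(f, 6, tuple([True] * 6), cfg,
                                     np.random.default_rng(0))
        assert n_iter <= 30 and not conv


class TestGaqpsoSelect:
    def test_matches_exhaustive_search_on_toy_problems(self):
        for seed in range(5):
            n = 6
            f = _rugged_fitness(n, seed)
            _, best, *_ = gaqpso_select(f, n, TOY_CONFIG, np.random.default_rng(seed + 70))
            assert best == pytest.approx(_brute_force(f, n))

    def test_best_fitness_trace_nondecreasing(self):
        f = _rugged_fitness(8, 4)
        _, _, trace, *_ = gaqpso_select(f, 8, TOY_CONFIG, np.random.default_rng(0))
        assert np.all(np.diff(trace) >= 0)

    def test_returned_mask_never_empty(self):
        # a fitness rewarding emptiness still yields >= 1 sensor
        f = lambda mask: -float(sum(mask))
        mask, *_ = gaqpso_select(f, 6, SelectorConfig(max_iter=50, patience=10),
                                 np.random.default_rng(0))
        assert any(mask) and sum(mask) == 1


class TestChains:
    def test_tri_final_fitness_at_least_each_stage(self, evaluator):
        res = tri_optimize(evaluator, seed=0)
        stage_fits = [res.stages["rfa_subset"].fitness,
                      res.stages["sa_subset"].fitness,
                      res.stages["gaqpso_subset"].fitness]
        assert res.subset.fitness >= max(stage_fits) - 1e-12
        assert np.all(np.diff(res.trace) >= 0)

    def test_tri_matches_exhaustive_on_reduced_problem(self):
        sc = eo.default_scenarios(temperatures=(4.0, 20.0))
        cycles = eo.generate_dataset(sc, 6, seed=11)
        tab = eo.feature_table(eo.preprocess_dataset(cycles).cycles)
        tab = tab[tab.sensor.isin([f"S{i}" for i in range(1, 7)])]
        X, y, temps = pivot_features(tab)
        cfg = SelectorConfig(max_iter=800, patience=120, pop_size=24,
                             sa_alpha=0.99, sa_t0=3.0, top_k=4)
        ev = SubsetEvaluator(X, y, temps, cfg, seed=11)
        best = max(ev.fitness(m) for m in
                   itertools.product([False, True], repeat=6) if any(m))
        res = tri_optimize(ev, seed=11)
        assert res.subset.fitness == pytest.approx(best)

    def test_redundant_group_contributes_at_most_one_member(self, default_evaluator):
        res = tri_optimize(default_evaluator, seed=1)
        trio = {"S3", "S7", "S8"}
        assert len(trio & set(res.subset.sensors)) <= 1

    def test_ablation_runs_all_seven_chains_deterministically(self, evaluator):
        from enoseopt.select import ABLATION_CHAINS

        out1 = ablation_run(evaluator, seed=5)
        assert set(out1) == set(ABLATION_CHAINS)
        out2 = ablation_run(evaluator, seed=5)
        for name in out1:
            assert out1[name].subset.mask == out2[name].subset.mask
            assert out1[name].trace == out2[name].trace

    def test_redundancy_reduction_formula_on_subsets(self, evaluator):
        res = tri_optimize(evaluator, seed=2)
        s = res.subset
        assert s.redundancy_reduction == pytest.approx(100 * (1 - s.n_kept / 10))


class TestModelFacade:
    def test_from_feature_table_fit_and_summary(self, feature_tab):
        model = SensorSelectionModel.from_feature_table(feature_tab, seed=0)
        res = model.fit(chain="SA", seed=0)
        text = res.summary()
        assert "selected sensors" in text and "redundancy reduction" in text
        assert res.subset.n_kept >= 1

    def test_unknown_chain_rejected(self, feature_tab):
        model = SensorSelectionModel.from_feature_table(feature_tab, seed=0)
        with pytest.raises(ValueError, match="chain"):
            model.fit(chain="bogus")
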