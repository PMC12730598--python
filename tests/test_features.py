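"""Curve-feature extraction and the feature-correlation objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from enoseopt.features import (
    FEATURE_NAMES,
    CurveFeatures,
    GlobalVariables,
    extract_features,
    feature_correlation,
    make_target_curve,
    normalize_weights,
    similarity,
)
from enoseopt.simulate import rise_plateau


class TestExtractFeatures:
    def test_constant_trace(self):
        t = np.arange(300.0)
        f = extract_features(np.full(300, 2.5), t)
        assert f.p_max == f.p_min == 2.5
        assert f.area == pytest.approx(2.5 * 299.0)
        assert f.degenerate and f.t1 == f.t2 == f.t3 == 299.0

    def test_half_rise_time_matches_root_finding_oracle(self):
        # t2 solves 1-exp(-c t) = 0.5 * (1 - exp(-c T_end))
        a, c = 2.0, 0.02
        t = np.arange(300.0)
        trace = a * (1 - np.exp(-c * t))
        f = extract_features(trace, t)
        t2_oracle = brentq(lambda u: (1 - np.exp(-c * u)) - 0.5 * (1 - np.exp(-c * 299.0)),
                           0, 299.0)
        assert abs(f.t2 - t2_oracle) <= 1.0  # grid resolution
        assert f.t1 <= f.t2 <= f.t3

    def test_unit_rectangle_area(self):
        t = np.arange(301.0)
        assert extract_features(np.ones(301), t).area == pytest.approx(300.0)

    def test_plateau_tail_invariance(self):
        # appending a constant plateau leaves p_max, rise times unchanged
        # and grows the area exactly by plateau * tail duration
        c = 0.05
        t = np.arange(200.0)
        trace = 1 - np.exp(-c * t)
        f0 = extract_features(trace, t)
        tail = np.full(100, trace[-1])
        t_ext = np.arange(300.0)
        f1 = extract_features(np.concatenate([trace, tail]), t_ext)
        assert f1.p_max == pytest.approx(f0.p_max)
        assert (f1.t1, f1.t2, f1.t3) == (f0.t1, f0.t2, f0.t3)
        extra = trace[-1] * (t_ext[-1] - t[-1])
        assert f1.area == pytest.approx(f0.area + extra, rel=1e-6)

    def test_equilibrium_time_settling_band(self):
        t = np.arange(300.0)
        trace = 1 - np.exp(-0.05 * t)
        f = extract_features(trace, t)
        final = trace[-1]
        later = trace[t >= f.t_eq]
        assert np.all(np.abs(later - final) <= 0.02 * abs(final) + 1e-12)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            extract_features(np.zeros(5), np.array([0, 1, 2, 4, 8.0]))

    def test_invariant_ordering_enforced(self):
        with pytest.raises(ValueError):
            CurveFeatures(p_max=0.0, p_min=1.0, t_eq=0, area=0, t1=0, t2=0, t3=0)


class TestSimilarity:
    def test_identical_curves_cosine_unity(self):
        x = np.array([1.0, 2.0, 3.0])
        assert similarity(x, x, "cosine") == pytest.approx(1.0)

    def test_orthogonal_curves_map_to_half(self):
        assert similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                          "cosine") == pytest.approx(0.5)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert similarity(x, 3.0 * x + 7.0, "pearson") == pytest.approx(1.0)

    def test_euclidean_self_similarity_unity_and_decreasing(self):
        x = np.zeros(100)
        assert similarity(x, x, "euclidean") == pytest.approx(1.0)
        assert similarity(x, x + 1.0, "euclidean") == pytest.approx(0.5)

    def test_zero_variance_pearson_degenerate(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            s = similarity(np.ones(10), np.arange(10.0), "pearson")
        assert s == 0.5

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10**6),
           metric=st.sampled_from(["pearson", "cosine", "euclidean"]))
    def test_similarity_bounded_in_unit_interval(self, seed, metric):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 30))
        assert 0.0 <= similarity(x, y, metric) <= 1.0


class TestTargetCurve:
    def test_zero_amplitude_gives_constant_baseline(self):
        gv = GlobalVariables(a=0.0, b=0.0, c=0.01, d=1.5, e=0.0)
        assert np.allclose(make_target_curve(gv, np.arange(100.0)), 1.5)

    def test_amplitude_linearity(self):
        t = np.arange(100.0)
        g1 = GlobalVariables(a=1.0, b=0.5, c=0.02, d=0.0)
        g2 = GlobalVariables(a=2.0, b=0.5, c=0.02, d=0.0)
        assert np.allclose(2 * make_target_curve(g1, t), make_target_curve(g2, t))

    def test_noisy_curve_reproducible_under_seed(self):
        gv = GlobalVariables(a=1.0, b=0.0, c=0.02, d=0.0, e=0.3)
        t = np.arange(50.0)
        assert np.array_equal(make_target_curve(gv, t, seed=3),
                              make_target_curve(gv, t, seed=3))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GlobalVariables(a=1, b=0, c=0.0, d=0)
        with pytest.raises(ValueError):
            GlobalVariables(a=1, b=0, c=0.1, d=0, e=-0.1)


class TestFeatureCorrelation:
    def test_perfect_match_gives_unity_for_any_weights(self):
        t = np.arange(120.0)
        gv = GlobalVariables(a=1.2, b=0.4, c=0.03, d=-0.2)
        target = make_target_curve(gv, t)
        traces = np.tile(target, (10, 1))
        for w in (None, np.arange(1.0, 11.0)):
            assert feature_correlation(traces, t, gv, weights=w,
                                       metric="euclidean") == pytest.approx(1.0)

    def test_one_hot_weights_reduce_to_single_similarity(self):
        rng = np.random.default_rng(2)
        t = np.arange(80.0)
        traces = rng.normal(size=(10, 80))
        gv = GlobalVariables(a=1.0, b=0.0, c=0.02, d=0.0)
        w = np.zeros(10)
        w[3] = 1.0
        expected = similarity(traces[3], make_target_curve(gv, t), "pearson")
        assert feature_correlation(traces, t, gv, weights=w) == pytest.approx(expected)

    def test_invariant_under_joint_permutation_of_sensors_and_weights(self):
        rng = np.random.default_rng(4)
        t = np.arange(60.0)
        traces = rng.normal(size=(10, 60))
        w = rng.random(10)
        gv = GlobalVariables(a=1.0, b=0.0, c=0.05, d=0.0)
        perm = rng.permutation(10)
        c0 = feature_correlation(traces, t, gv, weights=w)
        c1 = feature_correlation(traces[perm], t, gv, weights=w[perm])
        assert c0 == pytest.approx(c1)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10**6))
    def test_score_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(50.0)
        traces = rng.normal(size=(4, 50))
        gv = GlobalVariables(a=float(rng.uniform(0.1, 3)), b=float(rng.uniform(0, 2)),
                             c=float(rng.uniform(0.01, 0.1)), d=float(rng.normal()))
        c = feature_correlation(traces, t, gv, metric="pearson")
        assert 0.0 <= c <= 1.0

    def test_weights_validated_and_normalized(self):
        assert normalize_weights(None, 4).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="non-negative"):
            normalize_weights([-1, 1, 1, 1], 4)
        with pytest.raises(ValueError, match="expected"):
            normalize_weights([1, 1], 4)


def test_rise_plateau_reference_shape():
    u = np.linspace(-2, 5, 100)
    f = rise_plateau(u)
    assert np.all(f[u <= 0] == 0)
    assert np.all(np.diff(f[u > 0]) >= 0)
    assert f.max() < 1.0
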