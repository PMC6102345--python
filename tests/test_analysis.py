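"""Layer-trend, cumulative-variance, baseline and contrast tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salnet import (LayerMetricProfile, compare_groups, cumulative_variance,
                    layer_trend, random_baseline)
from salnet.analysis import event_window_stack


class TestLayerTrend:
    def test_exact_linear_profile_recovers_slope(self):
        values = np.array([[0.5 * i] * 3 for i in range(6)])
        res = layer_trend(LayerMetricProfile(values))
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.ci99[0] == pytest.approx(res.slope)
        assert res.ci99[1] == pytest.approx(res.slope)

    def test_constant_profile_gives_null_slope(self):
        res = layer_trend(LayerMetricProfile(np.ones((6, 4))))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_ci_contains_slope_and_df_counts_pooled_replicates(self, rng):
        values = 0.1 + 0.03 * np.arange(6)[:, None] + rng.normal(0, 0.05, (6, 50))
        res = layer_trend(LayerMetricProfile(values))
        assert res.ci99[0] <= res.slope <= res.ci99[1]
        assert res.df == 6 * 50 - 2

    def test_coverage_of_99_percent_interval(self):
        """Simulated slope 0.03 with noise sd 0.05: the 99% CI must cover
        the truth in nearly all seeded replications."""
        hits = 0
        for run in range(100):
            r = np.random.default_rng(run)
            values = np.array([0.1 + 0.03 * i + r.normal(0, 0.05, 200)
                               for i in range(6)])
            res = layer_trend(LayerMetricProfile(values))
            hits += res.ci99[0] <= 0.03 <= res.ci99[1]
        assert hits >= 95

    def test_too_few_layers_or_replicates_rejected(self):
        with pytest.raises(ValueError):
            layer_trend(LayerMetricProfile(np.ones((6, 1))))


class TestCumulativeVariance:
    def test_perfect_first_layer_saturates_at_one(self, rng):
        sal = rng.standard_normal(500)
        layers = [sal.copy(), rng.standard_normal(500), rng.standard_normal(500)]
        frac = cumulative_variance(sal, layers)
        assert np.allclose(frac, 1.0)

    def test_orthogonal_layers_explain_nothing(self):
        n = 1000
        sal = np.random.default_rng(99).standard_normal(n)
        layers = [np.random.default_rng(i).standard_normal(n) for i in range(6)]
        frac = cumulative_variance(sal, layers)
        increments = np.diff(np.concatenate([[0.0], frac]))
        assert np.all(increments < 0.01)

    def test_orthogonal_two_component_decomposition(self):
        """Salience = s1 + s2 with s1 orthogonal to s2 and equal variance:
        cumulative fractions are 0.5 then 1.0."""
        n = 1000
        t = np.arange(n)
        s1 = np.sqrt(2) * np.sin(2 * np.pi * 5 * t / n)
        s2 = np.sqrt(2) * np.sin(2 * np.pi * 11 * t / n)
        frac = cumulative_variance(s1 + s2, [s1, s2])
        assert frac[0] == pytest.approx(0.5, abs=0.05)
        assert frac[1] == pytest.approx(1.0, abs=0.05)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_monotone_nondecreasing_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        sal = r.standard_normal(200)
        layers = [r.standard_normal(200) for _ in range(6)]
        frac = cumulative_variance(sal, layers)
        assert np.all(np.diff(frac) >= -1e-12)
        assert frac[-1] <= 1.0 + 1e-12

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError):
            cumulative_variance(np.ones(100), [np.arange(100.0)])


class TestRandomBaseline:
    def test_first_layer_value_shared_with_model(self, rng):
        sal = rng.standard_normal(800)
        layers = [0.5 * sal + rng.standard_normal(800)] + \
            [rng.standard_normal(800) for _ in range(5)]
        model = cumulative_variance(sal, layers)
        base = random_baseline(sal, layers, seed=3)
        assert base[0] == pytest.approx(model[0], abs=1e-12)

    def test_seeded_reproducibility(self, rng):
        sal = rng.standard_normal(400)
        layers = [rng.standard_normal(400) for _ in range(6)]
        a = random_baseline(sal, layers, seed=11)
        b = random_baseline(sal, layers, seed=11)
        assert np.array_equal(a, b)

    def test_chance_increment_matches_analytic_expectation(self):
        """A random N(0,1) regressor explains on average 1/(n-1) of the
        remaining variance; the mean relative increment over seeded runs
        must sit within two standard errors of that."""
        n = 1000
        ratios = []
        for run in range(100):
            r = np.random.default_rng(10_000 + run)
            sal = r.standard_normal(n)
            layers = [r.standard_normal(n) for _ in range(6)]
            frac = random_baseline(sal, layers, seed=run)
            inc = np.diff(frac)
            remaining = 1.0 - frac[:-1]
            ratios.extend(inc / remaining)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0 / (n - 1)) < 2 * se


class TestCompareGroups:
    def test_identical_groups_give_zero_difference_and_p1(self, rng):
        p = LayerMetricProfile(rng.standard_normal((6, 5)))
        res = compare_groups(p, p)
        assert np.allclose(res.difference, 0.0)
        assert res.p == 1.0
        assert res.df == 4

    def test_swapping_groups_negates_difference(self, rng):
        a = LayerMetricProfile(rng.standard_normal((6, 5)))
        b = LayerMetricProfile(rng.standard_normal((6, 5)))
        assert np.allclose(compare_groups(a, b).difference,
                           -compare_groups(b, a).difference)

    def test_planted_early_layer_advantage_detected(self, rng):
        """Sparse-scene correlations boosted in the three early layers:
        the early-vs-deep contrast of dense-minus-sparse differences must
        be significant and negative."""
        base = 0.3 + rng.normal(0, 0.01, (6, 8))
        sparse = base.copy()
        sparse[:3] += 0.2 + rng.normal(0, 0.01, (3, 8))
        dense = base + rng.normal(0, 0.01, (6, 8))
        res = compare_groups(LayerMetricProfile(dense), LayerMetricProfile(sparse))
        assert np.all(res.difference[:3] < 0)
        assert res.p < 0.05

    def test_mismatched_layers_rejected(self, rng):
        a = LayerMetricProfile(rng.standard_normal((6, 3)))
        b = LayerMetricProfile(rng.standard_normal((3, 3)),
                               layers=("Pool2", "Pool3", "Conv4"))
        with pytest.raises(ValueError):
            compare_groups(a, b)


class TestEventWindowStack:
    def test_stacks_concatenate_matched_windows(self, rng):
        surp = rng.standard_normal(500)
        sal = rng.standard_normal(500)
        sal_stack, surp_stack = event_window_stack(surp, sal, [100, 300],
                                                   delay_samples=14,
                                                   half_window=30)
        assert surp_stack.size == sal_stack.size == 2 * 61
        assert np.array_equal(surp_stack[:61], surp[70:131])
        assert np.array_equal(sal_stack[:61], sal[84:145])

    def test_out_of_bounds_events_dropped(self, rng):
        surp = rng.standard_normal(200)
        sal_stack, surp_stack = event_window_stack(surp, surp, [5, 195])
        assert surp_stack.size == 0

    def test_category_filtered_stacks_feed_cumulative_variance(self, rng):
        """Per-category cumulative variance is the same operation applied
        to the stack of that category's event windows."""
        n = 2000
        surp_layers = [rng.standard_normal(n) for _ in range(3)]
        sal = 0.8 * surp_layers[0] + 0.3 * rng.standard_normal(n)
        events = {"speech": [300, 900], "music": [600, 1500]}
        for cat, idx in events.items():
            sal_stack, surp_stack = event_window_stack(surp_layers[0], sal, idx,
                                                       delay_samples=0)
            stacks = [event_window_stack(l, sal, idx, delay_samples=0)[1]
                      for l in surp_layers]
            frac = cumulative_variance(sal_stack, stacks)
            assert frac[0] > 0.5
            assert np.all(np.diff(frac) >= -1e-12)
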