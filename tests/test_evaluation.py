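"""Metric oracles: concordance, censoring KM, Breslow, Brier/IBS, harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survmeta import (
    MetaConfig,
    NetworkConfig,
    SchemeSpec,
    SurvivalCurve,
    breslow_baseline,
    brier_score_at,
    concordance_index,
    integrated_brier_score,
    km_censoring_estimator,
    run_benchmark,
)
from survmeta.evaluation import StepFunction


def brute_force_cindex(times, events, risks):
    """O(n^2) pair enumeration, independent of the vectorised implementation."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering_is_one(self):
        times = np.arange(1.0, 11.0)
        risks = -times  # strictly decreasing in event time
        assert concordance_index(times, np.ones(10), risks) == 1.0

    def test_reversed_ordering_is_zero(self):
        times = np.arange(1.0, 11.0)
        assert concordance_index(times, np.ones(10), times) == 0.0

    def test_censoring_exclusion_hand_case(self):
        # times (2,3,5), events (0,1,1): only the (3,5) pair is comparable
        c = concordance_index([2, 3, 5], [0, 1, 1], [9.0, 5.0, 1.0])
        assert c == 1.0

    def test_matches_brute_force_on_random_censored_data(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            times = rng.exponential(5, n) + 0.01
            events = rng.integers(0, 2, n)
            if not (events[:, None] & (times[:, None] < times[None, :])).any():
                continue
            risks = np.round(rng.normal(size=n), 1)  # rounding makes risk ties
            assert concordance_index(times, events, risks) == pytest.approx(
                brute_force_cindex(times, events, risks), abs=1e-12
            )

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5, 30) + 0.01
        events = rng.integers(0, 2, 30)
        events[:3] = 1
        risks = rng.normal(size=30)
        c1 = concordance_index(times, events, risks)
        c2 = concordance_index(times, events, -risks)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 25) + 0.01
        events = np.ones(25, dtype=int)
        risks = rng.normal(size=25)
        base = concordance_index(times, events, risks)
        for f in (np.exp, np.tanh, lambda r: 3 * r + 7):
            assert concordance_index(times, events, f(risks)) == base

    def test_agrees_with_scikit_survival_on_distinct_times(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(5)
        times = np.cumsum(rng.uniform(0.1, 1, 50))  # distinct
        events = rng.integers(0, 2, 50).astype(bool)
        events[:2] = True
        risks = rng.normal(size=50)
        ours = concordance_index(times, events.astype(int), risks)
        ref = concordance_index_censored(events, times, risks)[0]
        assert ours == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_and_equals_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        times = rng.exponential(5, n) + 0.01
        events = rng.integers(0, 2, n)
        events[rng.integers(0, n)] = 1
        risks = rng.normal(size=n)
        if not ((times[:, None] < times[None, :]) & (events[:, None] == 1)).any():
            return
        c = concordance_index(times, events, risks)
        assert 0.0 <= c <= 1.0
        assert c == pytest.approx(brute_force_cindex(times, events, risks),
                                  abs=1e-12)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [0, 0], [0.1, 0.2])


class TestCensoringKM:
    def test_no_censoring_gives_unit_curve(self):
        g = km_censoring_estimator([1, 2, 3], [1, 1, 1])
        assert g(0.5) == 1.0 and g(2.5) == 1.0

    def test_all_censored_product_limit(self):
        g = km_censoring_estimator([1, 2, 3, 4], [0, 0, 0, 0])
        np.testing.assert_allclose(g([1, 2, 3, 4]), [0.75, 0.5, 0.25, 0.0])
        assert g(0.5) == 1.0

    def test_nonincreasing(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(3, 40) + 0.01
        events = rng.integers(0, 2, 40)
        g = km_censoring_estimator(times, events)
        assert np.all(np.diff(g.values) <= 1e-15)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        times = rng.exponential(3, 60) + 0.01
        events = rng.integers(0, 2, 60)
        g = km_censoring_estimator(times, events)
        kmf = KaplanMeierFitter().fit(times, 1 - events)
        grid = np.sort(times)
        ref = kmf.survival_function_at_times(grid).values
        np.testing.assert_allclose(np.asarray(g(grid)), ref, atol=1e-12)


class TestBreslow:
    def test_nelson_aalen_special_case(self):
        # all risks 0, no censoring, distinct times: increments 1/n, 1/(n-1)...
        times = np.array([1.0, 2.0, 3.0, 4.0])
        h0 = breslow_baseline(times, np.ones(4), np.zeros(4))
        np.testing.assert_allclose(
            h0.values, np.cumsum([1 / 4, 1 / 3, 1 / 2, 1 / 1])
        )

    def test_shift_invariance_of_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5, 20) + 0.1
        events = np.ones(20, dtype=int)
        risks = rng.normal(size=20)
        s1 = SurvivalCurve(breslow_baseline(times, events, risks), risks)
        s2 = SurvivalCurve(breslow_baseline(times, events, risks + 5), risks + 5)
        grid = np.linspace(0.1, times.max(), 7)
        np.testing.assert_allclose(s1.survival_at(grid), s2.survival_at(grid),
                                   rtol=1e-9)

    def test_single_subject_single_event(self):
        h0 = breslow_baseline([2.0], [1], [0.0])
        assert h0(1.9) == 0.0 and h0(2.0) == 1.0 and h0(5.0) == 1.0

    def test_matches_lifelines_baseline(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(6)
        n = 80
        x = rng.standard_normal(n)
        times = rng.exponential(1 / (0.1 * np.exp(0.5 * x))) + 1e-3
        events = rng.integers(0, 2, n)
        events[:5] = 1
        df = pd.DataFrame({"x": x, "T": times, "E": events})
        cph = CoxPHFitter().fit(df, "T", "E")
        risks = cph.params_.iloc[0] * x
        ours = breslow_baseline(times, events, risks)
        ref = cph.baseline_cumulative_hazard_
        grid = ref.index.values[1:-1]
        # lifelines reports the baseline at the covariate mean, i.e. shifted
        # by exp(mean risk); our baseline is at risk = 0
        np.testing.assert_allclose(
            np.asarray(ours(grid)) * np.exp(risks.mean()),
            ref.values[1:-1, 0], rtol=1e-6,
        )

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="event"):
            breslow_baseline([1, 2], [0, 0], [0, 0])


class TestBrier:
    def test_perfect_step_predictions_score_zero(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.ones(3, dtype=int)
        g = km_censoring_estimator(times, events)
        for t in (0.5, 1.0, 2.5, 3.0):
            s_t = (t < times).astype(float)
            assert brier_score_at(t, times, events, s_t, g) == 0.0

    def test_constant_half_prediction_scores_quarter(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        g = km_censoring_estimator(times, events)
        assert brier_score_at(2.5, times, events, np.full(4, 0.5), g) == 0.25

    def test_two_subject_hand_case(self):
        # one event before t, one survivor, S = (0.2, 0.9), no censoring
        times = np.array([1.0, 5.0])
        events = np.array([1, 1])
        g = km_censoring_estimator(times, events)
        got = brier_score_at(2.0, times, events, np.array([0.2, 0.9]), g)
        assert got == pytest.approx((0.2**2 + 0.1**2) / 2, abs=1e-12)


class TestIBS:
    def test_pointwise_zero_gives_zero(self):
        times = np.sort(np.random.default_rng(0).exponential(5, 20)) + 0.1
        events = np.ones(20, dtype=int)
        surv = (times[None, :] > times[:, None]).astype(float).T
        # row i: S_i(t_j) = 1 for t_j < y_i else 0 -> perfect oracle
        surv = (np.tile(times[:, None], (1, 20)) > times[None, :]).astype(float)
        ibs = integrated_brier_score(surv, times, events, time_grid=times)
        assert ibs == 0.0

    def test_constant_brier_integrates_to_itself(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.ones(5, dtype=int)
        surv = np.full((5, 5), 0.5)
        # constant S=0.5 with no censoring gives Brier 0.25 at every grid point
        ibs = integrated_brier_score(surv, times, events, time_grid=times)
        assert ibs == pytest.approx(0.25, abs=1e-12)

    def test_trapezoid_two_point_arithmetic(self):
        grid = np.array([2.0, 4.0])
        bs = np.array([0.1, 0.3])
        assert np.trapezoid(bs, grid) / (grid[-1] - grid[0]) == pytest.approx(0.2)

    def test_bounds_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 30
            times = rng.exponential(5, n) + 0.1
            events = rng.integers(0, 2, n)
            events[:3] = 1
            risks = rng.normal(size=n)
            h0 = breslow_baseline(times, events, risks)
            ibs = integrated_brier_score(SurvivalCurve(h0, risks), times, events)
            assert 0.0 <= ibs <= 1.0


class TestStepFunction:
    def test_right_continuity_and_left_limits(self):
        f = StepFunction(np.array([1.0, 2.0]), np.array([0.5, 0.2]), 1.0)
        assert f(0.99) == 1.0 and f(1.0) == 0.5 and f(1.5) == 0.5
        assert f.left_limit(1.0) == 1.0 and f.left_limit(2.0) == 0.5
        assert f.left_limit(2.5) == 0.2


class TestBenchmarkHarness:
    NET = NetworkConfig(n_genes=20, hidden_sizes=[8], feature_size=4, init_seed=0)

    def test_trial_counts_and_determinism(self, small_cohort):
        data, _ = small_cohort
        schemes = [SchemeSpec(name="direct", target_train_size=20, epochs=5)]
        kwargs = dict(net_config=self.NET, n_trials=3, seed=13, test_fraction=0.5)
        r1 = run_benchmark(data, "task00", schemes, **kwargs)
        r2 = run_benchmark(data, "task00", schemes, **kwargs)
        assert r1["direct"].c_index.shape == (3,)
        np.testing.assert_array_equal(r1["direct"].c_index, r2["direct"].c_index)
        np.testing.assert_array_equal(r1["direct"].ibs, r2["direct"].ibs)
        s = r1["direct"].summary()
        assert s["c_index_ci"][0] <= s["c_index_mean"] <= s["c_index_ci"][1]

    def test_schemes_share_the_shot_subset(self, small_cohort):
        # shot draws depend only on (pool, size, trial seed), so every scheme
        # trained at the shot size sees identical sample ids within a trial
        from survmeta.data_model import draw_target_subset, stratified_split
        import warnings

        data, _ = small_cohort
        target = data.select_task("task00")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool, _ = stratified_split(target, 0.5, seed=13)
            a = draw_target_subset(pool, 20, seed=1013)
            b = draw_target_subset(pool, 20, seed=1013)
        assert a.sample_ids == b.sample_ids
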