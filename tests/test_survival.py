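import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from clinstrat import (
    OutcomeTable,
    km_estimate,
    logrank_test,
    random_geneset_null,
    simulate_cohort,
    truncate_horizon,
)


def make_outcomes(times, events, ids=None, endpoint="survival"):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return OutcomeTable(pd.DataFrame({"time": times, "event": events}, index=ids), endpoint)


class TestTruncateHorizon:
    def test_event_beyond_horizon_censored(self):
        out = truncate_horizon(make_outcomes([70.0], [True]), 60.0)
        assert out.time[0] == 60.0 and not out.event[0]

    def test_event_at_horizon_kept(self):
        out = truncate_horizon(make_outcomes([60.0], [True]), 60.0)
        assert out.time[0] == 60.0 and out.event[0]

    def test_all_before_horizon_identity(self):
        t = make_outcomes([10.0, 20.0], [True, False])
        out = truncate_horizon(t, 60.0)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_infinite_horizon_identity(self):
        t = make_outcomes([10.0, 200.0], [True, True])
        out = truncate_horizon(t, np.inf)
        pd.testing.assert_frame_equal(out.data, t.data)


class TestKMEstimate:
    def test_no_events_survival_stays_one(self):
        curve = km_estimate(make_outcomes([5.0, 6.0, 7.0], [False] * 3))
        assert len(curve.times) == 0  # no drops: S(t) = 1 throughout

    def test_single_event_one_term(self):
        curve = km_estimate(make_outcomes([3.0, 5.0, 9.0, 11.0], [True, False, False, False]))
        assert curve.survival.tolist() == [1 - 1 / 4]
        assert curve.at_risk.tolist() == [4]

    def test_hand_computed_curve_with_censoring(self):
        curve = km_estimate(make_outcomes([1.0, 1.5, 2.0], [True, False, True]))
        np.testing.assert_allclose(curve.times, [1.0, 2.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 1]

    def test_no_censoring_last_value_is_empirical_fraction(self, rng):
        times = rng.exponential(10, size=30).round(3)
        curve = km_estimate(make_outcomes(times, [True] * 30))
        assert curve.survival[-1] == pytest.approx(0.0, abs=1e-12)
        mid = np.median(times)
        idx = np.searchsorted(curve.times, mid, side="right") - 1
        assert curve.survival[idx] == pytest.approx(np.mean(times > mid), abs=1e-12)


class TestLogRank:
    def test_duplicated_experience_gives_null(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True, False, True] * 2
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=[f"s{i}" for i in range(6)])
        res = logrank_test(make_outcomes(times, events), groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group_statistic(self):
        """O_A=2, E_A=5/6, V=17/36 -> chi-square (7/6)^2/(17/36) = 49/17."""
        out = make_outcomes([1.0, 2.0, 3.0, 4.0], [True] * 4)
        groups = pd.Series(["A", "A", "B", "B"], index=out.sample_ids)
        res = logrank_test(out, groups)
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-9)
        assert res.df == 1
        assert res.observed["A"] == 2
        assert res.expected["A"] == pytest.approx(5 / 6)

    def test_observed_minus_expected_sums_to_zero(self, small_cohort):
        truth = pd.Series(small_cohort.truth.subtype_of_sample)
        res = logrank_test(small_cohort.outcomes["survival"], truth)
        assert abs((res.observed - res.expected).sum()) < 1e-9

    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_matches_lifelines(self, rng, n_groups):
        for _ in range(25):
            n = int(rng.integers(12, 50))
            times = rng.exponential(10, size=n)
            events = rng.random(n) < 0.7
            groups = rng.integers(1, n_groups + 1, size=n)
            if len(np.unique(groups)) < n_groups or not events.any():
                continue
            out = make_outcomes(times, events)
            res = logrank_test(out, pd.Series(groups, index=out.sample_ids))
            ref = multivariate_logrank_test(times, groups, events)
            assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-6)
            assert res.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_strong_hazard_ratio_detected(self):
        detected = 0
        for seed in range(10):
            c = simulate_cohort(n_samples=300, n_genes=10, n_informative_per_subtype=2,
                                hazards=(0.005, 0.010, 0.015), seed=seed)
            truth = pd.Series(c.truth.subtype_of_sample)
            out = truncate_horizon(c.outcomes["survival"], 60.0)
            if logrank_test(out, truth).p_value < 0.01:
                detected += 1
        assert detected >= 9

    def test_no_events_errors(self):
        out = make_outcomes([1.0, 2.0], [False, False])
        groups = pd.Series([1, 2], index=out.sample_ids)
        with pytest.raises(ValueError, match="events"):
            logrank_test(out, groups)

    def test_single_group_errors(self):
        out = make_outcomes([1.0, 2.0], [True, True])
        groups = pd.Series([1, 1], index=out.sample_ids)
        with pytest.raises(ValueError, match="groups"):
            logrank_test(out, groups)


class TestRandomGenesetNull:
    def test_zero_draws_empty(self, small_cohort):
        res = random_geneset_null(
            small_cohort.expression, small_cohort.outcomes["survival"],
            geneset_size=10, k=3, observed_p=0.01, n_draws=0, n_replicates=2, seed=0,
        )
        assert res.n_draws == 0 and res.n_smaller == 0

    def test_oversized_geneset_errors(self, small_cohort):
        with pytest.raises(ValueError):
            random_geneset_null(
                small_cohort.expression, small_cohort.outcomes["survival"],
                geneset_size=10**6, k=3, observed_p=0.5, n_draws=1, seed=0,
            )

    def test_deterministic(self, small_cohort):
        kwargs = dict(geneset_size=30, k=3, observed_p=0.05, n_draws=4,
                      n_replicates=2, seed=123)
        a = random_geneset_null(small_cohort.expression,
                                small_cohort.outcomes["survival"], **kwargs)
        b = random_geneset_null(small_cohort.expression,
                                small_cohort.outcomes["survival"], **kwargs)
        np.testing.assert_array_equal(a.null_ps, b.null_ps)

    def test_strictly_smaller_convention(self, small_cohort):
        res = random_geneset_null(
            small_cohort.expression, small_cohort.outcomes["survival"],
            geneset_size=30, k=3, observed_p=0.0, n_draws=3, n_replicates=2, seed=5,
        )
        assert res.n_smaller == 0  # nothing is strictly below p = 0
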