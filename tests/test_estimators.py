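import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wcr
from wcr.estimators import StepFunction

from _oracles import brute_force_curves
from conftest import make_cohort


class TestRiskSets:
    def test_complete_data(self, tiny_cohort):
        rs = wcr.build_risk_sets(tiny_cohort)
        assert np.allclose(rs.times, [1, 2, 3])
        assert np.allclose(rs.n_at_risk, [3, 2, 1])
        assert np.allclose(rs.d[1], [1, 1, 1])

    def test_weighted_counts(self):
        cohort = make_cohort([1, 2], [1, 1], weights=[2, 1])
        rs = wcr.build_risk_sets(cohort, cohort.weight)
        assert np.allclose(rs.n_at_risk, [3, 1])
        assert np.allclose(rs.d[1], [2, 1])

    def test_tie_pooling_across_causes(self):
        cohort = make_cohort([2, 2], [1, 2])
        rs = wcr.build_risk_sets(cohort)
        assert rs.times.tolist() == [2]
        assert rs.n_at_risk[0] == 2 and rs.d[1][0] == 1 and rs.d[2][0] == 1

    def test_censored_at_event_time_stays_at_risk(self):
        # censoring at t is counted after events at t: both remain in n_j
        cohort = make_cohort([5, 5], [1, 0])
        rs = wcr.build_risk_sets(cohort)
        assert rs.n_at_risk[0] == 2


class TestKaplanMeier:
    def test_hand_product_limit(self):
        cohort = make_cohort([2, 4, 5], [1, 1, 0])
        s = wcr.km_survival(wcr.build_risk_sets(cohort))
        assert s(1.9) == 1.0
        assert np.isclose(s(2), 2 / 3)
        assert np.isclose(s(4), 1 / 3)
        assert np.isclose(s(100), 1 / 3)

    def test_no_events_in_cause_set(self):
        cohort = make_cohort([1, 2], [2, 2])
        s = wcr.km_survival(wcr.build_risk_sets(cohort), cause_set=[1])
        assert s(5) == 1.0

    def test_weighted_product_limit_by_hand(self):
        cohort = make_cohort([1, 2], [1, 1], weights=[2, 1])
        rs = wcr.build_risk_sets(cohort, cohort.weight)
        s = wcr.km_survival(rs)
        assert np.isclose(s(1), 1 / 3)
        assert np.isclose(s(2), 0.0)

    def test_greenwood_variance_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        cohort = make_cohort(t, e)
        s = wcr.km_survival(wcr.build_risk_sets(cohort))
        kmf = KaplanMeierFitter().fit(t, e)
        sf = kmf.survival_function_.iloc[:, 0]
        for tau, val in zip(s.times, s.values):
            assert np.isclose(val, sf.loc[tau]), tau
        # Greenwood pointwise variance via lifelines' reported CI machinery
        var_ll = (kmf._cumulative_sq_.reindex(s.times).to_numpy()) * s.values**2
        assert np.allclose(s.variance, var_ll, atol=1e-12)


class TestCIFs:
    def test_naive_vs_aj_hand_example(self):
        # competing death at t=1 censored by the naive estimator
        cohort = make_cohort([1, 2], [2, 1])
        rs = wcr.build_risk_sets(cohort)
        naive = wcr.naive_km_cif(rs, 1)
        aj = wcr.competing_risks_cif(rs, 1)
        assert naive(1.5) == 0.0 and naive(2) == 1.0
        assert aj(1.5) == 0.0 and np.isclose(aj(2), 0.5)
        aj2 = wcr.competing_risks_cif(rs, 2)
        assert np.isclose(aj2(1), 0.5)

    def test_three_subject_identity(self):
        cohort = make_cohort([1, 2, 3], [1, 2, 0])
        rs = wcr.build_risk_sets(cohort)
        c1 = wcr.cif_at(wcr.competing_risks_cif(rs, 1), 3)
        c2 = wcr.cif_at(wcr.competing_risks_cif(rs, 2), 3)
        s = wcr.cif_at(wcr.km_survival(rs), 3)
        assert np.isclose(c1, 1 / 3) and np.isclose(c2, 1 / 3) and np.isclose(s, 1 / 3)
        assert np.isclose(c1 + c2 + s, 1.0)

    def test_single_cause_reduces_to_km(self):
        rng = np.random.default_rng(2)
        cohort = make_cohort(rng.exponential(5, 50), rng.integers(0, 2, 50))
        rs = wcr.build_risk_sets(cohort)
        aj = wcr.competing_risks_cif(rs, 1)
        km = wcr.km_survival(rs, cause_set=[1])
        assert np.allclose(aj.values, 1 - km.values, atol=1e-12)
        naive = wcr.naive_km_cif(rs, 1)
        assert np.allclose(aj.values, naive.values, atol=1e-12)

    def test_no_cause_k_events_gives_zero(self):
        cohort = make_cohort([1, 2], [2, 2])
        aj = wcr.competing_risks_cif(wcr.build_risk_sets(cohort), 1)
        assert wcr.cif_at(aj, 100) == 0.0

    def test_fixture_example_matches_companion_hand_computation(self, fixture_cohort):
        rs = wcr.build_risk_sets(fixture_cohort)
        aj1 = wcr.competing_risks_cif(rs, 1)
        aj2 = wcr.competing_risks_cif(rs, 2)
        naive = wcr.naive_km_cif(rs, 1)
        assert np.isclose(wcr.cif_at(aj1, 20), 17 / 36)
        assert np.isclose(wcr.cif_at(aj2, 20), 19 / 36)
        assert np.isclose(wcr.cif_at(naive, 20), 5 / 9)


class TestStepFunction:
    def test_right_continuous_evaluation(self):
        fn = StepFunction(np.array([2.0]), np.array([0.5]), origin_value=0.0)
        assert fn(2) == 0.5
        assert fn(1.99) == 0.0
        assert fn(1e6) == 0.5
        with pytest.raises(ValueError):
            wcr.cif_at(fn, -1)

    def test_monotonicity_validation(self):
        with pytest.raises(ValueError):
            StepFunction(np.array([2.0, 1.0]), np.array([0.1, 0.2]))


@st.composite
def small_cohorts(draw):
    n = draw(st.integers(2, 12))
    times = draw(st.lists(st.integers(1, 15), min_size=n, max_size=n))
    events = draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    weights = draw(st.lists(st.integers(1, 3), min_size=n, max_size=n))
    return times, events, weights


@settings(max_examples=120, derandomize=True, deadline=None)
@given(small_cohorts())
def test_brute_force_oracle_and_invariants(case):
    """Vectorized estimators reproduce a loop-based risk-set enumeration
    exactly; naive KM dominates AJ; CIFs + all-cause survival sum to 1."""
    times, events, weights = case
    cohort = make_cohort(times, events, weights=weights)
    for w in (None, cohort.weight):
        rs = wcr.build_risk_sets(cohort, w)
        km = wcr.km_survival(rs)
        oracle = brute_force_curves(times, events, None if w is None else weights)
        for c in rs.causes:
            aj = wcr.competing_risks_cif(rs, c)
            naive = wcr.naive_km_cif(rs, c)
            for tau, (s_o, cif_o, naive_o) in oracle.items():
                assert np.isclose(aj(tau), cif_o[c], atol=1e-12)
                assert np.isclose(naive(tau), naive_o[c], atol=1e-12)
                assert np.isclose(km(tau), s_o, atol=1e-12)
                assert naive(tau) >= aj(tau) - 1e-12
        if rs.causes:
            total = sum(wcr.competing_risks_cif(rs, c)(rs.times[-1]) for c in rs.causes)
            assert np.isclose(total + km(rs.times[-1]), 1.0, atol=1e-10)


def test_integer_weight_equivalence():
    """Weights (1,2,3) equal replicating subjects 1x/2x/3x."""
    times = [3.0, 1.0, 4.0, 2.0]
    events = [1, 2, 0, 1]
    weights = [1, 2, 3, 2]
    cohort = make_cohort(times, events, weights=weights)
    rep_t = np.repeat(times, weights)
    rep_e = np.repeat(events, weights)
    replicated = make_cohort(rep_t, rep_e)
    rs_w = wcr.build_risk_sets(cohort, cohort.weight)
    rs_r = wcr.build_risk_sets(replicated)
    for c in (1, 2):
        a, b = wcr.competing_risks_cif(rs_w, c), wcr.competing_risks_cif(rs_r, c)
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestBootstrap:
    @staticmethod
    def _stat(cohort):
        rs = wcr.build_risk_sets(cohort)
        return wcr.cif_at(wcr.competing_risks_cif(rs, 1), 10.0)

    def test_same_seed_reproducible(self, fixture_cohort):
        a = wcr.bootstrap_ci(fixture_cohort, self._stat, reps=50, seed=3)
        b = wcr.bootstrap_ci(fixture_cohort, self._stat, reps=50, seed=3)
        assert a.lower == b.lower and a.upper == b.upper

    def test_constant_statistic_zero_width(self, fixture_cohort):
        res = wcr.bootstrap_ci(fixture_cohort, lambda c: 0.7, reps=20, seed=0)
        assert res.lower == res.upper == 0.7

    def test_degenerate_replicates_counted(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 0, 0, 0])

        def stat(c):
            if not np.any(c.event == 1):
                raise ValueError("no events of target cause")
            return self._stat(c)

        res = wcr.bootstrap_ci(cohort, stat, reps=200, seed=1)
        assert res.n_degenerate > 0
        assert np.isfinite(res.lower) and res.lower <= res.upper

    def test_reps_validation(self, fixture_cohort):
        with pytest.raises(ValueError):
            wcr.bootstrap_ci(fixture_cohort, self._stat, reps=1, seed=0)
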