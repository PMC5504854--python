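import numpy as np
import pandas as pd
import pytest

import wcr
from wcr.weights import truncate_weights

from conftest import make_cohort


def _weight_set(values):
    table = pd.DataFrame(
        {
            "subject_id": np.arange(len(values)),
            "numerator_prob": 1.0,
            "denominator_prob": 1.0 / np.asarray(values, dtype=float),
            "raw_weight": np.asarray(values, dtype=float),
            "final_weight": np.asarray(values, dtype=float),
            "truncated": False,
        }
    )
    return wcr.WeightSet(table=table)


class TestPropensity:
    def test_intercept_only_equals_sample_proportion(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 1, 1], arms=["t", "t", "t", "c"], reference="c")
        fit = wcr.fit_propensity(cohort, "arm", [])
        treated = cohort.arm == "t"
        assert np.allclose(fit.fitted_probabilities[treated.to_numpy()], 0.75, atol=1e-6)

    def test_saturated_fit_recovers_cell_proportions(self):
        # X=0 cell: 1/2 treated; X=1 cell: 2/3 treated
        x = [0, 0, 1, 1, 1]
        arms = ["t", "c", "t", "t", "c"]
        cohort = make_cohort([1] * 5, [1] * 5, arms=arms, covs={"x": x}, reference="c")
        fit = wcr.fit_propensity(cohort, "arm", ["x"])
        p_t = fit.probabilities["t"].to_numpy()
        assert np.allclose(p_t[np.array(x) == 0], 0.5, atol=1e-5)
        assert np.allclose(p_t[np.array(x) == 1], 2 / 3, atol=1e-5)

    def test_single_level_outcome_errors(self):
        cohort = make_cohort([1, 2], [1, 1], arms=["t", "t"])
        with pytest.raises(ValueError, match="single level"):
            wcr.fit_propensity(cohort, "arm", [])

    def test_perfect_separation_raises(self):
        x = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        arms = ["c", "c", "c", "t", "t", "t"]
        cohort = make_cohort([1] * 6, [1] * 6, arms=arms, covs={"x": x}, reference="c")
        with pytest.raises(ValueError):
            wcr.fit_propensity(cohort, "arm", ["x"])

    def test_collinear_design_raises(self):
        cohort = make_cohort(
            [1, 2, 3, 4], [1, 1, 1, 1], arms=["t", "c", "t", "c"],
            covs={"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]}, reference="c",
        )
        with pytest.raises(ValueError, match="rank deficient"):
            wcr.fit_propensity(cohort, "arm", ["x", "y"])


class TestStabilizedWeights:
    def test_uninformative_covariates_give_unit_weights(self):
        cohort = make_cohort(
            [1, 2, 3, 4], [1, 1, 1, 1], arms=["t", "t", "t", "c"],
            covs={"x": [5.0, 5.0, 5.0, 5.0]}, reference="c",
        )
        fit = wcr.fit_propensity(cohort, "arm", [])
        ws = wcr.stabilized_weights(fit, None, cohort)
        assert np.allclose(ws.final_weight, 1.0, atol=1e-6)

    def test_hand_arithmetic_single_stage(self):
        # cells: X=0 -> P(t|X)=0.5, X=1 -> P(t|X)=0.75 (saturated fit);
        # marginal P(t)=4/6; a treated X=0 subject gets (4/6)/0.5 = 4/3
        x = [0, 0, 1, 1, 1, 1]
        arms = ["t", "c", "t", "t", "t", "c"]
        cohort = make_cohort([1] * 6, [1] * 6, arms=arms, covs={"x": x}, reference="c")
        fit = wcr.fit_propensity(cohort, "arm", ["x"])
        ws = wcr.stabilized_weights(fit, None, cohort)
        w0t = ws.final_weight[0]
        assert np.isclose(w0t, (4 / 6) / 0.5, atol=1e-5)

    def test_two_stage_control_weight_uses_only_stage1(self, sim_cohort):
        cohort, _ = sim_cohort
        work = cohort.data.copy()
        work["_case"] = (work["arm"] != "control").astype(int)
        tmp = wcr.CohortTable(work, reference_arm="control",
                              covariates=cohort.covariates + ["_case"])
        stage1 = wcr.fit_propensity(tmp, "_case", ["age", "ses"])
        case_mask = (cohort.arm != "control").to_numpy()
        stage2 = wcr.fit_propensity(cohort, "arm", ["age", "ses"], subset=case_mask)
        two = wcr.stabilized_weights(stage1, stage2, cohort)
        one = wcr.stabilized_weights(stage1, None, cohort)
        ctl = ~case_mask
        assert np.allclose(two.final_weight[ctl], one.final_weight[ctl], atol=1e-12)
        assert not np.allclose(two.final_weight[case_mask], one.final_weight[case_mask])

    def test_small_denominator_flagged(self):
        # an absurdly high floor forces every subject below it
        cohort = make_cohort([1, 2, 3, 4], [1] * 4, arms=["t", "t", "t", "c"], reference="c")
        fit = wcr.fit_propensity(cohort, "arm", [])
        ws = wcr.stabilized_weights(fit, None, cohort, probability_floor=0.9)
        assert len(ws.flagged_small_denominator) > 0

    def test_stabilization_mean_near_one(self, sim_cohort):
        cohort, _ = sim_cohort
        ws = wcr.iptw_from_cohort(cohort, truncation_percentile=None)
        assert abs(ws.mean() - 1.0) < 0.02
        # weighted arm totals approximate marginal arm proportions
        w = ws.align_to(cohort)
        arm = cohort.arm.to_numpy()
        for a in cohort.arms:
            frac_w = w[arm == a].sum() / w.sum()
            frac = np.mean(arm == a)
            assert abs(frac_w - frac) < 0.03


class TestTruncation:
    def test_hand_percentile_cap(self):
        ws = _weight_set([1.0] * 9 + [100.0])
        out = truncate_weights(ws, 90, "cap")
        # 90th percentile by linear interpolation on sorted weights:
        # position 0.9*(10-1)=8.1 between 1 and 100 -> 1 + 0.1*99 = 10.9
        assert np.isclose(out.cap_value, 10.9)
        assert np.isclose(out.final_weight.max(), 10.9)
        assert np.sum(out.table["truncated"]) == 1
        assert np.allclose(np.sort(out.final_weight)[:9], 1.0)

    def test_delete_mode_removals_recorded(self):
        ws = _weight_set([1.0] * 9 + [100.0])
        out = truncate_weights(ws, 90, "delete")
        assert len(out.table) == 9
        assert len(out.removed) == 1
        assert out.removed["raw_weight"].iloc[0] == 100.0

    def test_equal_weights_unchanged(self):
        for mode in ("cap", "delete"):
            out = truncate_weights(_weight_set([2.0] * 10), 99, mode)
            assert len(out.table) == 10
            assert np.allclose(out.final_weight, 2.0)

    def test_cap_idempotent(self):
        ws = _weight_set(list(np.linspace(0.5, 8, 20)))
        once = truncate_weights(ws, 95, "cap")
        twice = truncate_weights(once, 95, "cap")
        assert np.allclose(once.final_weight, twice.final_weight, atol=1e-12)

    def test_never_increases_and_bounds(self):
        rng = np.random.default_rng(0)
        ws = _weight_set(rng.lognormal(0, 1, 200))
        out = truncate_weights(ws, 99, "cap")
        assert np.all(out.final_weight <= ws.final_weight + 1e-15)
        assert np.all(out.final_weight <= out.cap_value + 1e-15)

    def test_low_percentile_rejected(self):
        with pytest.raises(ValueError, match="50"):
            truncate_weights(_weight_set([1, 2, 3]), 50, "cap")


class TestBalance:
    def test_identical_distributions_zero_smd(self):
        x = [1.0, 2.0, 3.0] * 2
        cohort = make_cohort([1] * 6, [1] * 6, arms=["t"] * 3 + ["c"] * 3,
                             covs={"x": x[:3] + x[:3]}, reference="c")
        bal = wcr.balance_diagnostics(cohort, None, ["x"])
        assert bal.max_abs_smd(weighted=False) < 1e-12

    def test_unit_weights_weighted_equals_unweighted(self, sim_cohort):
        cohort, _ = sim_cohort
        ones = _weight_set(np.ones(cohort.n))
        ones.table["subject_id"] = cohort.data["subject_id"].to_numpy()
        bal = wcr.balance_diagnostics(cohort, ones)
        assert np.allclose(
            bal.smd["smd_weighted"], bal.smd["smd_unweighted"], atol=1e-12
        )

    def test_weighting_improves_balance(self, sim_cohort):
        cohort, _ = sim_cohort
        ws = wcr.iptw_from_cohort(cohort)
        bal = wcr.balance_diagnostics(cohort, ws)
        assert bal.max_abs_smd(weighted=True) < bal.max_abs_smd(weighted=False)

    def test_zero_variance_flagged(self):
        cohort = make_cohort([1, 2, 3, 4], [1] * 4, arms=["t", "t", "c", "c"],
                             covs={"x": [1.0, 1.0, 1.0, 1.0]}, reference="c")
        bal = wcr.balance_diagnostics(cohort, None, ["x"])
        assert bal.max_abs_smd(weighted=False) == 0.0
        assert bal.flags
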