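"""Sequential trial conduct: recommendation, stopping, and full runs."""

import numpy as np
import pytest

from quasicrm import (
    DEFAULT_SKELETONS,
    DesignConfig,
    GradeDistribution,
    ModelEnsemble,
    RobustQuasiCRM,
    Scenario,
    TrialData,
    check_stop,
    recommend_dose,
    run_trial,
    table2_scenario,
)
from oracles import grid_posterior

THETA_ET = 0.47


def make_config(K=3, **kwargs):
    ens = ModelEnsemble.from_skeletons(DEFAULT_SKELETONS[:K])
    kwargs.setdefault("target_et", THETA_ET)
    return DesignConfig(ensemble=ens, **kwargs)


def degenerate_scenario(grade: int, J: int = 6) -> Scenario:
    probs = [0.0] * 4
    probs[grade] = 1.0
    return Scenario("degenerate", tuple(GradeDistribution(tuple(probs)) for _ in range(J)))


class TestRecommendDose:
    def test_closest_to_target(self):
        assert recommend_dose((0.10, 0.30, 0.50), 0.47 / 1.5, current_dose=2) == 2

    def test_tie_and_no_skip(self):
        """Equidistant estimates tie to the lower dose; the no-skip rule then
        caps the assignment at one level above the current dose."""
        got = recommend_dose((0.05, 0.10, 0.31, 0.32), 0.315, current_dose=1)
        assert got == 2
        unrestricted = recommend_dose((0.05, 0.10, 0.31, 0.32), 0.315,
                                      current_dose=1, escalation_restricted=False)
        assert unrestricted == 3  # the tie itself resolves to dose 3, not 4

    def test_no_escalation_past_top(self):
        assert recommend_dose((0.1, 0.2, 0.3), 0.32, current_dose=3) == 3

    def test_deescalation_may_skip(self):
        assert recommend_dose((0.10, 0.5, 0.7, 0.9), 0.12, current_dose=4) == 1


class TestCheckStop:
    def test_no_stop_on_empty_data(self):
        config = make_config()
        res = RobustQuasiCRM(TrialData(6), config.ensemble,
                             config.target_norm).fit()
        # prior overdose mass is well below the cutoff (grid-verified)
        _, _, prior_over = grid_posterior(DEFAULT_SKELETONS[0], np.zeros(6),
                                          np.zeros(6), target_norm=config.target_norm)
        assert prior_over < config.stop_cutoff
        assert not check_stop(res, config)

    def test_stops_after_repeated_grade4_at_lowest_dose(self):
        config = make_config(K=1)
        ens = ModelEnsemble.from_skeletons([DEFAULT_SKELETONS[2]])
        config = DesignConfig(ensemble=ens, target_et=THETA_ET)
        data = TrialData.from_scores([1] * 5, [1.0] * 5, n_doses=6)
        res = RobustQuasiCRM(data, ens, config.target_norm).fit()
        _, _, over = grid_posterior(DEFAULT_SKELETONS[2], data.counts(),
                                    data.score_sums(), target_norm=config.target_norm)
        assert over > 0.9
        assert res.prob_overdose == pytest.approx(over, rel=1e-6)
        assert check_stop(res, config)

    def test_cutoff_one_never_stops(self):
        config = make_config(stop_cutoff=1.0)
        data = TrialData.from_scores([1] * 10, [1.0] * 10, n_doses=6)
        res = RobustQuasiCRM(data, config.ensemble, config.target_norm).fit()
        assert not check_stop(res, config)


class TestRunTrial:
    def test_all_safe_scenario_climbs_and_selects_top(self):
        """With no toxicity anywhere the estimates sit far below the target,
        the trial escalates one level per cohort and selects the top dose."""
        result = run_trial(degenerate_scenario(0), make_config(), rng=1)
        assert not result.stopped
        assert result.selected_dose == 6
        doses = result.data.doses
        assert np.all(np.diff(doses) <= 1)
        assert list(doses[:6]) == [1, 2, 3, 4, 5, 6]
        assert result.n_patients == 20

    def test_all_grade4_scenario_stops_early(self):
        result = run_trial(degenerate_scenario(3), make_config(), rng=1)
        assert result.stopped
        assert result.selected_dose is None
        assert result.n_patients < 20

    def test_deterministic_given_seed(self):
        config = make_config()
        scenario = table2_scenario("A")
        a = run_trial(scenario, config, rng=7)
        b = run_trial(scenario, config, rng=7)
        assert list(a.data.doses) == list(b.data.doses)
        assert np.array_equal(a.data.y, b.data.y)
        assert a.selected_dose == b.selected_dose
        assert a.trace == b.trace

    def test_no_skip_property_across_seeds(self):
        config = make_config()
        scenario = table2_scenario("C")
        for seed in range(10):
            result = run_trial(scenario, config, rng=seed)
            assert np.all(np.diff(result.data.doses) <= 1)
            assert result.n_patients == config.max_n or result.stopped

    def test_selection_restricted_to_tried_doses(self):
        config = make_config()
        for seed in range(10):
            result = run_trial(table2_scenario("B"), config, rng=seed)
            if not result.stopped:
                assert result.n_per_dose()[result.selected_dose - 1] > 0

    def test_single_skeleton_matches_k1_ensemble_path(self):
        """A one-model ensemble must trace exactly the same trial as the
        plain single-skeleton design (the robust pipeline degenerates to
        Quasi-CRM at K=1)."""
        scenario = table2_scenario("A")
        single = make_config(K=1)
        # at K=1 model averaging, selection, and mixture stopping all coincide
        degenerate = make_config(K=1, use_bma=True, stop_under="bma")
        for seed in (0, 3, 11):
            u = np.random.default_rng(seed).random(single.max_n)
            a = run_trial(scenario, single, uniforms=u)
            b = run_trial(scenario, degenerate, uniforms=u)
            assert list(a.data.doses) == list(b.data.doses)
            assert a.selected_dose == b.selected_dose
            assert a.stopped == b.stopped

    def test_cohort_size_three(self):
        config = make_config(cohort_size=3)
        result = run_trial(degenerate_scenario(0), config, rng=2)
        doses = result.data.doses
        # patients within a cohort share a dose
        assert all(len(set(doses[i:i + 3])) == 1 for i in range(0, 18, 3))

    def test_trace_frame_exports(self):
        result = run_trial(table2_scenario("A"), make_config(), rng=4)
        frame = result.trace_frame()
        assert {"n", "dose", "selected_model", "pi_hat",
                "prob_overdose_d1"} <= set(frame.columns)
        assert len(frame) == len(result.trace)


class TestDesignConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"target_et": 0.0}, {"target_et": 2.0},
        {"start_dose": 0}, {"start_dose": 7},
        {"max_n": 2, "cohort_size": 3},
        {"stop_cutoff": 0.4}, {"stop_under": "sometimes"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_config(**kwargs)
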