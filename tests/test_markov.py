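"""Markov engine: stochasticity invariants, closed-form oracles, builders."""

import numpy as np
import pytest

from abdoscreen.markov import (MarkovModel, RewardModel, StateSpace,
                               TransitionError, TransitionModel,
                               aaa_initial_state, build_aaa_model,
                               build_cancer_model, build_no_disease_model,
                               cancer_initial_state, run_cohort,
                               run_cohorts_batch, validate_against_counts)
from abdoscreen.natural_history import STAGES, calibrate_diagnosis_rates
from abdoscreen.parameters import AnalysisSettings

from ._oracles import discounted_reward_closed_form

SETTINGS = AnalysisSettings()
NO_MORT = np.zeros(46)
FLAT_UTILITY = np.ones(46)


def _random_chain(rng, n_states):
    """A time-homogeneous chain with one absorbing state, strictly
    substochastic transient dynamics, and rewards on transient states."""
    names = tuple(f"s{i}" for i in range(n_states - 1)) + ("dead_other",)
    tags = {s: {} for s in names}
    tags["dead_other"] = {"dead_cause": "other"}
    space = StateSpace(names, frozenset({"dead_other"}), tags)
    T = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        row = rng.dirichlet(np.ones(n_states))
        row[-1] = max(row[-1], 0.1)  # keep absorption fast enough to truncate
        T[i] = row / row.sum()
    T[-1, -1] = 1.0
    trans = TransitionModel(space, T, NO_MORT)
    reward = np.append(rng.uniform(0.0, 500.0, n_states - 1), 0.0)
    umult = np.append(rng.uniform(0.1, 1.0, n_states - 1), 0.0)
    rewards = RewardModel(reward, umult, FLAT_UTILITY, np.zeros((n_states, n_states)))
    return MarkovModel(space, trans, rewards)


class TestEngineOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_discounted_rewards_match_fundamental_matrix(self, seed):
        """Engine totals on random time-homogeneous chains agree with the
        (I - dM)^-1 closed form to 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        model = _random_chain(rng, n)
        init = rng.dirichlet(np.ones(n))
        rate = float(rng.uniform(0.0, 0.06))
        settings = AnalysisSettings(discount_rate_costs=rate,
                                    discount_rate_qalys=rate)
        _, out = run_cohort(model, 55, settings, init)
        M = model.transitions.matrix(55)
        expected_cost = discounted_reward_closed_form(
            M, init, model.rewards.state_cost, rate, 45)
        expected_qaly = discounted_reward_closed_form(
            M, init, model.rewards.utility_multiplier, rate, 45)
        assert out.discounted_cost == pytest.approx(expected_cost, abs=1e-10)
        assert out.discounted_qaly == pytest.approx(expected_qaly, abs=1e-10)

    def test_batch_runner_matches_single_cohort_runner(self, default_params):
        """The vectorised engine is numerically identical to the per-cohort
        loop for the synthetic kidney model."""
        nh = default_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)
        model = build_cancer_model(nh, "control",
                                   default_params.other_cause_mortality["male"],
                                   rates, default_params.baseline_utilities["male"])
        dist = {"I": 0.5, "II": 0.2, "III": 0.2, "IV": 0.1}
        init = cancer_initial_state(model, "control", dist)
        ages = np.array([58, 64, 71])
        batch = run_cohorts_batch(model, ages, SETTINGS,
                                  np.tile(init, (3, 1)))
        for i, age in enumerate(ages):
            _, single = run_cohort(model, int(age), SETTINGS, init)
            assert batch["discounted_cost"][i] == pytest.approx(
                single.discounted_cost, abs=1e-10)
            assert batch["discounted_qaly"][i] == pytest.approx(
                single.discounted_qaly, abs=1e-10)
            assert batch["diagnoses"][i] == pytest.approx(
                single.diagnoses, abs=1e-10)


class TestInvariants:
    def test_occupancy_conserved_every_cycle(self, default_params):
        nh = default_params.diseases["colon"]
        rates = calibrate_diagnosis_rates(nh)
        model = build_cancer_model(nh, "screening",
                                   default_params.other_cause_mortality["female"],
                                   rates, default_params.baseline_utilities["female"])
        init = cancer_initial_state(model, "screening",
                                    {"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1})
        trace, _ = run_cohort(model, 60, SETTINGS, init)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = [model.space.index(s) for s in model.space.absorbing]
        absorbed = trace.occupancy[:, dead].sum(axis=1)
        assert (np.diff(absorbed) >= -1e-12).all()

    def test_row_sum_violation_is_reported(self):
        space = StateSpace(("a", "dead_other"), frozenset({"dead_other"}),
                           {"a": {}, "dead_other": {"dead_cause": "other"}})
        bad = np.array([[0.6, 0.3], [0.0, 1.0]])
        with pytest.raises(TransitionError, match="row"):
            TransitionModel(space, bad, NO_MORT)

    def test_higher_death_probability_weakly_reduces_life_years(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)
        mort = tiny_params.other_cause_mortality["male"]
        ly = []
        for mult in (1.0, 1.5):
            model = build_cancer_model(nh, "screening", np.clip(mort * mult, 0, 1),
                                       rates, tiny_params.baseline_utilities["male"])
            init = cancer_initial_state(model, "screening",
                                        {"I": 1.0, "II": 0, "III": 0, "IV": 0})
            _, out = run_cohort(model, 60, SETTINGS, init)
            ly.append(out.discounted_ly)
        assert ly[1] <= ly[0]

    def test_higher_discount_rate_weakly_reduces_totals(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)
        outs = []
        for rate in (0.015, 0.05):
            s = AnalysisSettings(discount_rate_costs=rate, discount_rate_qalys=rate)
            model = build_cancer_model(nh, "control",
                                       tiny_params.other_cause_mortality["male"],
                                       rates, tiny_params.baseline_utilities["male"])
            init = cancer_initial_state(model, "control",
                                        {"I": 1.0, "II": 0, "III": 0, "IV": 0})
            _, out = run_cohort(model, 60, s, init)
            outs.append(out)
        assert outs[1].discounted_qaly <= outs[0].discounted_qaly
        assert outs[1].discounted_cost <= outs[0].discounted_cost

    def test_zero_discount_equates_discounted_and_undiscounted(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)
        s = AnalysisSettings(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        model = build_cancer_model(nh, "control",
                                   tiny_params.other_cause_mortality["male"],
                                   rates, tiny_params.baseline_utilities["male"])
        init = cancer_initial_state(model, "control",
                                    {"I": 1.0, "II": 0, "III": 0, "IV": 0})
        _, out = run_cohort(model, 60, s, init)
        assert out.discounted_cost == pytest.approx(out.undiscounted_cost)
        assert out.discounted_qaly == pytest.approx(out.undiscounted_qaly)

    def test_deaths_by_cause_sum_to_dead_occupancy(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)
        model = build_cancer_model(nh, "screening",
                                   tiny_params.other_cause_mortality["male"],
                                   rates, tiny_params.baseline_utilities["male"])
        init = cancer_initial_state(model, "screening",
                                    {"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25})
        trace, out = run_cohort(model, 60, SETTINGS, init)
        dead_idx = [model.space.index(s) for s in model.space.absorbing]
        assert sum(out.deaths_by_cause.values()) == pytest.approx(
            trace.occupancy[-1, dead_idx].sum(), abs=1e-12)

    def test_state_cost_contribution_is_linear(self, tiny_params):
        """Doubling one state's per-cycle cost doubles that state's
        contribution to the discounted total."""
        nh = tiny_params.diseases["kidney"]
        rates = calibrate_diagnosis_rates(nh)

        def total_cost(later_cost):
            nh.treatment_cost["IV"]["later"] = later_cost
            model = build_cancer_model(nh, "screening",
                                       NO_MORT, rates, FLAT_UTILITY)
            init = cancer_initial_state(model, "screening",
                                        {"I": 0, "II": 0, "III": 0, "IV": 1.0})
            _, out = run_cohort(model, 60, SETTINGS, init)
            return out.discounted_cost

        c0, c1, c2 = total_cost(0.0), total_cost(10000.0), total_cost(20000.0)
        assert c2 - c1 == pytest.approx(c1 - c0, rel=1e-9)
        assert c2 - c0 == pytest.approx(2.0 * (c1 - c0), rel=1e-9)


class TestCancerModelStructure:
    def test_certain_stage4_mortality_absorbs_in_one_cycle(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        nh.cancer_mortality["IV"] = 1.0
        rates = calibrate_diagnosis_rates(nh)
        model = build_cancer_model(nh, "screening", NO_MORT, rates, FLAT_UTILITY)
        init = cancer_initial_state(model, "screening",
                                    {"I": 0, "II": 0, "III": 0, "IV": 1.0})
        trace, _ = run_cohort(model, 60, SETTINGS, init)
        assert trace.occupancy[1, model.space.index("dead_cancer")] == \
            pytest.approx(1.0)

    def test_no_mortality_conserves_alive_occupancy(self, tiny_params):
        nh = tiny_params.diseases["kidney"]
        nh.cancer_mortality = {s: 0.0 for s in STAGES}
        rates = calibrate_diagnosis_rates(nh)
        model = build_cancer_model(nh, "control", NO_MORT, rates, FLAT_UTILITY)
        init = cancer_initial_state(model, "control",
                                    {"I": 1.0, "II": 0, "III": 0, "IV": 0})
        trace, _ = run_cohort(model, 55, SETTINGS, init)
        alive = model.transitions.alive
        np.testing.assert_allclose(trace.occupancy[:, alive].sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_null_effect_when_nothing_differs_by_stage(self, tiny_params):
        """With zero cancer mortality, zero treatment costs and unit utility
        multipliers, the stage shift is inert: both arms produce identical
        lifetime Markov outcomes."""
        nh = tiny_params.diseases["kidney"]
        nh.cancer_mortality = {s: 0.0 for s in STAGES}
        nh.treatment_cost = {s: {"year1": 0.0, "later": 0.0} for s in STAGES}
        nh.utility_multiplier = {s: {"year1": 1.0, "later": 1.0} for s in STAGES}
        rates = calibrate_diagnosis_rates(nh)
        mort = tiny_params.other_cause_mortality["male"]
        util = tiny_params.baseline_utilities["male"]
        outs = {}
        for arm in ("screening", "control"):
            model = build_cancer_model(nh, arm, mort, rates, util)
            init = cancer_initial_state(
                model, arm, {"I": 0.5, "II": 0.2, "III": 0.2, "IV": 0.1})
            _, outs[arm] = run_cohort(model, 62, SETTINGS, init)
        assert outs["screening"].discounted_qaly == pytest.approx(
            outs["control"].discounted_qaly, abs=1e-12)
        assert outs["screening"].discounted_cost == pytest.approx(
            outs["control"].discounted_cost, abs=1e-12)


class TestAAAModel:
    def test_no_rupture_no_operative_mortality_no_aaa_deaths(self, default_params):
        spec = default_params.copy().aaa()
        spec.rupture_rate = {"small": 0.0, "medium": 0.0, "large": 0.0}
        spec.elective_repair["operative_mortality"] = 0.0
        for arm in ("screening", "control"):
            model = build_aaa_model(spec, arm, NO_MORT, FLAT_UTILITY)
            init = aaa_initial_state(model, arm, spec.size_distribution)
            _, out = run_cohort(model, 60, SETTINGS, init)
            assert out.deaths_by_cause.get("disease", 0.0) == pytest.approx(0.0)

    def test_certain_large_rupture_with_no_survival_kills_next_cycle(
            self, default_params):
        spec = default_params.copy().aaa()
        spec.rupture_rate["large"] = 1.0
        spec.emergency_repair["survival"] = 0.0
        model = build_aaa_model(spec, "control", NO_MORT, FLAT_UTILITY)
        init = aaa_initial_state(model, "control",
                                 {"small": 0.0, "medium": 0.0, "large": 1.0})
        trace, _ = run_cohort(model, 60, SETTINGS, init)
        assert trace.occupancy[1, model.space.index("dead_aaa")] == \
            pytest.approx(1.0)

    def test_surveillance_prevents_aaa_deaths(self, default_params):
        """Screen-detected AAA under surveillance with elective repair incurs
        fewer aneurysm deaths than the undetected natural course."""
        spec = default_params.aaa()
        mort = default_params.other_cause_mortality["male"]
        util = default_params.baseline_utilities["male"]
        deaths = {}
        for arm in ("screening", "control"):
            model = build_aaa_model(spec, arm, mort, util)
            init = aaa_initial_state(model, arm, spec.size_distribution)
            _, out = run_cohort(model, 65, SETTINGS, init)
            deaths[arm] = out.deaths_by_cause.get("disease", 0.0)
        assert deaths["screening"] < deaths["control"]

    def test_three_cycle_enumeration_oracle(self, default_params):
        """Brute-force enumeration of the control arm over 3 cycles from the
        large state matches the engine trace."""
        spec = default_params.copy().aaa()
        model = build_aaa_model(spec, "control", NO_MORT, FLAT_UTILITY)
        init = aaa_initial_state(model, "control",
                                 {"small": 0.0, "medium": 0.0, "large": 1.0})
        r = spec.rupture_rate["large"]
        surv = spec.emergency_repair["survival"]
        stay = 1.0 - r
        dead = post = 0.0
        large = 1.0
        for _ in range(3):
            dead += large * r * (1.0 - surv)
            post += large * r * surv
            large *= stay
        settings = AnalysisSettings(horizon_age=63)
        trace, _ = run_cohort(model, 60, settings, init)
        assert trace.occupancy[3, model.space.index("dead_aaa")] == \
            pytest.approx(dead, abs=1e-12)
        assert trace.occupancy[3, model.space.index("post_repair")] == \
            pytest.approx(post, abs=1e-12)


class TestNoDiseaseModel:
    def test_zero_mortality_life_years_equal_horizon(self):
        model = build_no_disease_model(FLAT_UTILITY, NO_MORT)
        s = AnalysisSettings(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        _, out = run_cohort(model, 60, s, np.array([1.0, 0.0]))
        assert out.undiscounted_ly == pytest.approx(40.0)

    def test_constant_mortality_matches_geometric_series(self):
        """With constant annual death probability p and trapezoidal rewards,
        expected life years are sum over cycles of the mid-cycle survivors."""
        p = 0.07
        model = build_no_disease_model(FLAT_UTILITY, np.full(46, p))
        s = AnalysisSettings(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        _, out = run_cohort(model, 55, s, np.array([1.0, 0.0]))
        n = 45
        survivors = (1.0 - p) ** np.arange(n + 1)
        expected = (0.5 * (survivors[:-1] + survivors[1:])).sum()
        assert out.undiscounted_ly == pytest.approx(expected, abs=1e-12)

    def test_unit_utility_makes_qalys_equal_life_years(self):
        model = build_no_disease_model(FLAT_UTILITY, np.full(46, 0.03))
        _, out = run_cohort(model, 60, SETTINGS, np.array([1.0, 0.0]))
        assert out.discounted_qaly == pytest.approx(out.discounted_ly)


class TestCountValidation:
    def test_zero_prevalence_expects_zero(self, tiny_params):
        for block in tiny_params.diseases.values():
            if hasattr(block, "incidence"):
                block.incidence = {s: np.zeros(46) for s in ("male", "female")}
            else:
                block.prevalence = {s: np.zeros(46) for s in ("male", "female")}
        counts = validate_against_counts(tiny_params, scale=4019)
        assert (counts["expected_count"] == 0).all()

    def test_exact_poisson_interval_for_mean_ten(self, tiny_params):
        """Expected count 10 carries the exact (Garwood) 95% interval
        [4.80, 18.39]."""
        sf = tiny_params.diseases["kidney_cysts"]
        sf.prevalence = {s: np.full(46, 10.0 / 4019.0) for s in ("male", "female")}
        counts = validate_against_counts(tiny_params, scale=4019)
        row = counts.loc["kidney_cysts"]
        assert row["expected_count"] == pytest.approx(10.0)
        assert row["poisson_lo"] == pytest.approx(4.795, abs=0.005)
        assert row["poisson_hi"] == pytest.approx(18.39, abs=0.005)
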