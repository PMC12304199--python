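"""Parameter container: validation, path addressing, serialisation,
scenarios and PSA draws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abdoscreen.parameters import (Distribution, ParameterSet,
                                   ParameterValidationError, ScenarioError,
                                   ScenarioSpec, apply_scenario, get_parameter,
                                   load_parameter_set, parameter_sets_equal,
                                   sample_psa_draws, save_parameter_set,
                                   set_parameter, validate_parameter_set)


class TestValidation:
    def test_default_set_has_eleven_modelled_diseases(self, default_params):
        """Ten cancers plus AAA are modelled long-term; the remainder are
        secondary-finding categories."""
        cancers = default_params.cancers()
        assert len(cancers) == 10
        assert default_params.aaa() is not None
        assert len(default_params.secondary_findings()) >= 5

    def test_negative_cost_rejected(self, tiny_params):
        tiny_params.diseases["kidney"].treatment_cost["I"]["year1"] = -5.0
        with pytest.raises(ParameterValidationError, match="treatment_cost.I"):
            validate_parameter_set(tiny_params)

    def test_probability_outside_unit_interval_rejected(self, tiny_params):
        tiny_params.diseases["kidney"].sensitivity["II"] = 1.4
        with pytest.raises(ParameterValidationError, match="sensitivity.II"):
            validate_parameter_set(tiny_params)

    def test_cohort_weights_must_sum_to_one(self, tiny_params):
        tiny_params.cohorts[0].weight = 0.6
        with pytest.raises(ParameterValidationError, match="weights sum"):
            validate_parameter_set(tiny_params)

    def test_stage_distribution_must_be_simplex(self, tiny_params):
        tiny_params.diseases["kidney"].current_stage_distribution["I"] = 0.6
        with pytest.raises(ParameterValidationError, match="stage_distribution"):
            validate_parameter_set(tiny_params)

    def test_beta_on_a_cost_is_a_type_mismatch(self, tiny_params):
        tiny_params.psa_distributions[
            "diseases.kidney.treatment_cost.I.year1"] = Distribution(
                "beta", {"alpha": 2.0, "beta": 2.0})
        with pytest.raises(ParameterValidationError, match="non-probability"):
            validate_parameter_set(tiny_params)

    def test_unresolvable_distribution_path_rejected(self, tiny_params):
        tiny_params.psa_distributions["diseases.nonexistent.thing"] = Distribution(
            "beta", {"alpha": 2.0, "beta": 2.0})
        with pytest.raises(ParameterValidationError, match="does not resolve"):
            validate_parameter_set(tiny_params)


class TestPathAccess:
    def test_get_and_set_roundtrip(self, tiny_params):
        path = "diseases.kidney.dwell_time.II"
        assert get_parameter(tiny_params, path) == 1.5
        set_parameter(tiny_params, path, 2.5)
        assert get_parameter(tiny_params, path) == 2.5

    def test_dict_leaf_update_preserves_other_keys(self, tiny_params):
        set_parameter(tiny_params, "diseases.kidney.current_stage_distribution",
                      {"I": 0.5, "II": 0.1, "III": 0.15, "IV": 0.25})
        dist = tiny_params.diseases["kidney"].current_stage_distribution
        assert dist["I"] == 0.5 and abs(sum(dist.values()) - 1) < 1e-12

    def test_unknown_path_raises(self, tiny_params):
        with pytest.raises(KeyError):
            get_parameter(tiny_params, "diseases.kidney.no_such_field")


class TestSerialisation:
    def test_roundtrip_is_identity(self, default_params, tmp_path):
        """Write-then-load reproduces the set field by field."""
        manifest = save_parameter_set(default_params, tmp_path / "params.yaml")
        loaded = load_parameter_set(manifest)
        assert parameter_sets_equal(default_params, loaded)

    def test_overwrite_requires_force(self, tiny_params, tmp_path):
        save_parameter_set(tiny_params, tmp_path / "p.yaml")
        with pytest.raises(FileExistsError):
            save_parameter_set(tiny_params, tmp_path / "p.yaml")
        save_parameter_set(tiny_params, tmp_path / "p.yaml", force=True)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameter_set(tmp_path / "absent.yaml")


class TestScenarios:
    def test_identity_scenario_is_fixed_point(self, default_params):
        out = apply_scenario(default_params, ScenarioSpec("identity"))
        assert parameter_sets_equal(out, default_params)
        again = apply_scenario(out, ScenarioSpec("identity"))
        assert parameter_sets_equal(again, default_params)

    def test_base_set_is_never_mutated(self, default_params):
        before = default_params.copy()
        apply_scenario(default_params, ScenarioSpec(
            "double_kidney", prevalence_multipliers={"kidney": 2.0}))
        assert parameter_sets_equal(default_params, before)

    def test_prevalence_multiplier_scales_only_its_target(self, default_params):
        out = apply_scenario(default_params, ScenarioSpec(
            "double_kidney", prevalence_multipliers={"kidney": 2.0}))
        assert out.diseases["kidney"].incidence_scale == pytest.approx(
            2.0 * default_params.diseases["kidney"].incidence_scale)
        assert parameter_sets_equal(out.diseases["colon"],
                                    default_params.diseases["colon"]) or \
            out.diseases["colon"].incidence_scale == \
            default_params.diseases["colon"].incidence_scale

    def test_discount_override_applies_to_costs_and_qalys(self, default_params):
        out = apply_scenario(default_params, ScenarioSpec(
            "discount_15", discount_rate_costs=0.015, discount_rate_qalys=0.015))
        assert out.settings.discount_rate_costs == 0.015
        assert out.settings.discount_rate_qalys == 0.015

    def test_unknown_modifier_target_is_named(self, default_params):
        with pytest.raises(ScenarioError, match="spleenwort"):
            apply_scenario(default_params, ScenarioSpec(
                "bad", prevalence_multipliers={"spleenwort": 2.0}))

    def test_disease_mask_drops_blocks_and_their_distributions(self, default_params):
        out = apply_scenario(default_params, ScenarioSpec(
            "aaa_only", disease_mask=["aaa"]))
        assert set(out.diseases) == {"aaa"}
        assert all(not p.startswith("diseases.kidney")
                   for p in out.psa_distributions)

    def test_empty_mask_rejected(self, default_params):
        with pytest.raises(ParameterValidationError):
            apply_scenario(default_params, ScenarioSpec("none", disease_mask=[]))


class TestPSADraws:
    def test_all_fixed_distributions_reproduce_base(self, tiny_params):
        tiny_params.psa_distributions = {
            "diseases.kidney.coverage": Distribution("fixed", {"value": 1.0})}
        draws = sample_psa_draws(tiny_params, 5, seed=3)
        assert all(parameter_sets_equal(d, tiny_params) for d in draws)

    def test_same_seed_gives_identical_sequences(self, tiny_params):
        tiny_params.psa_distributions = {
            "diseases.kidney.sensitivity.I": Distribution(
                "beta", {"alpha": 8.0, "beta": 2.0}),
            "diseases.kidney.dwell_time.I": Distribution(
                "lognormal", {"mu": 1.0, "sigma": 0.2}),
        }
        a = sample_psa_draws(tiny_params, 10, seed=11)
        b = sample_psa_draws(tiny_params, 10, seed=11)
        for x, y in zip(a, b):
            assert parameter_sets_equal(x, y)
        c = sample_psa_draws(tiny_params, 10, seed=12)
        assert not all(parameter_sets_equal(x, y) for x, y in zip(a, c))

    def test_beta_draw_moments_match_analytic(self, tiny_params):
        """beta(2,2) has mean 1/2 and sd 1/sqrt(20); the empirical mean over
        10000 draws must fall within 3 standard errors."""
        tiny_params.psa_distributions = {
            "diseases.kidney.sensitivity.I": Distribution(
                "beta", {"alpha": 2.0, "beta": 2.0})}
        draws, values, _ = sample_psa_draws(tiny_params, 10000, seed=5,
                                            return_values=True)
        mean = values["diseases.kidney.sensitivity.I"].mean()
        se = (1.0 / np.sqrt(20.0)) / np.sqrt(10000)
        assert abs(mean - 0.5) < 3 * se

    def test_dirichlet_draws_stay_on_simplex(self, tiny_params):
        tiny_params.psa_distributions = {
            "diseases.kidney.current_stage_distribution": Distribution(
                "dirichlet", {f"alpha_{s}": 10.0 for s in ("I", "II", "III", "IV")})}
        for draw in sample_psa_draws(tiny_params, 20, seed=7):
            dist = draw.diseases["kidney"].current_stage_distribution
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)


class TestDistribution:
    @pytest.mark.parametrize("kind,params", [
        ("beta", {"alpha": 0.0, "beta": 1.0}),
        ("gamma", {"shape": 1.0, "scale": -2.0}),
        ("lognormal", {"mu": 0.0, "sigma": 0.0}),
        ("dirichlet", {"alpha_a": 1.0, "alpha_b": -1.0}),
        ("fixed", {"value": 1.0, "extra": 2.0}),
        ("weibull", {"shape": 1.0}),
    ])
    def test_invalid_parameterisations_rejected(self, kind, params):
        assert Distribution(kind, params).validate("p")

    @given(st.floats(0.05, 0.95), st.floats(5.0, 200.0))
    def test_beta_mean_parameterisation(self, mean, kappa):
        from abdoscreen.synthetic import _beta_params

        p = _beta_params(mean, kappa)
        assert p["alpha"] / (p["alpha"] + p["beta"]) == pytest.approx(mean)
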