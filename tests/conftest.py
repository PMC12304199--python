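import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    """The deterministic paper-like parameter set (study conditions)."""
    from abdoscreen import generate_default_parameters

    return generate_default_parameters()


@pytest.fixture(scope="session")
def basecase_result(default_params):
    """Deterministic basecase evaluation, shared across tests."""
    from abdoscreen import pipeline

    return pipeline.evaluate(default_params)


@pytest.fixture(scope="session")
def basecase_psa(default_params):
    """The probabilistic basecase (2000 draws, fixed seed)."""
    from abdoscreen.psa import run_psa

    return run_psa(default_params, 2000, seed=20250901)


@pytest.fixture()
def tiny_params():
    """A minimal hand-built parameter set: one cancer, one secondary finding,
    two cohorts.  Cheap enough for per-test mutation."""
    import abdoscreen.natural_history as nhm
    from abdoscreen.natural_history import (CancerNaturalHistory,
                                            SecondaryFindingSpec)
    from abdoscreen.parameters import (AnalysisSettings, CohortSpec,
                                       ParameterSet, validate_parameter_set)
    from abdoscreen.pathway import DiagnosticPathway, default_cost_schedule

    n = nhm.N_AGES
    nh = CancerNaturalHistory(
        organ="kidney",
        incidence={"male": np.full(n, 8e-4), "female": np.full(n, 4e-4)},
        dwell_time={"I": 3.0, "II": 1.5, "III": 1.0, "IV": 1.0},
        current_stage_distribution={"I": 0.4, "II": 0.15, "III": 0.18, "IV": 0.27},
        sensitivity={"I": 0.8, "II": 0.85, "III": 0.9, "IV": 0.9},
        coverage=1.0,
        cancer_mortality={"I": 0.02, "II": 0.05, "III": 0.1, "IV": 0.3},
        treatment_cost={"I": {"year1": 8000.0, "later": 300.0},
                        "II": {"year1": 10000.0, "later": 500.0},
                        "III": {"year1": 14000.0, "later": 900.0},
                        "IV": {"year1": 30000.0, "later": 10000.0}},
        utility_multiplier={"I": {"year1": 0.95, "later": 0.98},
                            "II": {"year1": 0.92, "later": 0.96},
                            "III": {"year1": 0.85, "later": 0.92},
                            "IV": {"year1": 0.7, "later": 0.75}},
        pathway_id="cancer_kidney",
    )
    sf = SecondaryFindingSpec(
        organ="kidney", category="serious",
        prevalence={"male": np.full(n, 0.03), "female": np.full(n, 0.03)},
        pathway_id="secondary_kidney", name="kidney_cysts")
    ages = np.arange(55, 101).astype(float)
    mort = {s: np.clip(0.004 * np.exp(0.09 * (ages - 55)), 0, 0.999)
            for s in ("male", "female")}
    util = {s: np.clip(0.83 - 0.004 * (ages - 55), 0.3, 1.0)
            for s in ("male", "female")}
    ps = ParameterSet(
        cohorts=[CohortSpec(60, "male", 0.5), CohortSpec(65, "female", 0.5)],
        diseases={"kidney": nh, "kidney_cysts": sf},
        cost_schedule=default_cost_schedule(),
        pathways={
            "cancer_kidney": DiagnosticPathway(
                "cancer_kidney", [("ct", 140.0, 1.0), ("clinic", 170.0, 1.0)]),
            "secondary_kidney": DiagnosticPathway(
                "secondary_kidney", [("ultrasound", 55.0, 1.0)]),
        },
        other_cause_mortality=mort,
        baseline_utilities=util,
        settings=AnalysisSettings(),
    )
    validate_parameter_set(ps)
    return ps
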