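"""Synthetic parameter sets emulating the structure of the study inputs.

The detailed inputs such a model needs are not available as a public bundled
dataset, so this module generates complete, internally consistent stand-ins.  The
paper-like generator targets the printed anchors — roughly 10 screen-detected
kidney cancers, 10 other cancers, 60 AAA and well over 100 serious secondary
findings per 4019 people scanned, the exact incremental screening cost
schedule, and the qualitative pattern of per-disease contributions (AAA the
dominant positive, kidney secondary findings the dominant negative) — while
individual natural-history values are realistic magnitudes, not claims about
the study's supplement.

All values are synthetic; the random generator is used only by the fuzzing
(`target_pattern="random"`) variant, the paper-like set is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .natural_history import (AGE_GRID, AGE_MIN, N_AGES, SEXES, STAGES,
                              AAASpec, CancerNaturalHistory,
                              SecondaryFindingSpec)
from .parameters import (AnalysisSettings, CohortSpec, Distribution,
                         ParameterSet, validate_parameter_set)
from .pathway import DiagnosticPathway, default_cost_schedule


@dataclass
class SyntheticConfig:
    seed: int = 0
    scale: int = 4019          # cohort size used for count-style validation
    target_pattern: str = "paper_like"  # paper_like | random

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("scale must be >= 1")


def generate_life_table(seed: int = 0, smoking_hazard_ratio: float = 1.0,
                        jitter: float = 0.0) -> dict[str, np.ndarray]:
    """Annual other-cause death probabilities for ages 55-100, by sex.

    A Gompertz hazard (exponential increase with age) is the baseline;
    smoking adjustment multiplies on the hazard scale, turning an annual
    probability p into 1 - (1 - p)^hr, which preserves [0, 1] and composes
    multiplicatively.  ``jitter`` adds seeded lognormal noise for fuzzing.
    """
    if smoking_hazard_ratio <= 0:
        raise ValueError("smoking hazard ratio must be > 0")
    rng = np.random.default_rng(seed)
    table = {}
    for sex, a0, b in (("male", 0.0046, 0.089), ("female", 0.0031, 0.093)):
        hazard = a0 * np.exp(b * (AGE_GRID - AGE_MIN).astype(float))
        if jitter > 0:
            hazard = hazard * rng.lognormal(0.0, jitter, size=hazard.shape)
        p = 1.0 - np.exp(-hazard)
        p = 1.0 - (1.0 - p) ** smoking_hazard_ratio
        if (p >= 1.0).any():
            warnings.warn("life-table probabilities clamped below 1", stacklevel=2)
            p = np.clip(p, 0.0, 1.0 - 1e-9)
        table[sex] = p
    return table


def _baseline_utilities() -> dict[str, np.ndarray]:
    ages = (AGE_GRID - AGE_MIN).astype(float)
    return {"male": np.clip(0.832 - 0.0042 * ages, 0.3, 1.0),
            "female": np.clip(0.814 - 0.0040 * ages, 0.3, 1.0)}


def _cohorts() -> list[CohortSpec]:
    """Age/sex cohorts 55-81; basecase weight on the screening-eligible 55-74,
    declining with age, zero on 75-81 (activated by the trial-age scenario)."""
    cohorts = []
    raw = {}
    for sex, share in (("male", 0.54), ("female", 0.46)):
        for age in range(55, 82):
            w = share * math.exp(-0.055 * (age - 55)) if age <= 74 else 0.0
            raw[(age, sex)] = w
    total = sum(raw.values())
    for (age, sex), w in raw.items():
        cohorts.append(CohortSpec(age, sex, w / total))
    return cohorts


def _age_curve(rate65: float, slope: float = 0.05) -> np.ndarray:
    return np.clip(rate65 * np.exp(slope * (AGE_GRID - 65).astype(float)), 0.0, 1.0)


# organ: (incidence per person-year at 65 M/F, dwell I-IV, sensitivity I-IV,
#         coverage, symptomatic stage distribution, annual cancer mortality I-IV)
_CANCERS: dict[str, dict] = {
    "kidney": dict(inc=(1.05e-3, 5.2e-4), dwell=(3.0, 1.5, 1.2, 1.0),
                   sens=(0.75, 0.85, 0.92, 0.95), cov=1.0,
                   sympt=(0.42, 0.12, 0.18, 0.28),
                   mort=(0.025, 0.050, 0.095, 0.280), pathway="cancer_kidney"),
    "liver": dict(inc=(4.2e-4, 1.8e-4), dwell=(0.9, 0.6, 0.5, 0.5),
                  sens=(0.50, 0.60, 0.70, 0.80), cov=1.0,
                  sympt=(0.12, 0.15, 0.25, 0.48),
                  mort=(0.330, 0.380, 0.480, 0.620), pathway="cancer_generic"),
    "stomach": dict(inc=(3.0e-4, 1.3e-4), dwell=(1.5, 1.0, 0.8, 0.7),
                    sens=(0.15, 0.25, 0.40, 0.55), cov=0.9,
                    sympt=(0.18, 0.16, 0.22, 0.44),
                    mort=(0.090, 0.130, 0.230, 0.500), pathway="cancer_generic"),
    "oesophagus": dict(inc=(5.0e-4, 1.7e-4), dwell=(1.0, 0.8, 0.6, 0.6),
                       sens=(0.15, 0.20, 0.25, 0.30), cov=0.3,
                       sympt=(0.15, 0.15, 0.30, 0.40),
                       mort=(0.080, 0.150, 0.300, 0.550), pathway="cancer_generic"),
    "pancreas": dict(inc=(9.0e-4, 7.0e-4), dwell=(0.8, 0.5, 0.4, 0.4),
                     sens=(0.55, 0.65, 0.70, 0.75), cov=1.0,
                     sympt=(0.08, 0.10, 0.22, 0.60),
                     mort=(0.420, 0.500, 0.580, 0.660), pathway="cancer_generic"),
    "upper_urinary_tract": dict(inc=(1.3e-4, 6.5e-5), dwell=(2.5, 1.5, 1.0, 1.0),
                                sens=(0.60, 0.70, 0.80, 0.85), cov=1.0,
                                sympt=(0.35, 0.15, 0.20, 0.30),
                                mort=(0.040, 0.070, 0.130, 0.300),
                                pathway="cancer_kidney"),
    "colon": dict(inc=(1.9e-3, 1.3e-3), dwell=(3.0, 2.0, 1.5, 1.0),
                  sens=(0.15, 0.20, 0.26, 0.32), cov=0.4,
                  sympt=(0.15, 0.25, 0.30, 0.30),
                  mort=(0.008, 0.025, 0.080, 0.350), pathway="cancer_colon"),
    "adrenal": dict(inc=(3.2e-5, 2.8e-5), dwell=(3.0, 2.0, 1.0, 1.0),
                    sens=(0.90, 0.92, 0.95, 0.95), cov=1.0,
                    sympt=(0.30, 0.20, 0.20, 0.30),
                    mort=(0.080, 0.110, 0.200, 0.450), pathway="cancer_generic"),
    "gallbladder": dict(inc=(4.0e-5, 7.0e-5), dwell=(0.8, 0.6, 0.5, 0.5),
                        sens=(0.30, 0.45, 0.60, 0.70), cov=1.0,
                        sympt=(0.10, 0.12, 0.25, 0.53),
                        mort=(0.330, 0.380, 0.480, 0.610), pathway="cancer_generic"),
    "lymphoma": dict(inc=(1.0e-4, 8.0e-5), dwell=(6.0, 5.0, 4.0, 3.0),
                     sens=(0.50, 0.55, 0.60, 0.70), cov=0.9,
                     sympt=(0.20, 0.20, 0.25, 0.35),
                     mort=(0.045, 0.050, 0.060, 0.080), pathway="cancer_generic"),
}

# treatment costs GBP/year (kidney-derived schedule applied to all cancers):
# first year after diagnosis, then subsequent years (stage IV: ongoing systemic therapy)
_TREATMENT_COST = {"I": {"year1": 8000.0, "later": 300.0},
                   "II": {"year1": 10000.0, "later": 450.0},
                   "III": {"year1": 14000.0, "later": 900.0},
                   "IV": {"year1": 30000.0, "later": 10000.0}}
_UTILITY_MULT = {"I": {"year1": 0.95, "later": 0.98},
                 "II": {"year1": 0.92, "later": 0.96},
                 "III": {"year1": 0.85, "later": 0.92},
                 "IV": {"year1": 0.70, "later": 0.75}}

# secondary findings: (organ, category, prevalence at 65 (age slope 0), pathway, cost)
_SECONDARY: list[tuple[str, str, str, float, str, float]] = [
    ("kidney_cysts_stones", "kidney", "serious", 0.030, "secondary_kidney", 320.0),
    ("kidney_followup_fp", "kidney", "false_positive", 0.150, "fp_kidney", 95.0),
    ("liver_lesion", "liver", "serious", 0.004, "secondary_minor_imaging", 120.0),
    ("liver_followup_fp", "liver", "false_positive", 0.004, "fp_imaging", 80.0),
    ("pancreas_cyst", "pancreas", "serious", 0.006, "secondary_pancreas", 150.0),
    ("adrenal_incidentaloma", "adrenal", "serious", 0.007, "secondary_minor_imaging", 120.0),
    ("gallbladder_polyp", "gallbladder", "serious", 0.008, "secondary_gallbladder", 70.0),
    ("colon_wall_thickening", "colon", "serious", 0.002, "secondary_colon", 60.0),
    ("uut_finding", "upper_urinary_tract", "serious", 0.001, "secondary_minor_imaging", 120.0),
    ("lymph_nodes_spleen", "lymph_nodes_spleen", "serious", 0.0006,
     "secondary_minor_imaging", 120.0),
    ("other_followup_fp", "misc", "false_positive", 0.035, "fp_generic", 45.0),
    ("minor_findings", "misc", "minor", 0.220, "none", 0.0),
]


def _pathways() -> dict[str, DiagnosticPathway]:
    def pw(pid: str, resources: list[tuple[str, float, float]]) -> DiagnosticPathway:
        return DiagnosticPathway(pid, resources)

    return {p.pathway_id: p for p in [
        pw("cancer_kidney", [("ct_chest_abdo_pelvis", 140.0, 1.0),
                             ("urology_clinic", 170.0, 1.0),
                             ("mdt_review", 110.0, 1.0)]),
        pw("cancer_generic", [("contrast_ct", 140.0, 1.0),
                              ("specialist_clinic", 170.0, 1.0),
                              ("biopsy", 260.0, 0.7),
                              ("mdt_review", 110.0, 1.0)]),
        pw("cancer_colon", [("colonoscopy", 560.0, 1.0),
                            ("specialist_clinic", 170.0, 1.0),
                            ("mdt_review", 110.0, 1.0)]),
        pw("aaa_confirm", [("aortic_ultrasound", 62.0, 1.0),
                           ("vascular_clinic", 140.0, 1.0)]),
        pw("secondary_kidney", [("renal_ultrasound", 55.0, 1.0),
                                ("ct_urogram", 130.0, 0.5),
                                ("urology_clinic", 170.0, 1.0),
                                ("stone_clinic_followup", 30.0, 1.0)]),
        pw("fp_kidney", [("renal_ultrasound", 55.0, 1.0),
                         ("urology_clinic", 40.0, 1.0)]),
        pw("fp_generic", [("gp_or_clinic_followup", 45.0, 1.0)]),
        pw("secondary_pancreas", [("mri_pancreas", 150.0, 1.0)]),
        pw("secondary_gallbladder", [("ultrasound", 70.0, 1.0)]),
        pw("secondary_colon", [("gp_followup", 60.0, 1.0)]),
        pw("secondary_minor_imaging", [("follow_up_imaging", 120.0, 1.0)]),
        pw("fp_imaging", [("follow_up_imaging", 80.0, 1.0)]),
    ]}


def _aaa_spec() -> AAASpec:
    return AAASpec(
        prevalence={"male": np.clip(0.024 + 0.0010 * (AGE_GRID - 65).astype(float),
                                    0.002, 1.0),
                    "female": np.clip(0.008 + 0.0004 * (AGE_GRID - 65).astype(float),
                                      0.001, 1.0)},
        size_distribution={"small": 0.62, "medium": 0.23, "large": 0.15},
        growth={"small_to_medium": 0.025, "medium_to_large": 0.085},
        rupture_rate={"small": 0.0003, "medium": 0.005, "large": 0.050},
        elective_repair={"operative_mortality": 0.037, "cost": 12000.0},
        emergency_repair={"survival": 0.342, "cost": 18500.0},
        surveillance_cost={"small": 85.0, "medium": 170.0},
        pathway_id="aaa_confirm",
    )


def _beta_params(mean: float, kappa: float) -> dict[str, float]:
    return {"alpha": mean * kappa, "beta": (1.0 - mean) * kappa}


def _lognormal_params(mean: float, sigma: float) -> dict[str, float]:
    return {"mu": math.log(mean) - 0.5 * sigma * sigma, "sigma": sigma}


def _gamma_params(mean: float, cv: float = 0.2) -> dict[str, float]:
    shape = 1.0 / (cv * cv)
    return {"shape": shape, "scale": mean / shape}


def _psa_distributions(ps: ParameterSet) -> dict[str, Distribution]:
    dists: dict[str, Distribution] = {}
    for name, nh in ps.cancers().items():
        base = f"diseases.{name}"
        for s in STAGES:
            dists[f"{base}.dwell_time.{s}"] = Distribution(
                "lognormal", _lognormal_params(nh.dwell_time[s], 0.25))
            dists[f"{base}.cancer_mortality.{s}"] = Distribution(
                "beta", _beta_params(nh.cancer_mortality[s], 100.0))
            dists[f"{base}.sensitivity.{s}"] = Distribution(
                "beta", _beta_params(nh.sensitivity[s], 40.0))
        dists[f"{base}.current_stage_distribution"] = Distribution(
            "dirichlet", {f"alpha_{s}": 80.0 * nh.current_stage_distribution[s]
                          for s in STAGES})
        dists[f"{base}.incidence_scale"] = Distribution(
            "lognormal", _lognormal_params(1.0, 0.20))
    aaa = ps.aaa()
    if aaa is not None:
        base = "diseases.aaa"
        dists[f"{base}.prevalence_scale"] = Distribution(
            "lognormal", _lognormal_params(1.0, 0.15))
        for size in ("small", "medium", "large"):
            dists[f"{base}.rupture_rate.{size}"] = Distribution(
                "beta", _beta_params(aaa.rupture_rate[size], 150.0))
        for key in ("small_to_medium", "medium_to_large"):
            dists[f"{base}.growth.{key}"] = Distribution(
                "beta", _beta_params(aaa.growth[key], 150.0))
        dists[f"{base}.elective_repair.operative_mortality"] = Distribution(
            "beta", _beta_params(aaa.elective_repair["operative_mortality"], 200.0))
        dists[f"{base}.emergency_repair.survival"] = Distribution(
            "beta", _beta_params(aaa.emergency_repair["survival"], 120.0))
        dists[f"{base}.elective_repair.cost"] = Distribution(
            "gamma", _gamma_params(aaa.elective_repair["cost"], 0.15))
        dists[f"{base}.emergency_repair.cost"] = Distribution(
            "gamma", _gamma_params(aaa.emergency_repair["cost"], 0.15))
    for name in ps.secondary_findings():
        dists[f"diseases.{name}.prevalence_scale"] = Distribution(
            "lognormal", _lognormal_params(1.0, 0.15))
    for pid in ps.pathways:
        dists[f"pathways.{pid}.cost_multiplier"] = Distribution(
            "gamma", _gamma_params(1.0, 0.20))
    dists["radiation_harm"] = Distribution(
        "lognormal", _lognormal_params(0.00078, 0.30))
    return dists


def generate_default_parameters(config: SyntheticConfig | None = None) -> ParameterSet:
    """Deterministic paper-like parameter set (the default study conditions)."""
    config = config or SyntheticConfig()
    if config.target_pattern != "paper_like":
        raise ValueError("generate_default_parameters requires target_pattern='paper_like'")
    diseases: dict = {}
    for name, c in _CANCERS.items():
        diseases[name] = CancerNaturalHistory(
            organ=name,
            incidence={"male": _age_curve(c["inc"][0]),
                       "female": _age_curve(c["inc"][1])},
            dwell_time=dict(zip(STAGES, map(float, c["dwell"]))),
            current_stage_distribution=dict(zip(STAGES, map(float, c["sympt"]))),
            sensitivity=dict(zip(STAGES, map(float, c["sens"]))),
            coverage=float(c["cov"]),
            cancer_mortality=dict(zip(STAGES, map(float, c["mort"]))),
            treatment_cost={s: dict(v) for s, v in _TREATMENT_COST.items()},
            utility_multiplier={s: dict(v) for s, v in _UTILITY_MULT.items()},
            pathway_id=c["pathway"],
        )
    diseases["aaa"] = _aaa_spec()
    for name, organ, category, prev, pathway, _cost in _SECONDARY:
        diseases[name] = SecondaryFindingSpec(
            organ=organ, category=category,
            prevalence={sex: np.full(N_AGES, prev) for sex in SEXES},
            pathway_id=pathway, name=name)
    ps = ParameterSet(
        cohorts=_cohorts(),
        diseases=diseases,
        cost_schedule=default_cost_schedule(),
        pathways=_pathways(),
        other_cause_mortality=generate_life_table(config.seed,
                                                  smoking_hazard_ratio=2.0),
        baseline_utilities=_baseline_utilities(),
        settings=AnalysisSettings(rng_seed=config.seed),
    )
    ps.psa_distributions = _psa_distributions(ps)
    validate_parameter_set(ps)
    return ps


def generate_random_parameters(config: SyntheticConfig) -> ParameterSet:
    """A valid but randomised parameter set for property-test fuzzing."""
    if config.target_pattern != "random":
        raise ValueError("generate_random_parameters requires target_pattern='random'")
    rng = np.random.default_rng(config.seed)
    ps = generate_default_parameters(SyntheticConfig(seed=config.seed))
    for name, nh in ps.cancers().items():
        for s in STAGES:
            nh.dwell_time[s] = float(rng.uniform(0.3, 5.0))
            nh.cancer_mortality[s] = float(rng.uniform(0.005, 0.6))
            nh.sensitivity[s] = float(rng.uniform(0.1, 1.0))
        raw = rng.dirichlet(np.full(4, 2.0))
        nh.current_stage_distribution = {s: float(v) for s, v in zip(STAGES, raw)}
        nh.coverage = float(rng.uniform(0.2, 1.0))
        scale = float(rng.uniform(0.2, 3.0))
        for sex in SEXES:
            nh.incidence[sex] = np.clip(nh.incidence[sex] * scale, 0.0, 1.0)
    aaa = ps.aaa()
    aaa.prevalence_scale = float(rng.uniform(0.3, 2.5))
    raw = rng.dirichlet(np.full(3, 3.0))
    aaa.size_distribution = {k: float(v) for k, v in
                             zip(("small", "medium", "large"), raw)}
    for key in aaa.rupture_rate:
        aaa.rupture_rate[key] = float(rng.uniform(0.0, 0.15))
    for name, sf in ps.secondary_findings().items():
        sf.prevalence_scale = float(rng.uniform(0.2, 2.0))
    ps.other_cause_mortality = generate_life_table(
        config.seed, smoking_hazard_ratio=float(rng.uniform(1.0, 3.0)),
        jitter=0.05)
    validate_parameter_set(ps)
    return ps
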