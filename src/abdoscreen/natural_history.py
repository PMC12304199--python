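"""Cancer natural history: screen-detectable prevalence and diagnosis-rate calibration.

Each cancer is described by the rate at which people enter preclinical stage I
disease (incidence), mean sojourn ("dwell") times per stage, the stage
distribution observed at symptomatic diagnosis under current care, and the
sensitivity/anatomical coverage of a non-contrast upper abdominal CT for that
organ.  Preclinical disease progresses sequentially I -> II -> III -> IV; each
stage is exited by progression, symptomatic diagnosis, or (stage IV only)
cancer death.  Within-stage sojourns are exponential, so dwell times map to
annual probabilities via a constant hazard.

Two derived quantities feed the rest of the model:

* screen-detectable prevalence with its stage distribution, from a
  stationary-flow (length-biased sojourn) approximation, and
* per-stage annual symptomatic-diagnosis probabilities, calibrated so that the
  stage-at-diagnosis distribution of the control-arm process reproduces the
  observed current-care stage distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

AGE_MIN = 55
AGE_MAX = 100
AGE_GRID = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = len(AGE_GRID)
STAGES = ("I", "II", "III", "IV")
SEXES = ("male", "female")
AAA_SIZES = ("small", "medium", "large")


class CalibrationError(RuntimeError):
    """Raised when no diagnosis probability in (0, 1) reproduces the target."""


def _check_prob(value: float, what: str, errors: list[str]) -> None:
    if not (0.0 <= value <= 1.0):
        errors.append(f"{what}={value!r} outside [0, 1]")


@dataclass
class CancerNaturalHistory:
    """Natural-history block for one cancer.

    Age/sex-indexed arrays are keyed by sex over ``AGE_GRID`` (55..100).
    ``treatment_cost`` and ``utility_multiplier`` are keyed stage ->
    {"year1", "later"}: costs in GBP per year in the first year after
    diagnosis versus subsequent years, and utility multipliers applied to the
    age-specific baseline utility over the same two time-since-diagnosis bands.
    """

    organ: str
    incidence: dict[str, np.ndarray]
    dwell_time: dict[str, float]
    current_stage_distribution: dict[str, float]
    sensitivity: dict[str, float]
    coverage: float
    cancer_mortality: dict[str, float]
    treatment_cost: dict[str, dict[str, float]]
    utility_multiplier: dict[str, dict[str, float]]
    pathway_id: str = "none"
    incidence_scale: float = 1.0

    def validate(self, prefix: str = "") -> list[str]:
        errors: list[str] = []
        p = prefix or f"diseases.{self.organ}"
        for s in STAGES:
            if self.dwell_time.get(s, 0.0) <= 0:
                errors.append(f"{p}.dwell_time.{s} must be > 0")
            _check_prob(self.current_stage_distribution.get(s, -1.0),
                        f"{p}.current_stage_distribution.{s}", errors)
            _check_prob(self.sensitivity.get(s, -1.0), f"{p}.sensitivity.{s}", errors)
            _check_prob(self.cancer_mortality.get(s, -1.0),
                        f"{p}.cancer_mortality.{s}", errors)
            for band in ("year1", "later"):
                if self.treatment_cost.get(s, {}).get(band, 0.0) < 0:
                    errors.append(f"{p}.treatment_cost.{s}.{band} must be >= 0")
                _check_prob(self.utility_multiplier.get(s, {}).get(band, -1.0),
                            f"{p}.utility_multiplier.{s}.{band}", errors)
        _check_prob(self.coverage, f"{p}.coverage", errors)
        total = sum(self.current_stage_distribution.get(s, 0.0) for s in STAGES)
        if abs(total - 1.0) > 1e-9:
            errors.append(f"{p}.current_stage_distribution sums to {total}, expected 1")
        for sex in SEXES:
            arr = np.asarray(self.incidence.get(sex, np.array([])), dtype=float)
            if arr.shape != (N_AGES,):
                errors.append(f"{p}.incidence.{sex} must have {N_AGES} entries (ages 55-100)")
            elif (arr < 0).any() or (arr > 1).any():
                errors.append(f"{p}.incidence.{sex} has entries outside [0, 1]")
        if self.incidence_scale <= 0:
            errors.append(f"{p}.incidence_scale must be > 0")
        return errors


@dataclass
class ScreenDetection:
    """Screen-detectable prevalence and the stage mix among detected cases."""

    prevalence: float
    stage_distribution: dict[str, float]
    degenerate: bool = False  # True when prevalence is 0 and the stage mix undefined


@dataclass
class AAASpec:
    """Abdominal aortic aneurysm block (3.0-4.4 / 4.5-5.4 / >=5.5 cm sizes).

    Detection feeds surveillance with elective repair at the large threshold;
    undetected aneurysms grow and rupture with size-specific annual hazards.
    """

    prevalence: dict[str, np.ndarray]
    size_distribution: dict[str, float]
    growth: dict[str, float]          # small_to_medium, medium_to_large
    rupture_rate: dict[str, float]    # annual, by size, undetected
    elective_repair: dict[str, float]  # operative_mortality, cost
    emergency_repair: dict[str, float]  # survival, cost
    surveillance_cost: dict[str, float]  # GBP per year by size (small, medium)
    pathway_id: str = "none"
    prevalence_scale: float = 1.0

    def validate(self, prefix: str = "diseases.aaa") -> list[str]:
        errors: list[str] = []
        p = prefix
        for sex in SEXES:
            arr = np.asarray(self.prevalence.get(sex, np.array([])), dtype=float)
            if arr.shape != (N_AGES,):
                errors.append(f"{p}.prevalence.{sex} must have {N_AGES} entries")
            elif (arr < 0).any() or (arr > 1).any():
                errors.append(f"{p}.prevalence.{sex} has entries outside [0, 1]")
        for size in AAA_SIZES:
            _check_prob(self.size_distribution.get(size, -1.0),
                        f"{p}.size_distribution.{size}", errors)
            _check_prob(self.rupture_rate.get(size, -1.0),
                        f"{p}.rupture_rate.{size}", errors)
        total = sum(self.size_distribution.get(s, 0.0) for s in AAA_SIZES)
        if abs(total - 1.0) > 1e-9:
            errors.append(f"{p}.size_distribution sums to {total}, expected 1")
        for key in ("small_to_medium", "medium_to_large"):
            _check_prob(self.growth.get(key, -1.0), f"{p}.growth.{key}", errors)
        _check_prob(self.elective_repair.get("operative_mortality", -1.0),
                    f"{p}.elective_repair.operative_mortality", errors)
        _check_prob(self.emergency_repair.get("survival", -1.0),
                    f"{p}.emergency_repair.survival", errors)
        for key, d in (("elective_repair", self.elective_repair),
                       ("emergency_repair", self.emergency_repair)):
            if d.get("cost", 0.0) < 0:
                errors.append(f"{p}.{key}.cost must be >= 0")
        for size in ("small", "medium"):
            if self.surveillance_cost.get(size, 0.0) < 0:
                errors.append(f"{p}.surveillance_cost.{size} must be >= 0")
        if self.prevalence_scale <= 0:
            errors.append(f"{p}.prevalence_scale must be > 0")
        return errors


@dataclass
class SecondaryFindingSpec:
    """A non-cancer, non-AAA screen finding modelled via short-term diagnostic costs only."""

    organ: str
    category: str  # serious | minor | false_positive
    prevalence: dict[str, np.ndarray]
    pathway_id: str = "none"
    prevalence_scale: float = 1.0
    name: str = ""

    def validate(self, prefix: str = "") -> list[str]:
        errors: list[str] = []
        p = prefix or f"diseases.{self.name or self.organ}"
        if self.category not in ("serious", "minor", "false_positive"):
            errors.append(f"{p}.category={self.category!r} not one of serious/minor/false_positive")
        for sex in SEXES:
            arr = np.asarray(self.prevalence.get(sex, np.array([])), dtype=float)
            if arr.shape != (N_AGES,):
                errors.append(f"{p}.prevalence.{sex} must have {N_AGES} entries")
            elif (arr < 0).any() or (arr > 1).any():
                errors.append(f"{p}.prevalence.{sex} has entries outside [0, 1]")
        if self.prevalence_scale <= 0:
            errors.append(f"{p}.prevalence_scale must be > 0")
        return errors


def sojourn_to_annual_probability(dwell: float) -> float:
    """Annual exit probability for an exponential sojourn with mean ``dwell`` years.

    Returns 1 - exp(-1/dwell), in (0, 1).
    """
    if dwell <= 0:
        raise ValueError(f"dwell time must be > 0, got {dwell}")
    return 1.0 - math.exp(-1.0 / dwell)


def annual_probability_to_rate(p: float) -> float:
    """Continuous hazard equivalent to annual probability ``p``."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"annual probability must be in [0, 1), got {p}")
    return -math.log1p(-p)


def calibrate_diagnosis_rates(nh: CancerNaturalHistory) -> dict[str, float]:
    """Per-stage annual symptomatic-diagnosis probabilities reproducing the
    current-care stage-at-diagnosis distribution.

    In the control-arm process an undiagnosed stage-s case is diagnosed with
    probability d_s per year, otherwise progresses with probability
    (1 - d_s) * p_s where p_s comes from the stage dwell time.  The chance of
    being diagnosed while in stage s (vs progressing out) is then

        P_s = d_s / (d_s + (1 - d_s) * p_s)

    and the stage-at-diagnosis distribution is the sequential product of these
    absorption probabilities.  d_I..d_III are solved stage by stage with
    bracketed root-finding against the conditional targets; the stage
    distribution alone cannot identify d_IV (diagnosis is the only progression
    exit from stage IV), so d_IV is taken from the stage IV dwell time, i.e.
    the stage IV sojourn ends in symptomatic diagnosis.
    """
    targets = [nh.current_stage_distribution[s] for s in STAGES]
    rates: dict[str, float] = {}
    remaining = 1.0
    for idx, stage in enumerate(STAGES[:3]):
        t = targets[idx]
        if remaining <= 1e-12:
            # upstream stages absorb essentially everything
            rates[stage] = sojourn_to_annual_probability(nh.dwell_time[stage])
            continue
        r = t / remaining
        p_s = sojourn_to_annual_probability(nh.dwell_time[stage])
        if r <= 0.0:
            rates[stage] = 0.0
        elif r >= 1.0 - 1e-12:
            rates[stage] = 1.0 - 1e-9
        else:
            def f(d: float, r: float = r, p: float = p_s) -> float:
                return d / (d + (1.0 - d) * p) - r

            lo, hi = 1e-15, 1.0 - 1e-15
            if f(lo) * f(hi) > 0:
                raise CalibrationError(
                    f"no diagnosis probability in (0, 1) attains target share "
                    f"{r:.6g} for {nh.organ} stage {stage}")
            rates[stage] = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
        remaining -= t
    rates["IV"] = sojourn_to_annual_probability(nh.dwell_time["IV"])
    return rates


def stage_at_diagnosis_distribution(nh: CancerNaturalHistory,
                                    rates: dict[str, float]) -> dict[str, float]:
    """Stage-at-diagnosis distribution implied by diagnosis probabilities ``rates``.

    Closed-form sequential absorption in the control-arm process (no competing
    other-cause mortality).  Stage IV is certain to end in diagnosis.
    """
    dist: dict[str, float] = {}
    remaining = 1.0
    for stage in STAGES[:3]:
        d = rates[stage]
        p = sojourn_to_annual_probability(nh.dwell_time[stage])
        denom = d + (1.0 - d) * p
        share = d / denom if denom > 0 else 0.0
        dist[stage] = remaining * share
        remaining *= 1.0 - share
    dist["IV"] = remaining
    return dist


def screen_detectable_prevalence(nh: CancerNaturalHistory, age: int, sex: str,
                                 diagnosis_rates: dict[str, float] | None = None,
                                 ) -> ScreenDetection:
    """Probability that a person of given age/sex harbours a screen-detectable
    preclinical cancer, with the stage mix among detected cases.

    Uses the stationary-flow (length-biased sojourn) approximation: occupancy
    of stage s equals the entry rate into s divided by the total exit rate
    (progression + symptomatic diagnosis + stage IV cancer death), and the
    entry rate into s+1 is the entry rate into s times the progressing
    fraction.  Detection multiplies occupancy by stage sensitivity and organ
    coverage.  Competing other-cause mortality is ignored here (second order
    at these sojourns) but retained in the Markov models.
    """
    if diagnosis_rates is None:
        diagnosis_rates = calibrate_diagnosis_rates(nh)
    ai = int(age) - AGE_MIN
    if not (0 <= ai < N_AGES):
        raise ValueError(f"age {age} outside modelled grid {AGE_MIN}-{AGE_MAX}")
    entry = float(nh.incidence[sex][ai]) * nh.incidence_scale
    detectable: dict[str, float] = {}
    for stage in STAGES:
        lam = 1.0 / nh.dwell_time[stage] if stage != "IV" else 0.0
        delta = annual_probability_to_rate(min(diagnosis_rates[stage], 1.0 - 1e-12))
        mu = (annual_probability_to_rate(min(nh.cancer_mortality["IV"], 1.0 - 1e-12))
              if stage == "IV" else 0.0)
        exit_rate = lam + delta + mu
        occupancy = entry / exit_rate if exit_rate > 0 else 0.0
        detectable[stage] = occupancy * nh.sensitivity[stage] * nh.coverage
        entry *= lam / exit_rate if exit_rate > 0 else 0.0
    prevalence = sum(detectable.values())
    if prevalence <= 0.0:
        return ScreenDetection(0.0, {s: 0.0 for s in STAGES}, degenerate=True)
    return ScreenDetection(prevalence,
                           {s: detectable[s] / prevalence for s in STAGES})
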