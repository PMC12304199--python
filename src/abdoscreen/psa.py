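"""Probabilistic sensitivity analysis, acceptability, value of information
and the scenario-analysis driver.

Two strategies are compared throughout: add the upper abdominal scan
("screening") versus current care.  Net benefit is NB = wtp * QALY - cost, so
the incremental net benefit (INB) of screening fully determines the decision;
EVPI and EVPPI are computed on the two-column NB matrix [0, INB].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline
from .parameters import ParameterSet, ScenarioSpec, apply_scenario, sample_psa_draws

logger = logging.getLogger(__name__)


@dataclass
class PSAResult:
    """Draw-level incremental outcomes from probabilistic analysis."""

    draws: pd.DataFrame          # inc_cost, inc_qaly, inmb + per-category contributions
    param_values: pd.DataFrame   # sampled scalar parameter values per draw
    wtp: float
    seed: int
    n_rejected: int = 0

    @property
    def n(self) -> int:
        return len(self.draws)

    def means(self) -> pd.Series:
        return self.draws.mean()

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        lo = (1.0 - level) / 2.0
        return self.draws.quantile([lo, 1.0 - lo]).T.rename(
            columns={lo: "lower", 1.0 - lo: "upper"})

    @property
    def prob_cost_effective(self) -> float:
        return float((self.draws["inmb"] > 0.0).mean())

    def nb_matrix(self) -> np.ndarray:
        """Net-benefit matrix (draws x strategies): current care, screening."""
        inb = self.draws["inmb"].to_numpy()
        return np.column_stack([np.zeros_like(inb), inb])


@dataclass
class VOIResult:
    evpi_per_person: float
    evppi_by_group: dict[str, float]
    method: str
    n: int
    metadata: dict = field(default_factory=dict)


def run_psa(params: ParameterSet, n: int, seed: int) -> PSAResult:
    """Propagate parameter uncertainty: evaluate the full pipeline per draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not params.psa_distributions and n > 1:
        logger.warning("no PSA distributions attached; draws will be identical")
    draws, values, n_rejected = sample_psa_draws(params, n, seed, return_values=True)
    wtp = params.settings.wtp
    rows = []
    for ps in draws:
        res = pipeline.evaluate(ps)
        row = {"inc_cost": res.inc_cost, "inc_qaly": res.inc_qaly,
               "inc_ly": res.inc_ly, "inmb": res.inmb}
        for cat, contrib in res.decomposition["inmb_contribution"].items():
            row[f"contrib.{cat}"] = contrib
        rows.append(row)
    if n_rejected:
        logger.info("PSA: %d rejected draws redrawn", n_rejected)
    return PSAResult(pd.DataFrame(rows), values, wtp, seed, n_rejected)


def ceac(psa: PSAResult, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Probability screening is cost-effective at each willingness-to-pay."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid is empty")
    dq = psa.draws["inc_qaly"].to_numpy()
    dc = psa.draws["inc_cost"].to_numpy()
    prob = [(wtp * dq - dc > 0.0).mean() for wtp in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})


def evpi(nb: np.ndarray) -> float:
    """Expected value of perfect information per person.

    ``nb`` is a draws x strategies net-benefit matrix; EVPI is the mean of the
    per-draw best NB minus the best of the mean NBs.
    """
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.shape[1] < 2:
        raise ValueError("need a draws x strategies matrix with >= 2 strategies")
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def _conditional_mean_inb(inb: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Estimate E[INB | theta_group] by spline regression on the group draws.

    Groups with more than four parameters are first projected onto their four
    leading principal components (standardised), as additive spline smoothers
    become unreliable in higher dimensions.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    keep = X.std(axis=0) > 1e-12 * scale
    if not keep.any():
        return np.full(len(inb), inb.mean())
    X = X[:, keep]
    if X.shape[1] > 4:
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        X = Xs @ vt[:4].T
    k = X.shape[1]
    # df 6 balances flexibility against the upward overfit bias that the
    # mean-of-max transform turns into spurious information value
    df = max(4, min(6, len(inb) // (20 * k)))
    bs = BSplines(X, df=[df] * k, degree=[3] * k)
    model = GLMGam(inb, np.ones((len(inb), 1)), smoother=bs,
                   alpha=[0.0] * k)
    fit = model.fit()
    return np.asarray(fit.fittedvalues)


def evppi(psa: PSAResult, parameter_group: list[str],
          group_name: str = "") -> tuple[float, dict]:
    """Expected value of partial perfect information for a parameter group.

    Regresses the incremental net benefit on the group's sampled values with
    an additive spline smoother, then applies the EVPI formula to the fitted
    conditional means.  Returns (value, metadata).
    """
    cols = [c for c in psa.param_values.columns
            if any(c == g or c.startswith(g + ".") or c.startswith(g)
                   for g in parameter_group)]
    meta = {"group": group_name, "n_parameters": len(cols), "n": psa.n,
            "method": "additive B-spline regression (PCA above 4 dims)"}
    if not cols:
        raise KeyError(f"no sampled parameters match group {parameter_group}")
    X = psa.param_values[cols].to_numpy()
    if (X.std(axis=0) <= 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)).all():
        meta["note"] = "group parameters constant across draws"
        return 0.0, meta
    inb = psa.draws["inmb"].to_numpy()
    g = _conditional_mean_inb(inb, X)
    value = float(np.maximum(g, 0.0).mean() - max(g.mean(), 0.0))
    return value, meta


def default_parameter_groups(params: ParameterSet) -> dict[str, list[str]]:
    """Parameter groupings used for EVPPI reporting.

    Mirrors how uncertainty sources are discussed: cancer dwell times (which
    drive screen-detectable prevalence and stage), cancer mortality, cancer
    incidence/prevalence scales, AAA parameters, costs and sensitivities.
    """
    paths = list(params.psa_distributions)
    groups = {
        "cancer_dwell_times": [p for p in paths if ".dwell_time" in p],
        "cancer_stage_distributions": [p for p in paths
                                       if ".current_stage_distribution" in p],
        "cancer_mortality": [p for p in paths if ".cancer_mortality" in p],
        "cancer_incidence": [p for p in paths if ".incidence_scale" in p],
        "aaa": [p for p in paths if ".aaa." in p],
        "secondary_findings": [p for p in paths
                               if ".prevalence_scale" in p and ".aaa." not in p],
        "diagnostic_costs": [p for p in paths if "pathways." in p],
    }
    return {k: v for k, v in groups.items() if v}


def compute_voi(psa: PSAResult,
                groups: dict[str, list[str]] | None = None,
                params: ParameterSet | None = None) -> VOIResult:
    """EVPI plus grouped EVPPI for the standard parameter groups."""
    total = evpi(psa.nb_matrix())
    if groups is None:
        groups = default_parameter_groups(params) if params is not None else {}
    by_group: dict[str, float] = {}
    meta: dict = {}
    for name, paths in groups.items():
        value, m = evppi(psa, paths, group_name=name)
        by_group[name] = value
        meta[name] = m
    return VOIResult(total, by_group, method="two-strategy INB regression",
                     n=psa.n, metadata=meta)


# ---------------------------------------------------------------------------
# scenario analysis

def default_scenario_catalogue(params: ParameterSet) -> list[ScenarioSpec]:
    """The pre-registered structural scenario catalogue (21 scenarios).

    Covers reduced stage-specific mortality with screen detection (full and
    half impact), halved stage shift, stage IV share +/-25%, treatment-cost
    multipliers, prevalence multipliers, a utility decrement for secondary
    findings, the wider trial age distribution, discount-rate variants, and
    disease inclusion masks (no AAA / only AAA / only kidney findings).
    """
    kidney_findings = [name for name, block in params.diseases.items()
                       if name == "kidney" or getattr(block, "organ", "") == "kidney"]
    non_aaa = [name for name, block in params.diseases.items()
               if type(block).__name__ != "AAASpec"]
    aaa_only = [name for name, block in params.diseases.items()
                if type(block).__name__ == "AAASpec"]
    # screen-detected cases carry lower stage-specific cancer mortality
    reduced = {"I": 0.75, "II": 0.78, "III": 0.82, "IV": 0.88}
    half = {s: 1.0 - (1.0 - m) / 2.0 for s, m in reduced.items()}
    trial_ages = range(55, 82)
    trial_weights = {}
    for sex, sex_w in (("male", 0.54), ("female", 0.46)):
        for age in trial_ages:
            # trial population: broad 55-81 spread, tapering after 75
            w = 1.0 if age <= 74 else 0.55
            trial_weights[f"{age}:{sex}"] = sex_w * w
    return [
        ScenarioSpec("1a_reduced_mortality_with_screening",
                     screening_mortality_multipliers=reduced),
        ScenarioSpec("1b_reduced_mortality_half_impact",
                     screening_mortality_multipliers=half),
        ScenarioSpec("2a_stage_shift_halved", stage_shift_attenuation=0.5),
        ScenarioSpec("2b_stage4_share_25pc_more", stage4_share_multiplier=1.25),
        ScenarioSpec("2c_stage4_share_25pc_less", stage4_share_multiplier=0.75),
        ScenarioSpec("3a_metastatic_costs_halved", treatment_cost_multipliers=[
            {"diseases": ["all_cancers"], "stages": ["IV"], "multiplier": 0.5}]),
        ScenarioSpec("3b_metastatic_costs_halved_except_kidney",
                     treatment_cost_multipliers=[
                         {"diseases": [n for n in params.cancers() if n != "kidney"],
                          "stages": ["IV"], "multiplier": 0.5}]),
        ScenarioSpec("3c_metastatic_costs_doubled", treatment_cost_multipliers=[
            {"diseases": ["all_cancers"], "stages": ["IV"], "multiplier": 2.0}]),
        ScenarioSpec("3d_metastatic_costs_doubled_except_kidney",
                     treatment_cost_multipliers=[
                         {"diseases": [n for n in params.cancers() if n != "kidney"],
                          "stages": ["IV"], "multiplier": 2.0}]),
        ScenarioSpec("3e_all_treatment_costs_halved", treatment_cost_multipliers=[
            {"diseases": ["all_cancers"], "stages": ["all"], "multiplier": 0.5}]),
        ScenarioSpec("4a_kidney_prevalence_doubled",
                     prevalence_multipliers={"kidney": 2.0}),
        ScenarioSpec("4b_kidney_prevalence_halved",
                     prevalence_multipliers={"kidney": 0.5}),
        ScenarioSpec("4c_all_cancer_prevalence_doubled",
                     prevalence_multipliers={"all_cancers": 2.0}),
        ScenarioSpec("4d_all_cancer_prevalence_halved",
                     prevalence_multipliers={"all_cancers": 0.5}),
        ScenarioSpec("5_secondary_finding_utility_decrement",
                     secondary_utility_decrement=0.003),
        ScenarioSpec("6_trial_age_distribution_55_81",
                     cohort_weights=trial_weights),
        ScenarioSpec("7a_discount_1_5pc", discount_rate_costs=0.015,
                     discount_rate_qalys=0.015),
        ScenarioSpec("7b_discount_5pc", discount_rate_costs=0.05,
                     discount_rate_qalys=0.05),
        ScenarioSpec("8a_no_aaa", disease_mask=non_aaa),
        ScenarioSpec("8b_only_aaa", disease_mask=aaa_only),
        ScenarioSpec("8c_only_kidney_findings", disease_mask=kidney_findings),
    ]


def run_scenarios(params: ParameterSet, catalogue: list[ScenarioSpec] | None = None,
                  n: int = 0, seed: int = 0,
                  include_basecase: bool = True) -> pd.DataFrame:
    """Evaluate a scenario catalogue; returns a grid of incremental results.

    Deterministic by default; with ``n >= 2`` each scenario also gets a PSA
    for the probability of cost-effectiveness.
    """
    if catalogue is None:
        catalogue = default_scenario_catalogue(params)
    rows = []
    items: list[tuple[str, ParameterSet]] = []
    if include_basecase:
        items.append(("basecase", params))
    for sc in catalogue:
        items.append((sc.name, apply_scenario(params, sc)))
    for name, ps in items:
        res = pipeline.evaluate(ps)
        row = {"scenario": name, "inc_cost": res.inc_cost, "inc_ly": res.inc_ly,
               "inc_qaly": res.inc_qaly, "inmb": res.inmb,
               "icer": str(res.icer)}
        if n >= 2:
            psa = run_psa(ps, n, seed)
            row["prob_cost_effective"] = psa.prob_cost_effective
        rows.append(row)
        logger.info("scenario %s: INMB %.2f", name, res.inmb)
    return pd.DataFrame(rows).set_index("scenario")
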