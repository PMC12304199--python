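"""Annual-cycle cohort Markov engine for the lifetime phase of the model.

Three model families share one engine:

* cancer models with undiagnosed stage I-IV states, diagnosed stage states
  split into first-year / subsequent-year bands, and death from cancer or
  other causes;
* an AAA model with size-based surveillance (screening arm) or undetected
  growth and rupture (control arm); and
* a two-state no-disease model.

Transition matrices depend on age only through the other-cause mortality
table: within a cycle, other-cause death (probability q at current age)
applies first and the remaining (1 - q) mass follows the disease-specific
matrix.  Rewards are accumulated with a trapezoidal half-cycle correction and
cycle k is discounted by (1 + r)^-k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .natural_history import (AAA_SIZES, AGE_MIN, N_AGES, STAGES, AAASpec,
                              CancerNaturalHistory)


class TransitionError(ValueError):
    """A transition row failed stochasticity (e.g. competing risks exceed 1)."""


@dataclass
class StateSpace:
    states: tuple[str, ...]
    absorbing: frozenset[str]
    tags: dict[str, dict]

    def __post_init__(self):
        if not self.absorbing:
            raise ValueError("state space needs at least one absorbing state")
        missing = [s for s in self.states if s not in self.tags]
        if missing:
            raise ValueError(f"states missing tags: {missing}")

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def n(self) -> int:
        return len(self.states)


class TransitionModel:
    """Row-stochastic transition matrices as a function of age.

    ``base`` is the disease-dynamics matrix applied to the survivors of
    other-cause death; rows of absorbing states are unit vectors.  ``q_by_age``
    is the annual other-cause death probability over ages 55..100.
    """

    def __init__(self, space: StateSpace, base: np.ndarray, q_by_age: np.ndarray,
                 dead_other: str = "dead_other"):
        self.space = space
        self.base = np.asarray(base, dtype=float)
        self.q_by_age = np.asarray(q_by_age, dtype=float)
        self.dead_other_idx = space.index(dead_other)
        self.alive = np.array([s not in space.absorbing for s in space.states])
        self._check_base()
        self._stack: np.ndarray | None = None

    def _check_base(self) -> None:
        n = self.space.n
        if self.base.shape != (n, n):
            raise TransitionError(f"base matrix shape {self.base.shape} != ({n}, {n})")
        if (self.base < -1e-12).any() or (self.base > 1 + 1e-12).any():
            bad = np.argwhere((self.base < -1e-12) | (self.base > 1 + 1e-12))[0]
            raise TransitionError(
                f"entry {self.space.states[bad[0]]} -> {self.space.states[bad[1]]} "
                f"outside [0, 1] (competing risks exceed 1?)")
        rowsum = self.base.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise TransitionError(
                f"row {self.space.states[bad]} sums to {rowsum[bad]!r}")
        for s in self.space.absorbing:
            i = self.space.index(s)
            unit = np.zeros(self.space.n)
            unit[i] = 1.0
            if not np.array_equal(self.base[i], unit):
                raise TransitionError(f"absorbing state {s} row is not a unit vector")

    def matrix(self, age: int, cycle: int = 0) -> np.ndarray:
        """Row-stochastic matrix at a given age (cycle retained for interface)."""
        return self.stack()[int(age) - AGE_MIN]

    def stack(self) -> np.ndarray:
        """Matrices for every age on the grid, shape (n_ages, S, S)."""
        if self._stack is None:
            q = self.q_by_age[:, None, None]
            M = np.where(self.alive[None, :, None], (1.0 - q) * self.base,
                         self.base[None, :, :])
            M[:, self.alive, self.dead_other_idx] += self.q_by_age[:, None]
            self._stack = M
        return self._stack


@dataclass
class RewardModel:
    """Per-cycle costs and utilities attached to states and transitions.

    Utilities are the product of the age/sex baseline utility and a per-state
    multiplier (1 for healthy/undiagnosed states, <1 for diagnosed disease,
    0 for dead states).
    """

    state_cost: np.ndarray            # GBP per cycle, shape (S,)
    utility_multiplier: np.ndarray    # shape (S,)
    baseline_utility: np.ndarray      # by age over the grid, shape (n_ages,)
    transition_cost: np.ndarray       # one-off GBP on transitions, (S, S)

    def utility(self, age: int) -> np.ndarray:
        ai = min(int(age) - AGE_MIN, N_AGES - 1)
        return self.baseline_utility[ai] * self.utility_multiplier

    def cost(self, age: int) -> np.ndarray:
        return self.state_cost


@dataclass
class MarkovModel:
    """A state space with its transition and reward models for one arm/sex."""

    space: StateSpace
    transitions: TransitionModel
    rewards: RewardModel
    diagnosis_mask: np.ndarray | None = None  # states whose inflow counts as a diagnosis


@dataclass
class Trace:
    occupancy: np.ndarray  # (n_cycles + 1, S)
    start_age: int
    n_cycles: int
    states: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "age", self.start_age + np.arange(self.n_cycles + 1))
        return df


@dataclass
class CohortOutcome:
    discounted_cost: float
    discounted_qaly: float
    discounted_ly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    undiscounted_ly: float
    deaths_by_cause: dict[str, float]
    diagnoses: float  # cumulative probability of (ever) diagnosis, incl. time zero
    one_off_qaly_decrement: float = 0.0


def run_cohort(model: MarkovModel, start_age: int, settings, init: np.ndarray,
               check: bool = True) -> tuple[Trace, CohortOutcome]:
    """Run one cohort from ``start_age`` to the horizon and aggregate rewards.

    ``init`` is the initial occupancy (must sum to 1).  Rewards use
    trapezoidal occupancy weighting; discounting applies (1+r)^-k to cycle k.
    """
    horizon = settings.horizon_age
    if start_age >= horizon:
        raise ValueError(f"start_age {start_age} must be below horizon {horizon}")
    n_cycles = horizon - start_age
    S = model.space.n
    init = np.asarray(init, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial occupancy sums to {init.sum()}")
    occ = np.empty((n_cycles + 1, S))
    occ[0] = init
    rc, rq = settings.discount_rate_costs, settings.discount_rate_qalys
    alive = model.transitions.alive.astype(float)
    dc = dq = du_c = du_q = dly = uly = 0.0
    diagnoses = 0.0
    dmask = model.diagnosis_mask
    if dmask is not None:
        diagnoses = float(init[dmask].sum())
    C = model.rewards.transition_cost
    has_tc = C.any()
    for k in range(n_cycles):
        age = start_age + k
        M = model.transitions.matrix(age)
        nxt = occ[k] @ M
        if check:
            s = nxt.sum()
            if abs(s - 1.0) > 1e-9:
                raise TransitionError(f"occupancy sums to {s!r} at cycle {k}")
        occ[k + 1] = nxt
        mid = 0.5 * (occ[k] + nxt)
        cost_k = float(mid @ model.rewards.cost(age))
        if has_tc:
            cost_k += float(((occ[k][:, None] * M) * C).sum())
        qaly_k = 0.5 * (float(occ[k] @ model.rewards.utility(age))
                        + float(nxt @ model.rewards.utility(age + 1)))
        ly_k = float(mid @ alive)
        df_c = (1.0 + rc) ** (-k)
        df_q = (1.0 + rq) ** (-k)
        dc += cost_k * df_c
        dq += qaly_k * df_q
        dly += ly_k * df_q
        du_c += cost_k
        du_q += qaly_k
        uly += ly_k
        if dmask is not None:
            # new diagnoses: flow from undiagnosed into diagnosed states
            diagnoses += float(occ[k][~dmask] @ M[np.ix_(~dmask, dmask)].sum(axis=1))
    deaths = {}
    for s in model.space.absorbing:
        cause = model.space.tags[s].get("dead_cause", s)
        deaths[cause] = deaths.get(cause, 0.0) + float(occ[-1, model.space.index(s)])
    trace = Trace(occ, start_age, n_cycles, model.space.states)
    outcome = CohortOutcome(dc, dq, dly, du_c, du_q, uly, deaths, diagnoses)
    return trace, outcome


def run_cohorts_batch(model: MarkovModel, start_ages: np.ndarray, settings,
                      init: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised :func:`run_cohort` over cohorts sharing a transition model.

    ``init`` has shape (C, S), one row per cohort.  Cohorts are advanced on a
    common age clock (the matrix depends on age only), so each step is a
    single matrix product.  Returns arrays keyed like CohortOutcome fields.
    """
    start_ages = np.asarray(start_ages, dtype=int)
    C = len(start_ages)
    horizon = settings.horizon_age
    rc, rq = settings.discount_rate_costs, settings.discount_rate_qalys
    order = np.argsort(start_ages, kind="stable")  # active cohorts form a prefix
    ages_sorted = start_ages[order]
    occ = np.array(init, dtype=float, copy=True)[order]
    alive = model.transitions.alive.astype(float)
    stack = model.transitions.stack()
    cost_vec = model.rewards.state_cost
    TC = model.rewards.transition_cost
    # per-age precomputations: one-off transition costs and utilities by state
    tc_by_age = (stack * TC).sum(axis=2) if TC.any() else None
    u_by_age = model.rewards.baseline_utility[:, None] * model.rewards.utility_multiplier
    dmask = model.diagnosis_mask
    if dmask is not None:
        diag_inflow_by_age = stack[:, ~dmask][:, :, dmask].sum(axis=2)
    out = {k: np.zeros(C) for k in ("discounted_cost", "discounted_qaly",
                                    "discounted_ly", "undiscounted_cost",
                                    "undiscounted_qaly", "undiscounted_ly",
                                    "diagnoses")}
    if dmask is not None:
        out["diagnoses"] += np.asarray(init)[:, dmask].sum(axis=1)
    acc = {k: np.zeros(C) for k in ("dc", "dq", "dly", "uc", "uq", "uly", "diag")}
    for age in range(int(ages_sorted[0]), horizon):
        n_active = int(np.searchsorted(ages_sorted, age, side="right"))
        if n_active == 0:
            continue
        ai = age - AGE_MIN
        k = (age - ages_sorted[:n_active]).astype(float)
        M = stack[ai]
        cur = occ[:n_active]
        nxt = cur @ M
        mid = 0.5 * (cur + nxt)
        cost_k = mid @ cost_vec
        if tc_by_age is not None:
            cost_k = cost_k + cur @ tc_by_age[ai]
        qaly_k = 0.5 * (cur @ u_by_age[ai] + nxt @ u_by_age[min(ai + 1, N_AGES - 1)])
        ly_k = mid @ alive
        df_c = (1.0 + rc) ** (-k)
        df_q = (1.0 + rq) ** (-k)
        acc["dc"][:n_active] += cost_k * df_c
        acc["dq"][:n_active] += qaly_k * df_q
        acc["dly"][:n_active] += ly_k * df_q
        acc["uc"][:n_active] += cost_k
        acc["uq"][:n_active] += qaly_k
        acc["uly"][:n_active] += ly_k
        if dmask is not None:
            acc["diag"][:n_active] += cur[:, ~dmask] @ diag_inflow_by_age[ai]
        occ[:n_active] = nxt
    inv = np.empty(C, dtype=int)
    inv[order] = np.arange(C)
    for key, name in (("dc", "discounted_cost"), ("dq", "discounted_qaly"),
                      ("dly", "discounted_ly"), ("uc", "undiscounted_cost"),
                      ("uq", "undiscounted_qaly"), ("uly", "undiscounted_ly")):
        out[name] += acc[key][inv]
    out["diagnoses"] += acc["diag"][inv]
    dead_disease = np.array([s in model.space.absorbing
                             and model.space.tags[s].get("dead_cause") == "disease"
                             for s in model.space.states])
    occ_orig = occ[inv]
    out["deaths_disease"] = occ_orig[:, dead_disease].sum(axis=1)
    out["deaths_other"] = occ_orig[:, ~dead_disease & ~model.transitions.alive].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# model builders

def build_cancer_model(nh: CancerNaturalHistory, arm: str, mortality: np.ndarray,
                       diagnosis_rates: dict[str, float],
                       baseline_utility: np.ndarray,
                       screening_mortality_multipliers: dict[str, float] | None = None,
                       symptomatic_diagnosis_cost: float = 0.0) -> MarkovModel:
    """Cancer Markov model for one arm and sex.

    Undiagnosed states progress (dwell-time hazard) or are symptomatically
    diagnosed (calibrated probability); undiagnosed stage IV additionally dies
    of cancer at the diagnosed stage IV rate.  Diagnosed states die of cancer
    at stage-specific rates and advance from the first-year to the
    subsequent-years band.  Undiagnosed states carry baseline utility and no
    treatment cost: screening benefit flows entirely through earlier
    diagnosis.  Screening-arm mortality multipliers implement
    better-outcome-with-screen-detection scenarios.
    """
    if arm not in ("screening", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    from .natural_history import sojourn_to_annual_probability
    names = ([f"undx_{s}" for s in STAGES]
             + [f"dx_{s}_y1" for s in STAGES]
             + [f"dx_{s}_y2" for s in STAGES]
             + ["dead_cancer", "dead_other"])
    tags = {}
    for s in STAGES:
        tags[f"undx_{s}"] = {"disease": nh.organ, "diagnosed": False, "stage": s}
        for band in ("y1", "y2"):
            tags[f"dx_{s}_{band}"] = {"disease": nh.organ, "diagnosed": True,
                                      "stage": s, "band": band}
    tags["dead_cancer"] = {"dead_cause": "disease"}
    tags["dead_other"] = {"dead_cause": "other"}
    space = StateSpace(tuple(names), frozenset({"dead_cancer", "dead_other"}), tags)
    n = space.n
    T = np.zeros((n, n))
    mult = screening_mortality_multipliers if arm == "screening" else None
    mort = {s: min(nh.cancer_mortality[s] * (mult or {}).get(s, 1.0), 1.0)
            for s in STAGES}
    for si, s in enumerate(STAGES):
        u = space.index(f"undx_{s}")
        d = diagnosis_rates[s]
        T[u, space.index(f"dx_{s}_y1")] = d
        if s != "IV":
            p = sojourn_to_annual_probability(nh.dwell_time[s])
            T[u, space.index(f"undx_{STAGES[si + 1]}")] = (1.0 - d) * p
        else:
            # late-stage disease kills whether or not formally diagnosed
            T[u, space.index("dead_cancer")] = (1.0 - d) * mort["IV"]
        T[u, u] = 1.0 - T[u].sum()
        for band, nxt in (("y1", f"dx_{s}_y2"), ("y2", f"dx_{s}_y2")):
            i = space.index(f"dx_{s}_{band}")
            T[i, space.index("dead_cancer")] = mort[s]
            T[i, space.index(nxt)] += 1.0 - mort[s]
    for dead in ("dead_cancer", "dead_other"):
        T[space.index(dead), space.index(dead)] = 1.0

    cost = np.zeros(n)
    umult = np.zeros(n)
    for s in STAGES:
        umult[space.index(f"undx_{s}")] = 1.0
        for band, key in (("y1", "year1"), ("y2", "later")):
            i = space.index(f"dx_{s}_{band}")
            cost[i] = nh.treatment_cost[s][key]
            umult[i] = nh.utility_multiplier[s][key]
    TC = np.zeros((n, n))
    if symptomatic_diagnosis_cost > 0:
        for s in STAGES:
            TC[space.index(f"undx_{s}"), space.index(f"dx_{s}_y1")] = \
                symptomatic_diagnosis_cost
    diag_mask = np.array([space.tags[s].get("diagnosed", False) for s in names])
    trans = TransitionModel(space, T, mortality)
    rewards = RewardModel(cost, umult, baseline_utility, TC)
    return MarkovModel(space, trans, rewards, diagnosis_mask=diag_mask)


def cancer_initial_state(model: MarkovModel, arm: str,
                         stage_distribution: dict[str, float]) -> np.ndarray:
    """Initial occupancy: diagnosed first-year states (screening) or the
    equivalent undiagnosed states (control), at the screen-detected stage mix."""
    init = np.zeros(model.space.n)
    prefix = "dx_{}_y1" if arm == "screening" else "undx_{}"
    for s in STAGES:
        init[model.space.index(prefix.format(s))] = stage_distribution[s]
    return init


def build_aaa_model(spec: AAASpec, arm: str, mortality: np.ndarray,
                    baseline_utility: np.ndarray) -> MarkovModel:
    """AAA Markov model for one arm, simplified to three size classes.

    Screening arm: detected aneurysms enter size-based surveillance; reaching
    the large threshold triggers elective repair (operative mortality and a
    one-off cost), with survivors in a post-repair state.  Control arm:
    undetected aneurysms grow small -> medium -> large and rupture with
    size-specific annual rates; rupture leads to emergency repair with a
    survival probability and one-off cost (charged on the survivor flow).
    """
    if arm not in ("screening", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    op_mort = spec.elective_repair["operative_mortality"]
    el_cost = spec.elective_repair["cost"]
    em_surv = spec.emergency_repair["survival"]
    em_cost = spec.emergency_repair["cost"]
    g_sm = spec.growth["small_to_medium"]
    g_ml = spec.growth["medium_to_large"]
    r = spec.rupture_rate

    if arm == "screening":
        names = ("surv_small", "surv_medium", "large_pre_repair", "post_repair",
                 "dead_aaa", "dead_other")
    else:
        names = ("undx_small", "undx_medium", "undx_large", "post_repair",
                 "dead_aaa", "dead_other")
    tags = {s: {"disease": "aaa", "size": s.split("_")[-1]} for s in names[:3]}
    tags["post_repair"] = {"disease": "aaa", "repaired": True}
    tags["dead_aaa"] = {"dead_cause": "disease"}
    tags["dead_other"] = {"dead_cause": "other"}
    space = StateSpace(names, frozenset({"dead_aaa", "dead_other"}), tags)
    n = space.n
    T = np.zeros((n, n))
    TC = np.zeros((n, n))
    post = space.index("post_repair")
    dead = space.index("dead_aaa")

    def rupture_split(i: int, p_rupture: float) -> None:
        T[i, post] += p_rupture * em_surv
        T[i, dead] += p_rupture * (1.0 - em_surv)
        TC[i, post] = em_cost

    if arm == "screening":
        small, med, large = (space.index(s) for s in
                             ("surv_small", "surv_medium", "large_pre_repair"))
        rupture_split(small, r["small"])
        T[small, med] = (1.0 - r["small"]) * g_sm
        rupture_split(med, r["medium"])
        # growth to the large threshold routes through the pre-repair state,
        # so elective and emergency one-off costs sit on distinct flows
        T[med, large] = (1.0 - r["medium"]) * g_ml
        T[large, post] = 1.0 - op_mort
        T[large, dead] = op_mort
        TC[large, post] = el_cost
        TC[large, dead] = el_cost
    else:
        small, med, large = (space.index(s) for s in
                             ("undx_small", "undx_medium", "undx_large"))
        rupture_split(small, r["small"])
        T[small, med] = (1.0 - r["small"]) * g_sm
        rupture_split(med, r["medium"])
        T[med, large] = (1.0 - r["medium"]) * g_ml
        rupture_split(large, r["large"])
    for i in (small, med, large):
        T[i, i] = 1.0 - T[i].sum() + T[i, i]
    T[post, post] = 1.0
    T[space.index("dead_aaa"), space.index("dead_aaa")] = 1.0
    T[space.index("dead_other"), space.index("dead_other")] = 1.0

    cost = np.zeros(n)
    if arm == "screening":
        cost[small] = spec.surveillance_cost["small"]
        cost[med] = spec.surveillance_cost["medium"]
    umult = np.zeros(n)
    umult[[small, med, large, post]] = 1.0  # AAA is asymptomatic pre-rupture
    trans = TransitionModel(space, T, mortality)
    rewards = RewardModel(cost, umult, baseline_utility, TC)
    return MarkovModel(space, trans, rewards)


def aaa_initial_state(model: MarkovModel, arm: str,
                      size_distribution: dict[str, float]) -> np.ndarray:
    init = np.zeros(model.space.n)
    order = (("surv_small", "surv_medium", "large_pre_repair") if arm == "screening"
             else ("undx_small", "undx_medium", "undx_large"))
    for state, size in zip(order, AAA_SIZES):
        init[model.space.index(state)] = size_distribution[size]
    return init


def build_no_disease_model(baseline_utility: np.ndarray,
                           mortality: np.ndarray) -> MarkovModel:
    """Two-state model for people with secondary or no findings."""
    space = StateSpace(("alive", "dead_other"), frozenset({"dead_other"}),
                       {"alive": {}, "dead_other": {"dead_cause": "other"}})
    T = np.array([[1.0, 0.0], [0.0, 1.0]])
    trans = TransitionModel(space, T, mortality)
    rewards = RewardModel(np.zeros(2), np.array([1.0, 0.0]), baseline_utility,
                          np.zeros((2, 2)))
    return MarkovModel(space, trans, rewards)


# ---------------------------------------------------------------------------
# validation against observed detection counts

def validate_against_counts(params, scale: int = 4019) -> pd.DataFrame:
    """Expected screen-detected counts per ``scale`` screened with exact
    Poisson 95% intervals, for comparison against trial counts."""
    from .natural_history import (SecondaryFindingSpec, calibrate_diagnosis_rates,
                                  screen_detectable_prevalence)
    rows = []
    prevalences: dict[str, float] = {}
    for name, block in params.diseases.items():
        if isinstance(block, CancerNaturalHistory):
            rates = calibrate_diagnosis_rates(block)
            prev = sum(c.weight * screen_detectable_prevalence(
                block, c.start_age, c.sex, rates).prevalence
                for c in params.cohorts)
        elif isinstance(block, AAASpec):
            prev = sum(c.weight * float(block.prevalence[c.sex][c.start_age - AGE_MIN])
                       * block.prevalence_scale for c in params.cohorts)
        else:
            prev = sum(c.weight * float(block.prevalence[c.sex][c.start_age - AGE_MIN])
                       * block.prevalence_scale for c in params.cohorts)
        prevalences[name] = prev
    for name, prev in prevalences.items():
        mean = prev * scale
        if mean > 0:
            lo = 0.5 * stats.chi2.ppf(0.025, 2 * mean)
            hi = 0.5 * stats.chi2.ppf(0.975, 2 * mean + 2)
        else:
            lo, hi = 0.0, 0.5 * stats.chi2.ppf(0.975, 2)
        rows.append({"disease": name, "prevalence": prev, "expected_count": mean,
                     "poisson_lo": float(lo), "poisson_hi": float(hi)})
    return pd.DataFrame(rows).set_index("disease")
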