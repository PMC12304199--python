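"""Model configuration: cohorts, disease blocks, costs, utilities, PSA distributions.

A :class:`ParameterSet` is the complete, validated configuration of the
screening model.  It serialises to a human-diffable YAML manifest plus CSV
tables for age/sex-indexed arrays, and every scalar in it is addressable by a
dotted path (``diseases.kidney.dwell_time.II``), which is how probabilistic
sensitivity analysis distributions and value-of-information parameter groups
refer to parameters.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .natural_history import (AGE_GRID, AGE_MIN, N_AGES, SEXES, STAGES,
                              AAASpec, CancerNaturalHistory,
                              SecondaryFindingSpec)
from .pathway import DiagnosticPathway, ScheduleItem, ScreeningCostSchedule


class ParameterValidationError(ValueError):
    """Validation failure; ``errors`` lists offending dotted paths."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("parameter validation failed:\n  " + "\n  ".join(errors))


class ConsistencyError(ValueError):
    """A cross-reference (e.g. a pathway id) points at a missing block."""


class ScenarioError(KeyError):
    """A scenario modifier names a parameter absent from the base set."""


@dataclass
class Distribution:
    """A PSA sampling distribution attached to one parameter path.

    ``fixed`` holds a single ``value``; ``beta`` takes ``alpha``/``beta``;
    ``gamma`` takes ``shape``/``scale``; ``lognormal`` takes ``mu``/``sigma``
    (log scale); ``dirichlet`` takes one ``alpha_<key>`` per component of the
    simplex dict it points at.
    """

    kind: str
    params: dict[str, float]
    seed_offset: int = 0

    def validate(self, path: str = "") -> list[str]:
        p = f"psa_distributions.{path}" if path else "psa_distribution"
        errors: list[str] = []
        if self.kind == "fixed":
            if set(self.params) != {"value"}:
                errors.append(f"{p}: fixed distribution needs exactly one 'value'")
        elif self.kind == "beta":
            if self.params.get("alpha", 0) <= 0 or self.params.get("beta", 0) <= 0:
                errors.append(f"{p}: beta requires alpha, beta > 0")
        elif self.kind == "gamma":
            if self.params.get("shape", 0) <= 0 or self.params.get("scale", 0) <= 0:
                errors.append(f"{p}: gamma requires shape, scale > 0")
        elif self.kind == "lognormal":
            if self.params.get("sigma", 0) <= 0:
                errors.append(f"{p}: lognormal requires sigma > 0")
        elif self.kind == "dirichlet":
            alphas = [v for k, v in self.params.items() if k.startswith("alpha_")]
            if not alphas or any(a <= 0 for a in alphas):
                errors.append(f"{p}: dirichlet requires all alpha_* > 0")
        else:
            errors.append(f"{p}: unknown kind {self.kind!r}")
        return errors

    def sample(self, rng: np.random.Generator):
        if self.kind == "fixed":
            return self.params["value"]
        if self.kind == "beta":
            return float(rng.beta(self.params["alpha"], self.params["beta"]))
        if self.kind == "gamma":
            return float(rng.gamma(self.params["shape"], self.params["scale"]))
        if self.kind == "lognormal":
            return float(rng.lognormal(self.params["mu"], self.params["sigma"]))
        if self.kind == "dirichlet":
            keys = sorted(k[len("alpha_"):] for k in self.params if k.startswith("alpha_"))
            alphas = [self.params[f"alpha_{k}"] for k in keys]
            draw = rng.dirichlet(alphas)
            return {k: float(v) for k, v in zip(keys, draw)}
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass
class CohortSpec:
    start_age: int
    sex: str
    weight: float


@dataclass
class AnalysisSettings:
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    wtp: float = 20000.0
    n_psa: int = 2000
    horizon_age: int = 100
    rng_seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            errors.append("settings.discount_rate must be >= 0")
        if self.wtp <= 0:
            errors.append("settings.wtp must be > 0")
        if self.n_psa < 1:
            errors.append("settings.n_psa must be >= 1")
        return errors


@dataclass
class ScenarioSpec:
    """A named bundle of structural modifiers applied on top of a base set.

    All fields default to "no change"; multipliers must be positive.
    ``treatment_cost_multipliers`` entries are dicts with keys ``diseases``
    (names, or ["all_cancers"]), ``stages`` (or ["all"]) and ``multiplier``.
    ``disease_mask`` keeps only the named disease blocks.
    """

    name: str
    screening_mortality_multipliers: dict[str, float] | None = None
    stage_shift_attenuation: float | None = None
    stage4_share_multiplier: float | None = None
    treatment_cost_multipliers: list[dict] | None = None
    prevalence_multipliers: dict[str, float] | None = None
    secondary_utility_decrement: float | None = None
    cohort_age_range: tuple[int, int] | None = None
    cohort_weights: dict | None = None  # {(age, sex): weight}, renormalised
    discount_rate_costs: float | None = None
    discount_rate_qalys: float | None = None
    disease_mask: list[str] | None = None
    radiation_harm: float | None = None
    extra_cost_per_screen: float | None = None

    def validate(self) -> list[str]:
        errors = []
        for d in (self.screening_mortality_multipliers or {},
                  self.prevalence_multipliers or {}):
            for k, v in d.items():
                if v <= 0:
                    errors.append(f"scenario {self.name}: multiplier {k}={v} must be > 0")
        for entry in self.treatment_cost_multipliers or []:
            if entry.get("multiplier", 1.0) <= 0:
                errors.append(f"scenario {self.name}: treatment cost multiplier must be > 0")
        if self.disease_mask is not None and not self.disease_mask:
            errors.append(f"scenario {self.name}: disease inclusion mask is empty")
        return errors


@dataclass
class ParameterSet:
    """The full model configuration."""

    cohorts: list[CohortSpec]
    diseases: dict[str, CancerNaturalHistory | AAASpec | SecondaryFindingSpec]
    cost_schedule: ScreeningCostSchedule
    pathways: dict[str, DiagnosticPathway]
    other_cause_mortality: dict[str, np.ndarray]  # sex -> annual prob, ages 55-100
    baseline_utilities: dict[str, np.ndarray]     # sex -> utility, ages 55-100
    settings: AnalysisSettings
    psa_distributions: dict[str, Distribution] = field(default_factory=dict)
    radiation_harm: float = 0.00078
    secondary_utility_decrement: float = 0.0
    stage_shift_attenuation: float = 1.0
    stage4_share_multiplier: float = 1.0
    screening_mortality_multipliers: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def cancers(self) -> dict[str, CancerNaturalHistory]:
        return {k: v for k, v in self.diseases.items()
                if isinstance(v, CancerNaturalHistory)}

    def aaa(self) -> AAASpec | None:
        for v in self.diseases.values():
            if isinstance(v, AAASpec):
                return v
        return None

    def secondary_findings(self) -> dict[str, SecondaryFindingSpec]:
        return {k: v for k, v in self.diseases.items()
                if isinstance(v, SecondaryFindingSpec)}


# ---------------------------------------------------------------------------
# validation

def validate_parameter_set(ps: ParameterSet) -> None:
    """Check every invariant; raise ParameterValidationError listing violations."""
    errors: list[str] = []
    wsum = sum(c.weight for c in ps.cohorts)
    if abs(wsum - 1.0) > 1e-9:
        errors.append(f"cohorts: weights sum to {wsum}, expected 1")
    for c in ps.cohorts:
        if not (55 <= c.start_age <= 81):
            errors.append(f"cohorts: start_age {c.start_age} outside 55-81")
        if c.sex not in SEXES:
            errors.append(f"cohorts: unknown sex {c.sex!r}")
        if c.weight < 0:
            errors.append(f"cohorts: negative weight for age {c.start_age} {c.sex}")
    for name, block in ps.diseases.items():
        errors.extend(block.validate(prefix=f"diseases.{name}"))
        if block.pathway_id not in ps.pathways and block.pathway_id != "none":
            raise ConsistencyError(
                f"diseases.{name}.pathway_id={block.pathway_id!r} has no pathway block")
    errors.extend(ps.cost_schedule.validate())
    for pid, pw in ps.pathways.items():
        errors.extend(pw.validate(prefix=f"pathways.{pid}"))
    for table, label, hi in ((ps.other_cause_mortality, "other_cause_mortality", 1.0),
                             (ps.baseline_utilities, "baseline_utilities", 1.0)):
        for sex in SEXES:
            arr = np.asarray(table.get(sex, np.array([])), dtype=float)
            if arr.shape != (N_AGES,):
                errors.append(f"{label}.{sex} must have {N_AGES} entries (ages 55-100)")
            elif (arr < 0).any() or (arr > hi).any():
                errors.append(f"{label}.{sex} has entries outside [0, {hi}]")
    errors.extend(ps.settings.validate())
    if ps.settings.horizon_age <= max((c.start_age for c in ps.cohorts), default=55):
        errors.append("settings.horizon_age must exceed the oldest cohort start age")
    if ps.radiation_harm < 0:
        errors.append("radiation_harm must be >= 0")
    if not (0.0 <= ps.stage_shift_attenuation <= 1.0):
        errors.append("stage_shift_attenuation must be in [0, 1]")
    if ps.stage4_share_multiplier <= 0:
        errors.append("stage4_share_multiplier must be > 0")
    for path, dist in ps.psa_distributions.items():
        errors.extend(dist.validate(path))
        try:
            value = get_parameter(ps, path)
        except KeyError:
            errors.append(f"psa_distributions.{path}: path does not resolve")
            continue
        if dist.kind in ("beta",) and not (isinstance(value, (int, float))
                                           and 0.0 <= value <= 1.0):
            errors.append(f"psa_distributions.{path}: beta attached to a "
                          f"non-probability (value {value!r})")
        if dist.kind == "dirichlet" and not isinstance(value, dict):
            errors.append(f"psa_distributions.{path}: dirichlet must point at a simplex dict")
        if dist.kind in ("gamma", "lognormal") and not isinstance(value, (int, float)):
            errors.append(f"psa_distributions.{path}: {dist.kind} must point at a scalar")
    if errors:
        raise ParameterValidationError(errors)


# ---------------------------------------------------------------------------
# dotted-path access

def get_parameter(ps: ParameterSet, path: str):
    """Resolve a dotted path (``diseases.kidney.dwell_time.II``) to its value."""
    obj = ps
    for token in path.split("."):
        if isinstance(obj, dict):
            if token not in obj:
                raise KeyError(f"path {path!r}: no key {token!r}")
            obj = obj[token]
        elif is_dataclass(obj) and hasattr(obj, token):
            obj = getattr(obj, token)
        else:
            raise KeyError(f"path {path!r}: cannot descend into {type(obj).__name__} "
                           f"at {token!r}")
    return obj


def set_parameter(ps: ParameterSet, path: str, value) -> None:
    """Assign a value at a dotted path (dict values replace the whole dict)."""
    tokens = path.split(".")
    obj = ps
    for token in tokens[:-1]:
        if isinstance(obj, dict):
            if token not in obj:
                raise KeyError(f"path {path!r}: no key {token!r}")
            obj = obj[token]
        elif is_dataclass(obj) and hasattr(obj, token):
            obj = getattr(obj, token)
        else:
            raise KeyError(f"path {path!r}: cannot descend at {token!r}")
    leaf = tokens[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"path {path!r}: no key {leaf!r}")
        if isinstance(obj[leaf], dict) and isinstance(value, dict):
            obj[leaf].update(value)
        else:
            obj[leaf] = value
    elif is_dataclass(obj) and hasattr(obj, leaf):
        setattr(obj, leaf, value)
    else:
        raise KeyError(f"path {path!r}: cannot assign at {leaf!r}")


# ---------------------------------------------------------------------------
# serialisation (YAML manifest + CSV tables)

def _array_frame(table: dict[str, np.ndarray], value_name: str) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for age, v in zip(AGE_GRID, table[sex]):
            rows.append({"age": int(age), "sex": sex, value_name: float(v)})
    return pd.DataFrame(rows)


def _frame_array(df: pd.DataFrame, value_name: str, what: str) -> dict[str, np.ndarray]:
    out = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("age")
        if list(sub["age"]) != list(map(int, AGE_GRID)):
            raise ParameterValidationError(
                [f"{what}: expected ages {AGE_MIN}-100 for sex {sex}"])
        out[sex] = sub[value_name].to_numpy(dtype=float)
    return out


def save_parameter_set(ps: ParameterSet, manifest_path: str | Path,
                       force: bool = False) -> Path:
    """Write the YAML manifest and its CSV tables next to it."""
    manifest_path = Path(manifest_path)
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists (use force=True to overwrite)")
    outdir = manifest_path.parent
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([{"age": c.start_age, "sex": c.sex, "weight": repr(c.weight)}
                  for c in ps.cohorts]).to_csv(outdir / "cohorts.csv", index=False)
    _array_frame(ps.other_cause_mortality, "value").to_csv(
        outdir / "other_cause_mortality.csv", index=False, float_format="%.17g")
    _array_frame(ps.baseline_utilities, "value").to_csv(
        outdir / "baseline_utilities.csv", index=False, float_format="%.17g")

    inc_rows, prev_rows = [], []
    for name, block in ps.diseases.items():
        if isinstance(block, CancerNaturalHistory):
            for sex in SEXES:
                for age, v in zip(AGE_GRID, block.incidence[sex]):
                    inc_rows.append({"disease": name, "age": int(age), "sex": sex,
                                     "value": float(v)})
        else:
            for sex in SEXES:
                for age, v in zip(AGE_GRID, block.prevalence[sex]):
                    prev_rows.append({"disease": name, "age": int(age), "sex": sex,
                                      "value": float(v)})
    pd.DataFrame(inc_rows).to_csv(outdir / "cancer_incidence.csv", index=False,
                                  float_format="%.17g")
    pd.DataFrame(prev_rows).to_csv(outdir / "finding_prevalence.csv", index=False,
                                   float_format="%.17g")

    def scalars(block) -> dict:
        d = {}
        for f in fields(block):
            if f.name in ("incidence", "prevalence"):
                continue
            v = getattr(block, f.name)
            d[f.name] = copy.deepcopy(v)
        return d

    manifest = {
        "format": "abdoscreen-parameters-v1",
        "tables": {
            "cohorts": "cohorts.csv",
            "other_cause_mortality": "other_cause_mortality.csv",
            "baseline_utilities": "baseline_utilities.csv",
            "cancer_incidence": "cancer_incidence.csv",
            "finding_prevalence": "finding_prevalence.csv",
        },
        "diseases": {
            name: {"type": type(block).__name__, **scalars(block)}
            for name, block in ps.diseases.items()
        },
        "cost_schedule": {
            "review_meeting_batch": ps.cost_schedule.review_meeting_batch,
            "extra_per_screen": ps.cost_schedule.extra_per_screen,
            "items": [{"name": i.name, "unit": i.unit, "unit_cost": i.unit_cost,
                       "applies_to": i.applies_to, "divide_by_batch": i.divide_by_batch}
                      for i in ps.cost_schedule.items],
        },
        "pathways": {
            pid: {"resources": [[n, c, q] for n, c, q in pw.resources],
                  "cost_multiplier": pw.cost_multiplier}
            for pid, pw in ps.pathways.items()
        },
        "settings": {f.name: getattr(ps.settings, f.name)
                     for f in fields(AnalysisSettings)},
        "radiation_harm": ps.radiation_harm,
        "secondary_utility_decrement": ps.secondary_utility_decrement,
        "stage_shift_attenuation": ps.stage_shift_attenuation,
        "stage4_share_multiplier": ps.stage4_share_multiplier,
        "screening_mortality_multipliers": dict(ps.screening_mortality_multipliers),
        "psa_distributions": {
            path: {"kind": d.kind, "params": dict(d.params),
                   "seed_offset": d.seed_offset}
            for path, d in ps.psa_distributions.items()
        },
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False, default_flow_style=None)
    return manifest_path


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML manifest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or manifest.get("format") != "abdoscreen-parameters-v1":
        raise ParameterValidationError([f"{path}: not an abdoscreen parameter manifest"])
    outdir = path.parent
    tables = manifest["tables"]
    cohorts_df = pd.read_csv(outdir / tables["cohorts"])
    cohorts = [CohortSpec(int(r.age), str(r.sex), float(r.weight))
               for r in cohorts_df.itertuples()]
    mortality = _frame_array(pd.read_csv(outdir / tables["other_cause_mortality"]),
                             "value", "other_cause_mortality")
    utilities = _frame_array(pd.read_csv(outdir / tables["baseline_utilities"]),
                             "value", "baseline_utilities")
    inc_df = pd.read_csv(outdir / tables["cancer_incidence"])
    prev_df = pd.read_csv(outdir / tables["finding_prevalence"])

    diseases: dict[str, CancerNaturalHistory | AAASpec | SecondaryFindingSpec] = {}
    for name, block in manifest["diseases"].items():
        block = dict(block)
        btype = block.pop("type")
        if btype == "CancerNaturalHistory":
            sub = inc_df[inc_df["disease"] == name]
            if sub.empty:
                raise ConsistencyError(f"diseases.{name}: no incidence rows in CSV")
            block["incidence"] = _frame_array(sub, "value", f"diseases.{name}.incidence")
            diseases[name] = CancerNaturalHistory(**block)
        elif btype in ("AAASpec", "SecondaryFindingSpec"):
            sub = prev_df[prev_df["disease"] == name]
            if sub.empty:
                raise ConsistencyError(f"diseases.{name}: no prevalence rows in CSV")
            block["prevalence"] = _frame_array(sub, "value", f"diseases.{name}.prevalence")
            cls = AAASpec if btype == "AAASpec" else SecondaryFindingSpec
            diseases[name] = cls(**block)
        else:
            raise ParameterValidationError([f"diseases.{name}: unknown type {btype!r}"])

    cs = manifest["cost_schedule"]
    schedule = ScreeningCostSchedule(
        items=[ScheduleItem(i["name"], i["unit"], float(i["unit_cost"]),
                            i["applies_to"], bool(i.get("divide_by_batch", False)))
               for i in cs["items"]],
        review_meeting_batch=float(cs["review_meeting_batch"]),
        extra_per_screen=float(cs.get("extra_per_screen", 0.0)))
    pathways = {pid: DiagnosticPathway(pid, [(n, float(c), float(q))
                                             for n, c, q in pw["resources"]],
                                       float(pw.get("cost_multiplier", 1.0)))
                for pid, pw in manifest["pathways"].items()}
    settings = AnalysisSettings(**manifest["settings"])
    psa = {p: Distribution(d["kind"], {k: float(v) for k, v in d["params"].items()},
                           int(d.get("seed_offset", 0)))
           for p, d in manifest.get("psa_distributions", {}).items()}
    ps = ParameterSet(
        cohorts=cohorts, diseases=diseases, cost_schedule=schedule,
        pathways=pathways, other_cause_mortality=mortality,
        baseline_utilities=utilities, settings=settings, psa_distributions=psa,
        radiation_harm=float(manifest.get("radiation_harm", 0.00078)),
        secondary_utility_decrement=float(manifest.get("secondary_utility_decrement", 0.0)),
        stage_shift_attenuation=float(manifest.get("stage_shift_attenuation", 1.0)),
        stage4_share_multiplier=float(manifest.get("stage4_share_multiplier", 1.0)),
        screening_mortality_multipliers={
            k: float(v) for k, v in
            manifest.get("screening_mortality_multipliers", {}).items()},
    )
    validate_parameter_set(ps)
    return ps


def parameter_sets_equal(a: ParameterSet, b: ParameterSet, rtol: float = 0.0,
                         atol: float = 1e-12) -> bool:
    """Field-wise equality, comparing arrays numerically."""

    def eq(x, y) -> bool:
        if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
            return np.allclose(np.asarray(x, float), np.asarray(y, float),
                               rtol=rtol, atol=atol)
        if is_dataclass(x) and is_dataclass(y):
            if type(x) is not type(y):
                return False
            return all(eq(getattr(x, f.name), getattr(y, f.name)) for f in fields(x))
        if isinstance(x, dict) and isinstance(y, dict):
            return set(x) == set(y) and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, (list, tuple)) and isinstance(y, (list, tuple)):
            return len(x) == len(y) and all(eq(u, v) for u, v in zip(x, y))
        if isinstance(x, float) and isinstance(y, float):
            return math.isclose(x, y, rel_tol=rtol, abs_tol=atol)
        return x == y

    return eq(a, b)


# ---------------------------------------------------------------------------
# scenarios

def apply_scenario(base: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet with the scenario's modifiers applied.

    The base set is never mutated; an identity scenario returns an equal copy.
    Unknown modifier targets raise :class:`ScenarioError` naming them.
    """
    errs = scenario.validate()
    if errs:
        raise ParameterValidationError(errs)
    ps = base.copy()

    if scenario.screening_mortality_multipliers:
        for stage in scenario.screening_mortality_multipliers:
            if stage not in STAGES:
                raise ScenarioError(f"unknown stage {stage!r} in mortality multipliers")
        ps.screening_mortality_multipliers = dict(scenario.screening_mortality_multipliers)
    if scenario.stage_shift_attenuation is not None:
        ps.stage_shift_attenuation = scenario.stage_shift_attenuation
    if scenario.stage4_share_multiplier is not None:
        ps.stage4_share_multiplier = scenario.stage4_share_multiplier
    if scenario.secondary_utility_decrement is not None:
        ps.secondary_utility_decrement = scenario.secondary_utility_decrement
    if scenario.radiation_harm is not None:
        ps.radiation_harm = scenario.radiation_harm
    if scenario.extra_cost_per_screen is not None:
        ps.cost_schedule.extra_per_screen = scenario.extra_cost_per_screen
    if scenario.discount_rate_costs is not None:
        ps.settings.discount_rate_costs = scenario.discount_rate_costs
    if scenario.discount_rate_qalys is not None:
        ps.settings.discount_rate_qalys = scenario.discount_rate_qalys

    for entry in scenario.treatment_cost_multipliers or []:
        names = entry.get("diseases", ["all_cancers"])
        stages = entry.get("stages", ["all"])
        mult = float(entry["multiplier"])
        cancer_names = list(ps.cancers())
        targets = cancer_names if names == ["all_cancers"] else names
        for name in targets:
            if name not in ps.diseases or not isinstance(
                    ps.diseases[name], CancerNaturalHistory):
                raise ScenarioError(f"treatment cost multiplier targets unknown "
                                    f"cancer {name!r}")
            nh = ps.diseases[name]
            stage_list = list(STAGES) if stages == ["all"] else stages
            for stage in stage_list:
                if stage not in STAGES:
                    raise ScenarioError(f"unknown stage {stage!r}")
                for band in ("year1", "later"):
                    nh.treatment_cost[stage][band] *= mult

    for name, mult in (scenario.prevalence_multipliers or {}).items():
        targets = list(ps.cancers()) if name == "all_cancers" else [name]
        for t in targets:
            if t not in ps.diseases:
                raise ScenarioError(f"prevalence multiplier targets unknown disease {t!r}")
            block = ps.diseases[t]
            if isinstance(block, CancerNaturalHistory):
                block.incidence_scale *= mult
            else:
                block.prevalence_scale *= mult

    if scenario.disease_mask is not None:
        unknown = [d for d in scenario.disease_mask if d not in ps.diseases]
        if unknown:
            raise ScenarioError(f"disease mask names unknown diseases {unknown}")
        keep = set(scenario.disease_mask)
        ps.diseases = {k: v for k, v in ps.diseases.items() if k in keep}
        ps.psa_distributions = {
            p: d for p, d in ps.psa_distributions.items()
            if not (p.startswith("diseases.")
                    and p.split(".")[1] not in keep)}

    if scenario.cohort_weights is not None:
        by_key = {(c.start_age, c.sex): c for c in ps.cohorts}
        new = []
        for key, w in scenario.cohort_weights.items():
            age, sex = (key if isinstance(key, tuple) else
                        (int(str(key).split(":")[0]), str(key).split(":")[1]))
            spec = by_key.get((age, sex))
            if spec is None:
                spec = CohortSpec(age, sex, 0.0)
                ps.cohorts.append(spec)
            new.append((spec, float(w)))
        total = sum(w for _, w in new)
        present = {id(s) for s, _ in new}
        for c in ps.cohorts:
            if id(c) not in present:
                c.weight = 0.0
        for spec, w in new:
            spec.weight = w / total
    if scenario.cohort_age_range is not None:
        lo, hi = scenario.cohort_age_range
        total = sum(c.weight for c in ps.cohorts if lo <= c.start_age <= hi)
        if total <= 0:
            raise ScenarioError(f"no cohort weight inside age range {lo}-{hi}")
        for c in ps.cohorts:
            c.weight = c.weight / total if lo <= c.start_age <= hi else 0.0

    validate_parameter_set(ps)
    return ps


# ---------------------------------------------------------------------------
# PSA sampling

def sample_psa_draws(base: ParameterSet, n: int, seed: int,
                     return_values: bool = False):
    """Draw ``n`` realised parameter sets from the PSA distributions.

    Parameters without a distribution keep their deterministic value; draws
    are reproducible bit-for-bit given ``seed``.  A draw failing validation is
    rejected and redrawn with an incremented sub-seed (count reported when
    ``return_values``).  With ``return_values`` also returns a DataFrame of
    the sampled scalar values per draw (dirichlet components expand to
    ``path.key`` columns), as consumed by EVPPI estimation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    paths = sorted(base.psa_distributions)
    draws: list[ParameterSet] = []
    records: list[dict[str, float]] = []
    n_rejected = 0
    for i in range(n):
        for attempt in range(100):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i, attempt]))
            ps = base.copy()
            record: dict[str, float] = {}
            for path in paths:
                dist = base.psa_distributions[path]
                value = dist.sample(rng)
                set_parameter(ps, path, value)
                if isinstance(value, dict):
                    for k, v in value.items():
                        record[f"{path}.{k}"] = v
                else:
                    record[path] = value
            try:
                validate_parameter_set(ps)
            except ParameterValidationError:
                n_rejected += 1
                continue
            draws.append(ps)
            records.append(record)
            break
        else:
            raise RuntimeError(f"draw {i}: rejected 100 consecutive candidates")
    if return_values:
        return draws, pd.DataFrame(records), n_rejected
    return draws
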