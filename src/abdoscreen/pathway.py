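"""Short-term screening and diagnosis stage (the decision tree).

Covers the incremental per-screen cost build-up (scan reporting, review
meetings batched over scans, result letters and referral calls), the standard
diagnostic pathway costed for each positive finding, the one-off radiation
utility decrement, and the assembly of screen outcome probabilities into the
initial state distributions handed to the lifetime Markov models.

Minor findings (small cysts/stones needing no follow-up) are classified as
negative screens under the roll-out assumption: in practice they would not be
taken to a review meeting, so they incur the negative-screen cost and no
diagnostic pathway cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .natural_history import (AAA_SIZES, STAGES, AAASpec, CancerNaturalHistory,
                              ScreenDetection, SecondaryFindingSpec)

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import CohortSpec, ParameterSet

DEFAULT_RADIATION_HARM = 0.00078  # one-off QALY decrement per person screened


class PathwayError(KeyError):
    """An outcome category has no diagnostic pathway mapping."""


@dataclass
class ScheduleItem:
    name: str
    unit: str
    unit_cost: float
    applies_to: str  # negative | positive | both
    divide_by_batch: bool = False  # review meetings are shared across scans


@dataclass
class ScreeningCostSchedule:
    """Per-screen resource schedule; meeting items are divided by the batch size."""

    items: list[ScheduleItem]
    review_meeting_batch: float = 15.0
    extra_per_screen: float = 0.0  # uniform add-on, used by max-justifiable-cost analysis

    def validate(self, prefix: str = "cost_schedule") -> list[str]:
        errors = []
        if self.review_meeting_batch < 1:
            errors.append(f"{prefix}.review_meeting_batch must be >= 1")
        for item in self.items:
            if item.unit_cost < 0:
                errors.append(f"{prefix}.{item.name}: unit cost must be >= 0")
            if item.applies_to not in ("negative", "positive", "both"):
                errors.append(f"{prefix}.{item.name}: applies_to={item.applies_to!r}")
        if self.extra_per_screen < 0:
            errors.append(f"{prefix}.extra_per_screen must be >= 0")
        return errors


@dataclass
class DiagnosticPathway:
    """Bundle of diagnostic resources triggered by one positive finding category."""

    pathway_id: str
    resources: list[tuple[str, float, float]]  # (resource name, unit cost GBP, quantity)
    cost_multiplier: float = 1.0

    def total_cost(self) -> float:
        return self.cost_multiplier * sum(c * q for _, c, q in self.resources)

    def validate(self, prefix: str = "") -> list[str]:
        p = prefix or f"pathways.{self.pathway_id}"
        errors = []
        for name, cost, qty in self.resources:
            if qty < 0:
                errors.append(f"{p}.{name}: quantity must be >= 0")
            if cost < 0:
                errors.append(f"{p}.{name}: unit cost must be >= 0")
        if self.cost_multiplier < 0:
            errors.append(f"{p}.cost_multiplier must be >= 0")
        return errors


def cost_negative_screen(schedule: ScreeningCostSchedule) -> float:
    """Cost per negative screen: items applying to negative screens."""
    total = sum(i.unit_cost / (schedule.review_meeting_batch if i.divide_by_batch else 1.0)
                for i in schedule.items if i.applies_to in ("negative", "both"))
    return total + schedule.extra_per_screen


def cost_positive_screen(schedule: ScreeningCostSchedule) -> float:
    """Cost per positive screen; batched items contribute unit cost / batch size."""
    total = sum(i.unit_cost / (schedule.review_meeting_batch if i.divide_by_batch else 1.0)
                for i in schedule.items if i.applies_to in ("positive", "both"))
    return total + schedule.extra_per_screen


def mean_screen_cost(schedule: ScreeningCostSchedule, p_positive: float) -> float:
    """Positive-rate-weighted average screen cost."""
    if not (0.0 <= p_positive <= 1.0):
        raise ValueError(f"p_positive must be in [0, 1], got {p_positive}")
    return ((1.0 - p_positive) * cost_negative_screen(schedule)
            + p_positive * cost_positive_screen(schedule))


def diagnostic_cost(outcome: str, pathways: dict[str, DiagnosticPathway]) -> float:
    """Total diagnostic pathway cost for a finding category.

    ``outcome`` is a pathway id; "none" is the empty pathway (minor findings
    under the roll-out assumption).
    """
    if outcome == "none" or outcome is None:
        return 0.0
    if outcome not in pathways:
        raise PathwayError(f"no diagnostic pathway mapped for outcome {outcome!r}")
    return pathways[outcome].total_cost()


def radiation_harm_decrement(params: "ParameterSet | None" = None) -> float:
    """One-off QALY decrement per screened person from scan radiation.

    Applied once, at screening, in the screening arm only, regardless of
    findings.  Scenario overrides set ``ParameterSet.radiation_harm``.
    """
    if params is None:
        return DEFAULT_RADIATION_HARM
    return params.radiation_harm


@dataclass
class OutcomeCategory:
    """One mutually exclusive branch of the screen outcome distribution."""

    name: str
    kind: str        # cancer | aaa | secondary | none
    positive: bool   # classified positive at the review meeting
    probability: float
    pathway_id: str = "none"
    stage_distribution: dict[str, float] | None = None  # cancers
    size_distribution: dict[str, float] | None = None   # AAA
    organ: str = ""
    category: str = ""  # secondary findings: serious | minor | false_positive


@dataclass
class ScreenOutcomeDistribution:
    categories: list[OutcomeCategory]

    def p_positive(self) -> float:
        return sum(c.probability for c in self.categories if c.positive)

    def check(self) -> None:
        total = sum(c.probability for c in self.categories)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities sum to {total}, expected 1")


@dataclass
class DecisionTreeResult:
    """Per-cohort short-term outputs of the screening/diagnosis decision tree."""

    outcome: ScreenOutcomeDistribution
    screen_cost: float              # screening arm mean screen cost, GBP/person
    diagnostic_cost: float          # expected diagnostic pathway cost, GBP/person
    harm_qaly: float                # one-off utility decrement, screening arm
    diagnostic_cost_by_category: dict[str, float]
    harm_by_category: dict[str, float]
    screen_cost_by_category: dict[str, float]

    @property
    def screening_short_term_cost(self) -> float:
        return self.screen_cost + self.diagnostic_cost


def _shift_stage_distribution(screen: dict[str, float], symptomatic: dict[str, float],
                              attenuation: float, stage4_multiplier: float,
                              ) -> dict[str, float]:
    """Apply scenario modifiers to the stage mix of screen-detected cases.

    ``attenuation`` mixes the screen-detected distribution toward the
    symptomatic (current-care) distribution: 1 keeps the full stage shift,
    0.5 halves it, 0 removes it.  ``stage4_multiplier`` rescales the stage IV
    share, renormalising stages I-III proportionally.
    """
    mixed = {s: attenuation * screen[s] + (1.0 - attenuation) * symptomatic[s]
             for s in STAGES}
    if stage4_multiplier != 1.0:
        s4 = min(mixed["IV"] * stage4_multiplier, 1.0)
        rest = sum(mixed[s] for s in STAGES[:3])
        scale = (1.0 - s4) / rest if rest > 0 else 0.0
        mixed = {s: mixed[s] * scale for s in STAGES[:3]} | {"IV": s4}
    total = sum(mixed.values())
    return {s: v / total for s, v in mixed.items()}


def screen_outcome_distribution(params: "ParameterSet", cohort: "CohortSpec",
                                detections: dict[str, ScreenDetection],
                                ) -> ScreenOutcomeDistribution:
    """Mutually exclusive screen outcome probabilities for one cohort.

    ``detections`` maps cancer names to their ScreenDetection for this cohort.
    Diseases are modelled independently; if synthetic prevalences overlap
    enough that the finding probabilities exceed 1 they are renormalised.
    """
    ai = cohort.start_age - 55
    cats: list[OutcomeCategory] = []
    for name, block in params.diseases.items():
        if isinstance(block, CancerNaturalHistory):
            det = detections[name]
            dist = _shift_stage_distribution(
                det.stage_distribution, block.current_stage_distribution,
                params.stage_shift_attenuation, params.stage4_share_multiplier,
            ) if not det.degenerate else {s: 0.0 for s in STAGES}
            cats.append(OutcomeCategory(
                name=name, kind="cancer", positive=True, probability=det.prevalence,
                pathway_id=block.pathway_id, stage_distribution=dist, organ=name))
        elif isinstance(block, AAASpec):
            prev = float(block.prevalence[cohort.sex][ai]) * block.prevalence_scale
            cats.append(OutcomeCategory(
                name=name, kind="aaa", positive=True, probability=min(prev, 1.0),
                pathway_id=block.pathway_id,
                size_distribution=dict(block.size_distribution), organ="aaa"))
        elif isinstance(block, SecondaryFindingSpec):
            prev = float(block.prevalence[cohort.sex][ai]) * block.prevalence_scale
            positive = block.category != "minor"
            cats.append(OutcomeCategory(
                name=name, kind="secondary", positive=positive,
                probability=min(prev, 1.0),
                pathway_id=block.pathway_id if positive else "none",
                organ=block.organ, category=block.category))
    total_findings = sum(c.probability for c in cats)
    if total_findings > 1.0:
        warnings.warn("finding probabilities exceed 1; renormalising", stacklevel=2)
        for c in cats:
            c.probability /= total_findings
        total_findings = 1.0
    cats.append(OutcomeCategory(name="no_finding", kind="none", positive=False,
                                probability=1.0 - total_findings))
    dist = ScreenOutcomeDistribution(cats)
    dist.check()
    return dist


def run_decision_tree(params: "ParameterSet", cohort: "CohortSpec",
                      detections: dict[str, ScreenDetection],
                      ) -> DecisionTreeResult:
    """Short-term screening-arm costs and harms for one cohort.

    The control arm incurs no short-term cost: the same prevalent cases exist
    undiagnosed (cases missed by the screen are excluded from both arms), and
    minor findings generate no activity under current care.  Diagnostic costs
    are incurred at time zero, before the first Markov cycle, and are not
    discounted.
    """
    outcome = screen_outcome_distribution(params, cohort, detections)
    schedule = params.cost_schedule
    c_neg = cost_negative_screen(schedule)
    c_pos = cost_positive_screen(schedule)
    radiation = radiation_harm_decrement(params)

    screen_cost_by_cat: dict[str, float] = {}
    diag_by_cat: dict[str, float] = {}
    harm_by_cat: dict[str, float] = {}
    for cat in outcome.categories:
        p = cat.probability
        screen_cost_by_cat[cat.name] = p * (c_pos if cat.positive else c_neg)
        diag_by_cat[cat.name] = p * diagnostic_cost(cat.pathway_id, params.pathways)
        harm = radiation
        if cat.kind == "secondary":
            harm += params.secondary_utility_decrement
        harm_by_cat[cat.name] = p * harm
    return DecisionTreeResult(
        outcome=outcome,
        screen_cost=sum(screen_cost_by_cat.values()),
        diagnostic_cost=sum(diag_by_cat.values()),
        harm_qaly=sum(harm_by_cat.values()),
        diagnostic_cost_by_category=diag_by_cat,
        harm_by_category=harm_by_cat,
        screen_cost_by_category=screen_cost_by_cat,
    )


def default_cost_schedule() -> ScreeningCostSchedule:
    """Incremental screening cost schedule for the add-on upper abdominal scan.

    Invitation and scan time are absorbed within existing thoracic scan costs
    and carry zero incremental cost.  The screening review meeting (consultant,
    specialist nurse and administrator for one hour) covers 15 scans and only
    applies to positive screens.
    """
    return ScreeningCostSchedule(items=[
        ScheduleItem("patient_invitation", "1 invite", 0.0, "both"),
        ScheduleItem("scan_time", "1 scan", 0.0, "both"),
        ScheduleItem("radiologist_reading", "1 scan", 15.0, "both"),
        ScheduleItem("screening_review_meeting", "1 h/15 scans", 217.69, "positive",
                     divide_by_batch=True),
        ScheduleItem("patient_letter", "1 letter", 6.85, "both"),
        ScheduleItem("patient_phone_referral", "1 patient", 3.03, "positive"),
    ], review_meeting_batch=15.0)
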