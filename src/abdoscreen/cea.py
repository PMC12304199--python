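"""Aggregation of cohort results into cost-effectiveness outputs.

Incremental costs, QALYs and life years; the ICER with dominance codes;
incremental net monetary benefit (INMB) at the willingness-to-pay threshold;
the maximum justifiable screening cost; the per-disease INMB decomposition;
and epidemiological outputs per 100,000 screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass
class ArmResult:
    """Discounted, population-weighted per-person outcomes for one arm."""

    cost: float
    qaly: float
    ly: float

    def __post_init__(self):
        if not all(np.isfinite([self.cost, self.qaly, self.ly])):
            raise ValueError("arm outcomes must be finite")
        if self.qaly > self.ly + 1e-9:
            raise ValueError(f"QALYs ({self.qaly}) exceed life years ({self.ly})")


@dataclass
class ICERResult:
    """An ICER value or a dominance code.

    ``code`` is "ratio", "dominant" (cheaper and more effective), "dominated"
    (costlier and less effective) or "undefined" (zero QALY increment).  For
    the south-west quadrant (cost saving, QALY losing) the ratio is reported
    with ``southwest=True``: there a HIGHER ratio favours the intervention.
    """

    code: str
    value: float | None = None
    southwest: bool = False

    def __str__(self) -> str:
        if self.code == "ratio":
            return f"{self.value:,.0f}" + (" (SW)" if self.southwest else "")
        return self.code


def icer(inc_cost: float, inc_qaly: float) -> ICERResult:
    if inc_qaly == 0.0:
        if inc_cost == 0.0:
            return ICERResult("ratio", 0.0)
        return ICERResult("undefined")
    if inc_cost < 0.0 and inc_qaly > 0.0:
        return ICERResult(DOMINANT)
    if inc_cost > 0.0 and inc_qaly < 0.0:
        return ICERResult(DOMINATED)
    return ICERResult("ratio", inc_cost / inc_qaly,
                      southwest=(inc_cost < 0.0 and inc_qaly < 0.0))


def inmb(inc_cost: float, inc_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dCost."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return wtp * inc_qaly - inc_cost


def max_justifiable_cost(base_screen_cost: float, inmb_value: float) -> float:
    """Screening cost per person at which INMB reaches zero.

    Per-person screen cost passes one-for-one into incremental cost, so the
    break-even cost is the current mean screen cost plus the INMB.
    """
    return base_screen_cost + inmb_value


def combine_weighted(outcomes: list[tuple[float, float, float]],
                     weights: list[float]) -> ArmResult:
    """Weight-average per-cohort (cost, qaly, ly) triples into an ArmResult."""
    if len(outcomes) != len(weights):
        raise ValueError(f"{len(outcomes)} outcomes but {len(weights)} weights")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, expected 1")
    arr = np.asarray(outcomes, dtype=float)
    cost, qaly, ly = (w @ arr).tolist()
    return ArmResult(cost, qaly, ly)


@dataclass
class CEAResult:
    """Complete deterministic cost-effectiveness output."""

    control: ArmResult
    screening: ArmResult
    wtp: float
    decomposition: pd.DataFrame   # per finding category: INMB contribution
    epi: pd.DataFrame             # deaths prevented / additional diagnoses per 100k
    mean_screen_cost: float       # GBP per person screened (screen stage only)
    p_positive: float

    @property
    def inc_cost(self) -> float:
        return self.screening.cost - self.control.cost

    @property
    def inc_qaly(self) -> float:
        return self.screening.qaly - self.control.qaly

    @property
    def inc_ly(self) -> float:
        return self.screening.ly - self.control.ly

    @property
    def icer(self) -> ICERResult:
        return icer(self.inc_cost, self.inc_qaly)

    @property
    def inmb(self) -> float:
        return inmb(self.inc_cost, self.inc_qaly, self.wtp)

    @property
    def max_justifiable_cost(self) -> float:
        return max_justifiable_cost(self.mean_screen_cost, self.inmb)


def build_decomposition(rows: list[dict], total_inmb: float,
                        tol: float = 1e-6) -> pd.DataFrame:
    """Assemble the per-category INMB decomposition and check completeness.

    Each row carries the category's prevalence-weighted contribution, split
    into its lifetime (Markov) component and its short-term screening /
    diagnostic component.  Contributions must sum to the total INMB.
    """
    df = pd.DataFrame(rows).set_index("category")
    total = float(df["inmb_contribution"].sum())
    if abs(total - total_inmb) > tol:
        raise ValueError(f"decomposition sums to {total}, expected {total_inmb}")
    return df.sort_values("inmb_contribution", ascending=False)


def epi_outputs(per_disease: list[dict], scale: int = 100_000) -> pd.DataFrame:
    """Deaths prevented and additional diagnoses per ``scale`` screened.

    ``per_disease`` rows carry the population-weighted cumulative disease
    deaths and diagnoses per person screened in each arm.
    """
    rows = []
    for rec in per_disease:
        rows.append({
            "disease": rec["disease"],
            "deaths_prevented": (rec["deaths_control"] - rec["deaths_screening"]) * scale,
            "additional_diagnoses": (rec["diagnoses_screening"]
                                     - rec["diagnoses_control"]) * scale,
            "expected_cases": rec.get("prevalence", np.nan) * scale,
        })
    df = pd.DataFrame(rows).set_index("disease")
    df.loc["total"] = df.sum()
    return df
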