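"""Model/results facade.

:class:`ScreeningCEA` wraps a validated parameter set the way a statistical
model wraps its data: construct it from a manifest or a synthetic generator,
call :meth:`fit` to run the evaluation (deterministic or probabilistic), and
read estimates, uncertainty and diagnostics off the returned results object,
including a formatted ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline, psa as psa_mod
from .cea import CEAResult
from .parameters import (ParameterSet, ScenarioSpec, apply_scenario,
                         load_parameter_set)
from .psa import PSAResult, VOIResult


class ScreeningCEA:
    """Cost-effectiveness model of one-off upper abdominal CT screening
    added to lung cancer screening, against current care.

    Parameters
    ----------
    params : ParameterSet
        Validated model configuration (cohorts, disease blocks, costs,
        utilities, analysis settings, PSA distributions).

    Examples
    --------
    >>> from abdoscreen import ScreeningCEA
    >>> model = ScreeningCEA.from_synthetic(seed=0)
    >>> res = model.fit()
    >>> round(res.inmb, 2) == res.inmb
    True
    """

    def __init__(self, params: ParameterSet):
        self.params = params

    @classmethod
    def from_manifest(cls, path: str | Path) -> "ScreeningCEA":
        return cls(load_parameter_set(path))

    @classmethod
    def from_synthetic(cls, seed: int = 0, pattern: str = "paper_like",
                       ) -> "ScreeningCEA":
        from .synthetic import (SyntheticConfig, generate_default_parameters,
                                generate_random_parameters)
        cfg = SyntheticConfig(seed=seed, target_pattern=pattern)
        params = (generate_default_parameters(cfg) if pattern == "paper_like"
                  else generate_random_parameters(cfg))
        return cls(params)

    def fit(self, method: str = "deterministic", n_draws: int | None = None,
            seed: int | None = None) -> "ScreeningCEAResults":
        """Evaluate the model.

        ``method="deterministic"`` runs the pipeline once at the mean
        parameter values; ``method="psa"`` additionally propagates parameter
        uncertainty over ``n_draws`` Monte-Carlo draws (default: the
        configured ``settings.n_psa``).
        """
        det = pipeline.evaluate(self.params)
        psa_result = None
        if method == "psa":
            n = n_draws or self.params.settings.n_psa
            s = seed if seed is not None else self.params.settings.rng_seed
            psa_result = psa_mod.run_psa(self.params, n, s)
        elif method != "deterministic":
            raise ValueError(f"unknown method {method!r}")
        return ScreeningCEAResults(self, det, psa_result)

    def with_scenario(self, scenario: ScenarioSpec) -> "ScreeningCEA":
        return ScreeningCEA(apply_scenario(self.params, scenario))

    def run_scenarios(self, catalogue: list[ScenarioSpec] | None = None,
                      n: int = 0, seed: int = 0) -> pd.DataFrame:
        return psa_mod.run_scenarios(self.params, catalogue, n=n, seed=seed)

    def age_sex_sweep(self) -> pd.DataFrame:
        """Per-cohort incremental results (the age/sex policy curves)."""
        return pipeline.per_cohort_inmb(self.params)


@dataclass
class ScreeningCEAResults:
    """Estimates, uncertainty and diagnostics from a fitted screening model."""

    model: ScreeningCEA
    deterministic: CEAResult
    psa: PSAResult | None = None
    _voi: VOIResult | None = field(default=None, repr=False)

    # -- point estimates -------------------------------------------------
    @property
    def inc_cost(self) -> float:
        return self._mean("inc_cost", self.deterministic.inc_cost)

    @property
    def inc_qaly(self) -> float:
        return self._mean("inc_qaly", self.deterministic.inc_qaly)

    @property
    def inc_ly(self) -> float:
        return self._mean("inc_ly", self.deterministic.inc_ly)

    @property
    def inmb(self) -> float:
        return self._mean("inmb", self.deterministic.inmb)

    def _mean(self, col: str, fallback: float) -> float:
        if self.psa is not None:
            return float(self.psa.draws[col].mean())
        return fallback

    @property
    def icer(self):
        from .cea import icer
        return icer(self.inc_cost, self.inc_qaly)

    @property
    def max_justifiable_cost(self) -> float:
        return self.deterministic.mean_screen_cost + self.inmb

    @property
    def prob_cost_effective(self) -> float | None:
        return None if self.psa is None else self.psa.prob_cost_effective

    @property
    def decomposition(self) -> pd.DataFrame:
        return self.deterministic.decomposition

    @property
    def epi(self) -> pd.DataFrame:
        return self.deterministic.epi

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        if self.psa is None:
            raise ValueError("credible intervals require a PSA fit")
        return self.psa.credible_interval(level)

    # -- uncertainty / VOI ------------------------------------------------
    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        if self.psa is None:
            raise ValueError("CEAC requires a PSA fit")
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 50001.0, 1000.0)
        return psa_mod.ceac(self.psa, wtp_grid)

    def voi(self, groups=None) -> VOIResult:
        if self.psa is None:
            raise ValueError("value of information requires a PSA fit")
        if self._voi is None or groups is not None:
            result = psa_mod.compute_voi(self.psa, groups=groups,
                                         params=self.model.params)
            if groups is not None:
                return result
            self._voi = result
        return self._voi

    def evpi(self) -> float:
        return self.voi().evpi_per_person

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Formatted results table (per person scanned, discounted)."""
        from statsmodels.iolib.table import SimpleTable

        det = self.deterministic
        rows = [
            ["Cost (GBP)", f"{det.control.cost:.2f}", f"{det.screening.cost:.2f}",
             f"{self.inc_cost:.2f}"],
            ["Life years", f"{det.control.ly:.3f}", f"{det.screening.ly:.3f}",
             f"{self.inc_ly:.4f}"],
            ["QALYs", f"{det.control.qaly:.3f}", f"{det.screening.qaly:.3f}",
             f"{self.inc_qaly:.4f}"],
        ]
        header = ["", "Current care", "Screening", "Incremental"]
        lines = [str(SimpleTable(rows, header,
                                 title="Upper abdominal CT screening CEA "
                                       "(per person scanned)"))]
        wtp = self.model.params.settings.wtp
        lines.append(f"ICER: {self.icer}  GBP/QALY   "
                     f"INMB at WTP {wtp:,.0f}: {self.inmb:.2f} GBP")
        lines.append(f"Mean screen cost: {det.mean_screen_cost:.2f} GBP  "
                     f"(positive screen rate {det.p_positive:.3f});  "
                     f"max justifiable cost: {self.max_justifiable_cost:.2f} GBP")
        if self.psa is not None:
            ci = self.conf_int()
            lines.append(
                f"PSA (n={self.psa.n}): prob cost-effective "
                f"{self.prob_cost_effective:.3f};  "
                f"INMB 95% CrI [{ci.loc['inmb', 'lower']:.2f}, "
                f"{ci.loc['inmb', 'upper']:.2f}]")
        lines.append("Top INMB contributions (GBP per person scanned):")
        top = det.decomposition["inmb_contribution"]
        for cat, v in pd.concat([top.head(3), top.tail(3)]).items():
            lines.append(f"  {cat:<28s} {v:+8.2f}")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_ce_plane(self, ax=None):
        """Scatter of PSA draws on the cost-effectiveness plane."""
        import matplotlib.pyplot as plt

        if self.psa is None:
            raise ValueError("CE plane requires a PSA fit")
        if ax is None:
            _, ax = plt.subplots()
        d = self.psa.draws
        ax.scatter(d["inc_qaly"], d["inc_cost"], s=6, alpha=0.4)
        ax.scatter([d["inc_qaly"].mean()], [d["inc_cost"].mean()], color="red")
        wtp = self.model.params.settings.wtp
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, linestyle=":", color="grey")
        ax.axhline(0, lw=0.6, color="black")
        ax.axvline(0, lw=0.6, color="black")
        ax.set_xlabel("Incremental QALYs per person")
        ax.set_ylabel("Incremental cost (GBP) per person")
        return ax

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        curve = self.ceac()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["wtp"], curve["prob_cost_effective"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (GBP/QALY)")
        ax.set_ylabel("Probability cost-effective")
        return ax
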