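"""Deterministic end-to-end evaluation of a parameter set.

One call runs the whole chain for every cohort: calibration of control-arm
diagnosis rates, screen-detectable prevalence, the screening/diagnosis
decision tree, the lifetime Markov models for both arms, and aggregation into
a :class:`~abdoscreen.cea.CEAResult`.  Both arms share the same prevalent
disease (cases missed by the screen are excluded from both), so the
incremental results isolate the effect of earlier, screen-led diagnosis.
"""

from __future__ import annotations

import numpy as np

from .cea import ArmResult, CEAResult, build_decomposition, epi_outputs
from .markov import (aaa_initial_state, build_aaa_model, build_cancer_model,
                     build_no_disease_model, cancer_initial_state,
                     run_cohorts_batch)
from .natural_history import (AGE_MIN, SEXES, AAASpec, CancerNaturalHistory,
                              SecondaryFindingSpec, calibrate_diagnosis_rates,
                              screen_detectable_prevalence)
from .parameters import ParameterSet
from .pathway import diagnostic_cost, run_decision_tree


def evaluate(params: ParameterSet) -> CEAResult:
    """Run the full model deterministically and aggregate all outputs."""
    cohorts = [c for c in params.cohorts if c.weight > 0]
    weights = np.array([c.weight for c in cohorts])
    settings = params.settings
    wtp = settings.wtp

    cancers = params.cancers()
    diag_rates = {name: calibrate_diagnosis_rates(nh) for name, nh in cancers.items()}
    detections = {
        name: {i: screen_detectable_prevalence(nh, c.start_age, c.sex, diag_rates[name])
               for i, c in enumerate(cohorts)}
        for name, nh in cancers.items()}

    trees = [run_decision_tree(params, c,
                               {name: detections[name][i] for name in cancers})
             for i, c in enumerate(cohorts)]

    # conditional Markov outcomes per disease/arm, batched per sex over start ages
    cond: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    n_cohorts = len(cohorts)
    sex_idx = {sex: [i for i, c in enumerate(cohorts) if c.sex == sex] for sex in SEXES}
    cat_by_cohort = [{cat.name: cat for cat in trees[i].outcome.categories}
                     for i in range(n_cohorts)]

    def batch(name: str, arm: str, builder) -> None:
        res = {k: np.zeros(n_cohorts) for k in
               ("discounted_cost", "discounted_qaly", "discounted_ly",
                "undiscounted_cost", "undiscounted_qaly", "undiscounted_ly",
                "diagnoses", "deaths_disease", "deaths_other")}
        for sex in SEXES:
            idx = sex_idx[sex]
            if not idx:
                continue
            model, make_init = builder(sex, arm)
            init = np.stack([make_init(i) for i in idx])
            ages = np.array([cohorts[i].start_age for i in idx])
            out = run_cohorts_batch(model, ages, settings, init)
            for k in res:
                res[k][idx] = out.get(k, np.zeros(len(idx)))
        cond[(name, arm)] = res

    for name, nh in cancers.items():
        sympt_cost = diagnostic_cost(nh.pathway_id, params.pathways)

        def cancer_builder(sex: str, arm: str, nh=nh, name=name,
                           sympt_cost=sympt_cost):
            model = build_cancer_model(
                nh, arm, params.other_cause_mortality[sex], diag_rates[name],
                params.baseline_utilities[sex],
                screening_mortality_multipliers=params.screening_mortality_multipliers,
                symptomatic_diagnosis_cost=sympt_cost)

            def make_init(i: int, model=model, arm=arm, name=name):
                cat = cat_by_cohort[i][name]
                dist = cat.stage_distribution
                if sum(dist.values()) <= 0:  # degenerate: no detectable mass
                    dist = dict.fromkeys(dist, 0.25)
                return cancer_initial_state(model, arm, dist)

            return model, make_init

        for arm in ("screening", "control"):
            batch(name, arm, cancer_builder)

    aaa_name = next((k for k, v in params.diseases.items()
                     if isinstance(v, AAASpec)), None)
    if aaa_name is not None:
        spec = params.diseases[aaa_name]

        def aaa_builder(sex: str, arm: str, spec=spec):
            model = build_aaa_model(spec, arm, params.other_cause_mortality[sex],
                                    params.baseline_utilities[sex])

            def make_init(i: int, model=model, arm=arm):
                return aaa_initial_state(model, arm, spec.size_distribution)

            return model, make_init

        for arm in ("screening", "control"):
            batch(aaa_name, arm, aaa_builder)

    def nodisease_builder(sex: str, arm: str):
        model = build_no_disease_model(params.baseline_utilities[sex],
                                       params.other_cause_mortality[sex])

        def make_init(i: int, model=model):
            init = np.zeros(model.space.n)
            init[0] = 1.0
            return init

        return model, make_init

    batch("no_disease", "screening", nodisease_builder)
    cond[("no_disease", "control")] = cond[("no_disease", "screening")]

    # assemble absolute per-cohort, per-arm outcomes
    markov_names = list(cancers) + ([aaa_name] if aaa_name else [])
    arm_outcomes = {arm: np.zeros((n_cohorts, 3)) for arm in ("screening", "control")}
    for i in range(n_cohorts):
        p_disease = sum(cat_by_cohort[i][name].probability for name in markov_names)
        for arm in ("screening", "control"):
            cost = qaly = ly = 0.0
            for name in markov_names:
                p = cat_by_cohort[i][name].probability
                r = cond[(name, arm)]
                cost += p * r["discounted_cost"][i]
                qaly += p * r["discounted_qaly"][i]
                ly += p * r["discounted_ly"][i]
            r0 = cond[("no_disease", arm)]
            rest = 1.0 - p_disease
            cost += rest * r0["discounted_cost"][i]
            qaly += rest * r0["discounted_qaly"][i]
            ly += rest * r0["discounted_ly"][i]
            if arm == "screening":
                cost += trees[i].screening_short_term_cost
                qaly -= trees[i].harm_qaly
            arm_outcomes[arm][i] = (cost, qaly, ly)

    control = ArmResult(*(weights @ arm_outcomes["control"]))
    screening = ArmResult(*(weights @ arm_outcomes["screening"]))
    inc_cost = screening.cost - control.cost
    inc_qaly = screening.qaly - control.qaly
    total_inmb = wtp * inc_qaly - inc_cost

    # per-category INMB decomposition: each category carries its members'
    # screen-class cost, diagnostic cost and radiation harm, plus (for
    # modelled diseases) the prevalence-weighted incremental Markov net benefit
    decomp_rows = []
    secondary = params.secondary_findings()
    for cat_name in list(cat_by_cohort[0]):
        markov_nb = short_cost = harm = 0.0
        prevalence = 0.0
        for i in range(n_cohorts):
            w = weights[i]
            cat = cat_by_cohort[i][cat_name]
            p = cat.probability
            prevalence += w * p
            short_cost += w * (trees[i].screen_cost_by_category[cat_name]
                               + trees[i].diagnostic_cost_by_category[cat_name])
            harm += w * trees[i].harm_by_category[cat_name]
            if (cat_name, "screening") in cond:
                rs = cond[(cat_name, "screening")]
                rc = cond[(cat_name, "control")]
                d_cost = rs["discounted_cost"][i] - rc["discounted_cost"][i]
                d_qaly = rs["discounted_qaly"][i] - rc["discounted_qaly"][i]
                markov_nb += w * p * (wtp * d_qaly - d_cost)
        contribution = markov_nb - short_cost - wtp * harm
        block = params.diseases.get(cat_name)
        organ = getattr(block, "organ", "none") if block is not None else "none"
        kind = ("secondary" if cat_name in secondary
                else "aaa" if isinstance(block, AAASpec)
                else "cancer" if isinstance(block, CancerNaturalHistory)
                else "none")
        decomp_rows.append({
            "category": cat_name, "organ": organ, "kind": kind,
            "prevalence": prevalence, "markov_nb": markov_nb,
            "short_term_cost": short_cost, "harm_qaly": harm,
            "inmb_contribution": contribution,
        })
    decomposition = build_decomposition(decomp_rows, total_inmb)

    epi_rows = []
    for name in markov_names:
        rs, rc = cond[(name, "screening")], cond[(name, "control")]
        prev = np.array([cat_by_cohort[i][name].probability
                         for i in range(n_cohorts)])
        epi_rows.append({
            "disease": name,
            "prevalence": float(weights @ prev),
            "deaths_control": float(weights @ (prev * rc["deaths_disease"])),
            "deaths_screening": float(weights @ (prev * rs["deaths_disease"])),
            "diagnoses_control": float(weights @ (prev * rc["diagnoses"])),
            "diagnoses_screening": float(weights @ (prev * rs["diagnoses"])),
        })
    epi = epi_outputs(epi_rows)

    mean_screen = float(weights @ np.array([trees[i].screen_cost
                                            for i in range(n_cohorts)]))
    p_pos = float(weights @ np.array([trees[i].outcome.p_positive()
                                      for i in range(n_cohorts)]))
    return CEAResult(control=control, screening=screening, wtp=wtp,
                     decomposition=decomposition, epi=epi,
                     mean_screen_cost=mean_screen, p_positive=p_pos)


def per_cohort_inmb(params: ParameterSet) -> "np.ndarray":
    """INMB per person scanned for each single-age, single-sex cohort.

    Returns a structured array of (age, sex, inc_cost, inc_qaly, inmb) rows,
    the age/sex sweep behind screening-policy age curves.
    """
    import pandas as pd

    rows = []
    for c in params.cohorts:
        sub = params.copy()
        for c2 in sub.cohorts:
            c2.weight = 1.0 if (c2.start_age == c.start_age and c2.sex == c.sex) else 0.0
        res = evaluate(sub)
        rows.append({"age": c.start_age, "sex": c.sex, "inc_cost": res.inc_cost,
                     "inc_qaly": res.inc_qaly, "inmb": res.inmb})
    return pd.DataFrame(rows)
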