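# abdoscreen

A multi-disease cost-effectiveness model of **one-off upper abdominal
non-contrast CT screening offered as an add-on to lung cancer screening**,
compared with current care, from an NHS perspective.  It is written for
health-economic modellers and screening researchers who want to evaluate —
and stress-test — the economics of bolting an abdominal screen onto an
existing thoracic CT visit.

The package models eleven conditions with lifetime annual-cycle cohort
Markov models — ten cancers (kidney, liver, stomach, oesophagus, pancreas,
upper urinary tract, colon, adrenal, gallbladder, lymphoma) and abdominal
aortic aneurysm (AAA) — plus secondary findings captured through short-term
diagnostic costs only.  A decision tree covers the screening and diagnosis
process; age/sex cohorts are weighted back into a composite screening
population.

## The model in brief

For each cancer, preclinical disease enters at stage I and progresses
sequentially with exponential within-stage sojourns, so a mean dwell time
*d<sub>s</sub>* maps to an annual progression probability 1 − e^(−1/d_s).
Screen-detectable prevalence uses a length-biased stationary-flow
approximation (entry rate × effective sojourn × sensitivity × coverage per
stage), and control-arm symptomatic-diagnosis probabilities are calibrated
by root-finding so the model reproduces the observed stage distribution at
diagnosis.  The screening arm starts diagnosed at the screen-detected stage
mix; the control arm starts undiagnosed at the same mix, so the incremental
results isolate the effect of earlier diagnosis.  Headline economics are the
incremental cost per QALY (ICER) and the incremental net monetary benefit,

&nbsp;&nbsp;&nbsp;&nbsp;INMB = λ·ΔQALY − ΔCost,&nbsp;&nbsp;λ = £20,000/QALY,

with probabilistic sensitivity analysis (PSA), cost-effectiveness
acceptability curves, expected value of perfect information (EVPI) and
grouped EVPPI, a 21-entry structural scenario catalogue, and a per-disease
INMB decomposition on top.

The study's own parameter values are not public, so `abdoscreen` ships a
synthetic parameter generator whose defaults reproduce the published
anchors: ~10 screen-detected kidney cancers, ~10 other cancers, ~60 AAA and
>100 serious secondary findings per 4019 people scanned; the exact
incremental screening cost schedule (£21.85 per negative screen, £39.39 per
positive); and the qualitative contribution pattern (AAA dominant positive,
kidney secondary findings the largest negative).  See `docs/methods.md` for
what the generator does and does not emulate.

## Worked example

```python
from abdoscreen import ScreeningCEA

model = ScreeningCEA.from_synthetic(seed=0)   # the default study conditions
res = model.fit()                             # deterministic evaluation
print(res.summary())
```

```
Upper abdominal CT screening CEA (per person scanned)
=============================================
           Current care Screening Incremental
---------------------------------------------
Cost (GBP)       122.63    184.66       62.04
Life years       12.845    12.853      0.0080
     QALYs        9.712     9.717      0.0053
---------------------------------------------
ICER: 11,733  GBP/QALY   INMB at WTP 20,000: 43.71 GBP
Mean screen cost: 26.54 GBP  (positive screen rate 0.267);  max justifiable cost: 70.26 GBP
Top INMB contributions (GBP per person scanned):
  aaa                            +65.38
  kidney                         +46.78
  colon                          +16.82
  kidney_cysts_stones            -11.25
  no_finding                     -19.20
  kidney_followup_fp             -22.50
```

Reading this: screening costs £62.04 extra per person over their lifetime
and gains 0.0053 QALYs, an ICER of £11,733/QALY — cost-effective at the
£20,000/QALY threshold with an INMB of £43.71 per person scanned.  The
screen itself averages £26.54; it could cost up to £70.26 and break even.
Early AAA detection carries the result (+£65.38 per person scanned), kidney
cancer is second, while the many kidney secondary findings and false
positives are the largest drag.

Uncertainty, scenarios and value of information:

```python
res = model.fit(method="psa", n_draws=2000, seed=1)
res.prob_cost_effective          # fraction of draws with positive INMB
res.conf_int()                   # 95% credible intervals
res.ceac()                       # acceptability curve over WTP values
res.evpi()                       # GBP per person
grid = model.run_scenarios()     # the 21 pre-registered scenarios
```

The same workflow is available from a shell:

```bash
abdoscreen generate-params --seed 0 --out bundle/params.yaml
abdoscreen run --params bundle/params.yaml --mode psa --n 2000 --out results/
abdoscreen scenarios --params bundle/params.yaml --out results/
abdoscreen validate --params bundle/params.yaml   # detection counts vs 4019 scanned
```

Every run writes machine-readable CSV tables (summary, INMB decomposition,
CE plane, CEAC, epidemiological outputs per 100,000 screened) and a
`run_manifest.json` sufficient to reproduce it.

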