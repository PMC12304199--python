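# Methods

`abdoscreen` is a multi-disease health-economic model of a one-off upper
abdominal non-contrast CT screen offered as an add-on to lung cancer
screening, compared with current care, from an NHS perspective.  Both arms
are assumed to receive lung screening; only the incremental abdominal
component is modelled.  This note documents the model structure, its
assumptions, the synthetic parameter set that plays the role of the study
inputs, and the numerical choices that matter.

## Model structure

A decision tree covers the short-term screening and diagnosis process; a set
of annual-cycle cohort Markov models covers lifetime outcomes.  The modelled
population is a weighted set of single-year age/sex cohorts (ages 55–81; the
basecase weights all lie on the screening-eligible 55–74 range).  Per-cohort
results are weight-averaged back into a composite population.

Eleven conditions get lifetime Markov models: ten cancers (kidney, liver,
stomach, oesophagus, pancreas, upper urinary tract, colon, adrenal,
gallbladder, lymphoma) and abdominal aortic aneurysm (AAA).  All other
findings ("secondary findings": serious non-cancer findings, minor findings,
false positives) are modelled only through their short-term diagnostic costs.
People with secondary findings or no findings follow a two-state no-disease
model (alive / dead from all causes) for life expectancy and utilities.

Diseases are modelled independently and the screen outcome distribution
treats categories as mutually exclusive (renormalising in the hypothetical
case that prevalences sum beyond 1).  People whose disease is missed by the
screen are excluded from both arms, so the screening and control arms carry
identical prevalent disease and the comparison isolates the effect of
earlier, screen-led diagnosis.

## Cancer natural history

Preclinical disease enters at stage I and progresses sequentially
I → II → III → IV.  Within-stage sojourns are exponential with mean equal to
the stage dwell time, so a dwell of `d` years maps to an annual progression
probability `1 − exp(−1/d)`.  Undiagnosed disease exits by progression,
symptomatic diagnosis, or (stage IV only) cancer death.

**Screen-detectable prevalence** uses a stationary-flow (length-biased
sojourn) approximation: occupancy of stage `s` is the entry rate into `s`
divided by the total exit rate (progression + symptomatic diagnosis + stage
IV death), the entry rate into `s+1` is the entry rate into `s` times the
progressing fraction, and detection multiplies occupancy by stage sensitivity
and organ coverage.  Competing other-cause mortality is ignored inside this
closed form (it is second order at these sojourn lengths) but retained in the
Markov models; the test suite quantifies the approximation against a
continuous-time individual-level simulation and requires agreement within
Monte-Carlo error.  Incidence is evaluated at the screening age (a
stationarity approximation over the preceding sojourn).

**Calibration.**  Control-arm annual symptomatic-diagnosis probabilities
`d_s` are solved stage by stage with bracketed root-finding so that the
sequential absorption probabilities reproduce the observed current-care
stage-at-diagnosis distribution.  The stage distribution identifies
`d_I..d_III` only — diagnosis is the only exit from stage IV, so any positive
`d_IV` yields the same distribution — and `d_IV` is therefore taken from the
stage IV dwell time (the stage IV sojourn ends in symptomatic diagnosis).
Calibration ignores other-cause and pre-diagnosis death; the realised
distribution in the full model therefore tilts slightly toward earlier
stages, which is the same approximation the closed-form prevalence makes.

## Markov models

**Cancer** (14 states): undiagnosed I–IV; diagnosed I–IV split into
first-year and subsequent-years bands; dead of cancer; dead of other causes.
The screening arm starts diagnosed (first-year band) at the screen-detected
stage mix; the control arm starts undiagnosed at the same mix.  Undiagnosed
states carry baseline utility and no treatment cost — the benefit of
screening flows entirely through earlier diagnosis.  Undiagnosed stage IV
carries the diagnosed stage IV cancer mortality (late-stage disease kills
whether or not formally diagnosed); undiagnosed stages I–III carry none.
Control-arm symptomatic diagnosis incurs the same diagnostic pathway cost as
screen-led diagnosis, attached to the diagnosing transition.

**AAA** (6 states per arm): three size classes (3.0–4.4 cm, 4.5–5.4 cm,
≥ 5.5 cm).  Screening: detected aneurysms enter size-based surveillance
(annual cost by size); growth to the large threshold triggers elective repair
(operative mortality, one-off cost) with survivors in a post-repair state;
aneurysms detected already large are repaired in the first cycle.  Control:
undetected aneurysms grow and rupture with size-specific annual rates;
rupture leads to emergency repair with a survival probability; the emergency
repair cost is charged on the survivor flow (those dying before or at surgery
incur no repair cost — a deliberate simplification).  AAA is treated as
asymptomatic before rupture (baseline utility in all pre-rupture states).

**Cycle conventions.**  Annual cycles to age 100 ("lifetime horizon":
all-cause mortality forces near-total absorption by then).  Within a cycle,
other-cause death (annual probability `q` at the current age, from a
smoking-adjusted Gompertz life table) applies first and the remaining
`1 − q` mass follows the disease dynamics.  Rewards use a trapezoidal
half-cycle correction (average of start- and end-of-cycle occupancy);
one-off transition costs are charged on the flows of the cycle in which they
occur; cycle `k` is discounted by `(1+r)^−k`, 3.5% per year for both costs
and QALYs in the basecase.  Utilities are age-specific baselines multiplied
by state multipliers (stage × time-since-diagnosis band for diagnosed
cancer).  The engine enforces row-stochasticity to 1e-12 and occupancy
conservation to 1e-9 at every cycle, and is verified against a
fundamental-matrix closed form to 1e-10 on random chains.

## Decision tree and costs

Per-screen incremental costs follow the published schedule: scan reporting
(£15) and the result letter (£6.85) for every screen; positive screens add a
referral call (£3.03) and a share of the screening review meeting (£217.69
per hour covering 15 scans → £14.51), giving £21.85 per negative and £39.39
per positive screen.  Invitation and scan time are absorbed within the
thoracic scan.  Minor findings are costed as negative screens (in roll-out
they would not reach a review meeting) and incur no diagnostic pathway.
Diagnostic pathway costs are incurred at time zero, undiscounted.  A one-off
radiation-harm utility decrement of 0.00078 per screened person applies in
the screening arm regardless of findings.

## Outputs

Per-person discounted costs, life years and QALYs per arm; incremental
cost-effectiveness ratio with dominance codes; incremental net monetary
benefit (INMB) at £20,000/QALY; the maximum justifiable screening cost
(mean screen cost + INMB, exploiting the one-for-one pass-through of screen
cost into incremental cost — verified end to end); deaths prevented and
additional diagnoses per 100,000 screened; and a per-category INMB
decomposition.  The decomposition attributes to each finding category its
members' own screen-class cost, diagnostic cost and radiation harm × WTP,
plus (for modelled diseases) the prevalence-weighted incremental Markov net
benefit; rows sum to total INMB to 1e-6 by construction.  Attributing the
radiation harm by membership (rather than pooling it on the no-finding row)
is a documented choice; the harm terms are reported separately in the
decomposition table so either attribution can be reconstructed.

## Probabilistic and scenario analysis

PSA draws each distribution-tagged parameter independently (dirichlet blocks
tie stage-distribution simplexes together), re-runs the full pipeline per
draw (default 2000 draws), and reports percentile credible intervals, the
cost-effectiveness plane, the CEAC, and the probability cost-effective
(fraction of draws with positive INMB at the threshold).  Default families:
beta for probabilities, gamma for costs, lognormal for dwell times and
positive scale factors, dirichlet for stage distributions — all overridable
in the manifest.  Invalid draws are rejected and redrawn with an incremented
sub-seed; all sampling is reproducible bit-for-bit given the seed.

EVPI is the mean of the per-draw best net benefit minus the best mean net
benefit over the two strategies.  Grouped EVPPI regresses the incremental
net benefit on the group's sampled values with additive cubic B-spline
smoothers (about 10 degrees of freedom per dimension at 2000 draws); groups
with more than four parameters are first projected onto their four leading
principal components, as additive smoothers degrade in higher dimensions.
The estimator is validated on constructed toys: near zero for independent
groups, near full EVPI under deterministic dependence, and bounded by EVPI
within estimator noise (5% of EVPI + £0.01).

The pre-registered scenario catalogue has 21 entries: reduced stage-specific
cancer mortality with screen detection (full and half impact, implemented as
per-stage mortality multipliers in the screening arm); stage shift halved
(mixing the screen stage mix halfway toward the symptomatic mix); stage IV
share ±25% (renormalising the other stages); metastatic and all-stage
treatment-cost multipliers (with and without kidney); kidney and all-cancer
prevalence doubled/halved; a 0.003 one-off utility decrement per secondary
finding; the wider 55–81 trial age distribution; 1.5% and 5% discount rates;
and disease-inclusion masks (no AAA, only AAA, only kidney findings).

## The synthetic parameter set

The generator produces a complete, validated configuration whose structure
matches the model's inputs.  Its defaults are fixed study conditions, chosen
once to sit at realistic magnitudes and to reproduce the printed anchors of
the trial it emulates:

* expected screen-detected counts per 4019 scanned of roughly 9 kidney
  cancers, 10 other cancers, 60 AAA and well over 100 serious secondary
  findings;
* an overall positive-screen fraction near 0.27 (the weighted-average screen
  cost of ~£26.77 implies a positive rate of about 0.28);
* a contribution pattern in which AAA is the dominant positive contributor,
  kidney cancer the second, colon/upper-urinary-tract/stomach small
  positives, pancreas/liver/lymphoma/gallbladder negatives (poor early-stage
  prognosis or indolent disease makes early detection cost without
  commensurate benefit), and kidney secondary findings the largest negative
  row, driven by their sheer number.

Treatment costs use a single kidney-derived schedule applied to all cancers
(first-year versus subsequent-year costs by stage, with ongoing systemic
therapy costs in stage IV).  Other-cause mortality is a Gompertz curve
adjusted for smoking on the hazard scale (HR 2.0), which preserves [0, 1]
and composes multiplicatively.  Cohort weights decline with age and carry a
54/46 male/female split.

What the generator does *not* emulate: correlation between parameters beyond
dirichlet simplexes, age-dependence of secondary-finding prevalence, repeat
screens, multi-morbidity (one finding per person), and any claim that its
values equal the unpublished study inputs.  Passing tests therefore
demonstrate that the machinery is correct and that the qualitative economics
of the screening problem are reproduced under realistic conditions — not
that the headline numbers would match a re-run of the original study.

## Numerical choices and limitations

* Calibration root-finding uses Brent's method on [1e-15, 1−1e-15] at
  machine tolerance; boundary targets (a stage share of 0 or 1) short-circuit
  to 0 or 1−1e-9.
* Degenerate screen detection (zero prevalence) is flagged and the cohort's
  stage mix is irrelevant (zero weight everywhere downstream).
* The PSA problem size (2000 draws over 40 active cohorts, 11 diseases, two
  arms, annual cycles to age 100) runs in a few minutes on one core via a
  vectorised cohort-batched engine, verified identical to the per-cohort
  reference engine to 1e-10.
* Diagnosis counts for AAA are not tracked (the AAA model has no symptomatic
  diagnosis event in the control arm), so "additional diagnoses" for AAA is
  reported as zero.
* The age/sex sweep re-evaluates the full pipeline per single cohort and is
  the slowest of the deterministic outputs (a few seconds).
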