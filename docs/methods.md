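# Methods

## Model

`brcasim` simulates the life course of a woman carrying a BRCA1 or BRCA2
pathogenic variant after breast-conserving therapy (BCT) for unilateral
stage I/II breast cancer, as a discrete-time competing-risks process on a
temporal Bayesian network.  Seven time-varying binary variables are unrolled
into one node per step — `rrso_performed`, `ipsilateral_event`,
`contralateral_bc`, `ovarian_cancer`, `death_bc`, `death_oc`, `death_other` —
with absorbing semantics: P(true at step k | true at step k-1) = 1, and while
false the activation probability comes from a conditional probability table
assembled from the evidence model.  The default grid is 40 annual steps; the
validation scenario uses 6 steps of 2.5 years.

Canonical parent structure (the published description only sketches it as
expert-structured; this DAG is the package's design):

* the static covariates (gene, exon group, age group, subtype, stage, chemo,
  policy) parent every temporal hazard node;
* `rrso_performed` parents `ovarian_cancer`, `ipsilateral_event` and
  `death_other` at the following step;
* `ipsilateral_event` and `contralateral_bc` parent `death_bc`;
* `ovarian_cancer` parents `death_oc`;
* each variable's step-k node parents its step-(k+1) node.

The model is exercised by ancestral (forward) sampling only; no exact
inference is performed.

## Hazard assembly

All published cumulative risks are converted with
`rate(p, o) = -ln(1-p)/o` and `q = 1 - exp(-rate * c)` where `c` is the step
length in years (1.0 or 2.5).  A multi-segment schedule (e.g. 10- and 25-year
cumulative risks) is treated as piecewise-constant hazard; beyond the last
published horizon the final segment's hazard is extended.  Composition of the
per-step probabilities reproduces the published cumulative values at segment
boundaries to machine precision and is invariant to step refinement (tested
to 1e-9).

**Event-risk reductions are rate multipliers.**  "Reduces risk by 58%" is
implemented as `rate x (1 - 0.58)`, i.e. a constant cause-specific hazard
ratio of 0.42.  This choice is horizon-invariant (the same reduction composes
identically on 1-year and 2.5-year grids) and makes the paired-arm recovery
of each effect equal its configured value exactly in expectation.  Applied
this way: RRSO on the ipsilateral hazard (0.58, post-BCT only), chemotherapy
on the ipsilateral hazard (0.49), tamoxifen on the contralateral hazard
(0.56 BRCA1 / 0.67 BRCA2), contralateral mastectomy (0.90), RRSO on the
ovarian hazard (0.80 BRCA1 / 0.79 BRCA2).  RRSO has no effect on the
contralateral hazard, and chemotherapy adds nothing to the contralateral
protection of tamoxifen; both assumptions are encoded structurally (the CPT
rows are identical across those parent configurations).

**The tamoxifen mortality effect is a cumulative-incidence multiplier.**
"Reduces 15-year mortality by 30% in luminal disease" is a statement about
cumulative mortality, not a hazard ratio, so the luminal first-primary
cumulative mortality curve is multiplied by 0.70 for the first 15 years;
after the window, hazard increments revert to the reference curve.  A rate
multiplier of 0.70 would recover only ~27-28% at 15 years at realistic
mortality levels.  This is the one effect deliberately not treated on the
rate scale.

**Ipsilateral mastectomy** (part of RRBM) switches the ipsilateral channel to
the post-mastectomy local-failure schedule, and post-mastectomy local events
are assumed not to contribute mortality (isolated locoregional recurrence
after mastectomy carries no survival impact); chemo/RRSO multipliers apply to
the post-BCT hazard only.

**Second events.**  When an ipsilateral (post-BCT) or contralateral event
activates at step k, its stage is drawn from the second-event stage
distribution (DCIS / I / II / III / de-novo metastatic) and its subtype from
the gene-specific triple-negative prevalence (0.69 BRCA1 / 0.15 BRCA2).  From
step k+1 the event contributes its stage/subtype-specific mortality rate,
*summed* with the first primary's on the hazard scale.  DCIS contributes a
lifetime (40-year) cumulative mortality of 3.3%; metastatic disease carries
mortality 1.0, approximated as 0.9999 over 5 years because certainty has no
finite hazard.

**Ovarian cancer** uses a constant annual rate implied by the gene x
exon-group lifetime (to age 80) risk; on detection a stage is drawn and the
stage-specific ovarian mortality schedule runs from the following step.

**Other-cause death** uses an annual probability by attained 5-year age band
(representative cohort ages 35/45/65 as origin).  When RRSO is performed
before age 45 in a woman diagnosed before 40, the other-cause rate is
multiplied by an excess factor (placeholder 1.5).

**RRSO timing** is drawn uniformly from the first 5 years of follow-up
(policy-dependent), configurable to a fixed step; the recovery experiments
fix it at year 0 so the marginal hazard ratio equals the configured effect.

## Simulation engine

Patients are allocated uniformly across cohort x policy cells with a
round-robin remainder in enumeration order.  Sampling is vectorised per cell:
at every step six uniform draws per patient are consumed in a fixed order
(ipsilateral, contralateral, ovarian, breast-cancer death, ovarian death,
other death), for all patients whether or not still at risk, plus a fixed
block of one-time draws (RRSO timing, event stages/subtypes).  Each cell has
its own numpy substream keyed by `(root seed, cohort index, policy index)`.
Two consequences: runs are exactly reproducible given the seed, and two arms
that share cell coordinates consume identical uniforms — common random
numbers — which is what makes the paired effect-recovery experiments tight.

Within a step, event variables are resolved before death variables, and a
second cancer influences death hazards only from the following step.  Ties
among death causes within a step are attributed breast cancer > ovarian
cancer > other; the rule affects cause labels only, never survival times.
Survival time is `step_index x step_years` at the first death activation, or
the horizon under administrative censoring (no earlier censoring exists).

## Summarisation

Kaplan-Meier curves and Cox proportional-hazards fits (Efron tie handling —
the discrete grid produces heavy ties) are delegated to lifelines.  The
multi-group log-rank statistic is computed internally in observed/expected
covariance form so per-group O/E counts are available, and is cross-checked
against lifelines' implementation in the test suite.  No confidence intervals
or P values accompany simulation output — simulated data admit no sampling
interpretation for them — though the test suite uses them internally for
statistical acceptance bounds.

## Parameters, provenance, placeholders

Every entry in the default `ParameterSet` carries a provenance tag.
`paper_body` entries are the printed evidence anchors: the effect sizes
above, the 10-year contralateral risks (27% BRCA1 / 19% BRCA2, assigned to
the 40-50 onset stratum), DCIS mortality 3.3%, metastatic mortality 1.0, TN
prevalence 0.69/0.15, the first-primary stage distribution 52.3/43.1/4.0
(stored as printed, sum 0.994, renormalised at sampling), the 80-year
ovarian-risk horizon, and the 5-year RRSO window.  `placeholder` entries
stand in for values that live only in supplementary tables or cited
literature: stage/subtype mortality schedules, age-stratified contralateral
schedules (the <40 and >50 strata, and all 25-year extensions), local-failure
incidence after BCT and after mastectomy, ovarian stage distribution and
stage-specific survival, other-cause mortality by age, the RRSO excess
multiplier, the second-event DCIS/metastatic shares, and a chemotherapy
effect on first-primary breast-cancer mortality (rate multiplier 0.70,
EBCTCG-scale) without which chemotherapy — reported as the dominant survival
factor — would have no mortality channel at all.

Placeholders are monotone and clinically plausible but are *not* the original
study inputs, so absolute survival curves produced with the default fixture
are illustrative, and published absolute survival figures are not
reproduced.  Every acceptance-grade check is placeholder-insensitive by
design: structural counts, allocation arithmetic, conversion identities, and
paired-arm recoveries in which both arms share all placeholders.

## Problem sizes and numerical choices

The recovery experiments use 200,000 patients per arm in
`scripts/acceptance.py` (Monte-Carlo standard errors of 0.2-0.8 percent
points) and 30,000 per arm in the test suite, both with 3-standard-error
acceptance bounds; the Cox SE is used for hazard-ratio recoveries and
binomial delta-method SEs for the cumulative-mortality recovery (the
favourable common-random-numbers covariance is ignored, making the bounds
conservative).  The full-study default of 1,000,000 patients (≈6,944 per
cohort, ≈771-772 per cell) is exercised as allocation arithmetic; simulation
examples and the validation scenario run at 20,000-100,000 patients.
Probabilities are handled with `log1p`/`expm1` throughout; conditional
per-step probabilities derived from cumulative curves are clipped to [0, 1]
against floating-point drift.

## Known limitations

* Risk modifiers are assumed independent and multiplicative on the hazard
  scale; no interactions are modelled.
* Second-event mortality ignores tamoxifen and chemotherapy received for the
  *second* cancer (no treatment model exists for second events).
* The ovarian hazard is constant in age (lifetime risk spread evenly to the
  horizon); real ovarian incidence is age-increasing, so the age-65 stratum's
  short remaining exposure is approximated.
* The exon-group ovarian-risk table and all mortality schedules are
  placeholders, as above; conclusions about absolute survival or about the
  *ranking* of policies in a specific clinical stratum require substituting
  the user's own evidence via a parameter file.
* The validation scenario exports curves for external comparison only; the
  reference cohort's individual-level data are not packaged.
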