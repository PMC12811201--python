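# Methods

## Model overview

`gateopener` implements a discrete-time (annual-cycle) multistate model of
colorectal-cancer (CRC) natural history and overlays screening strategies on
it. The disease process follows the adenoma–carcinoma sequence as a
single-step chain

```
no neoplasm → non-advanced adenoma → advanced adenoma → preclinical CRC
            → clinical CRC → CRC death
```

with other-cause (background) mortality acting on every alive state and CRC
case fatality acting on clinical cases as a function of years since
diagnosis and mode of detection. Screen-detected cancers carry lower annual
case fatality than symptom-detected ones, reflecting the earlier stage at
diagnosis; the two case-fatality rows are linked by a proportional-hazards
transform `q_screen = 1 − (1 − q_symptom)^HR` with HR < 1. Adenomas do not
regress, pathways are not distinguished (no serrated/classical split), CRC
is not stage-stratified, and there is no distal/proximal stratification.

### Within-cycle event order

The order of events inside one yearly cycle is a genuine modelling choice;
we fix it as:

1. screening events for the year (offers, tests, follow-up colonoscopies);
2. disease progression by one step along the chain (a natural
   preclinical→clinical transition is a *symptom-detected* diagnosis);
3. other-cause death, applied to every alive state including clinical CRC;
4. CRC death applied to clinical cases by `case_fatality[years_since_dx,
   mode]`;
5. years-since-diagnosis incremented.

Consequences worth knowing: a person can progress and die of other causes
in the same cycle; newly diagnosed cases face first-year case fatality in
their diagnosis year; screening at year 0 acts on the baseline population
before any progression. Ages advance with calendar year, with no half-cycle
correction. CRC deaths are counted whenever they occur inside the horizon,
regardless of diagnosis year.

### Execution modes

Every flow in the model is linear in state occupancy (independent Bernoulli
events per person), so the deterministic *expectation mode* — propagating
fractional cohort occupancies — is the exact mean of the *microsimulation
mode*, which draws each of the `n` individuals with a seeded generator.
The test suite verifies agreement within 3 Monte-Carlo standard errors over
20 replicates at n = 100,000. Expectation mode is the default for
comparisons (noise-free orderings); microsimulation is available for
distributional questions and is bit-reproducible under a fixed seed.

## FIT test performance

A quantitative FIT result at or above the hemoglobin cutoff is positive
(closed lower bound; the comparison operator is our choice and is applied
consistently in classification and simulation). The packaged
characteristics table covers cutoffs 17/10/8/6/4/3 μg Hb/g with aggregate
positivity, sensitivities for the nested lesion groups, and specificity for
the no-advanced-neoplasm group. No interpolation between cutoffs is ever
performed — characteristics at other cutoffs must come from record-level
recomputation — because inventing a dose–response shape between published
points would be a stronger assumption than refusing to.

The simulator consumes *per-state* positive probabilities, obtained from
the aggregates by a triangular mixture solve over the group counts
(n = 7398; 2115 any neoplasm; 728 advanced neoplasm; 54 preclinical
cancers; 6670 without advanced neoplasm). Published aggregates are rounded
to one decimal, so the solve can land marginally outside [0, 1]; results
are clamped with a warning. Count-weighted re-aggregation reproduces all
packaged aggregates within 0.5 percentage points (tested). Note the
specificity denominator deliberately includes non-advanced adenoma
carriers; the decomposition resolves this into a genuinely lesion-free
false-positive rate plus a non-advanced-adenoma positive rate, which is
what the state-transition engine needs.

## Screening strategies and adherence

* **Screening colonoscopy**: offered in 10-year intervals (once within the
  10-year horizon), used by 15% of invitees (default). Non-participants at
  year 0 are not re-offered within the horizon.
* **Biennial FIT**: cutoff fixed at the manufacturer preset of 17 μg/g,
  offered at years 0, 2, 4, 6, 8; 50% first-round uptake (default).
* **Gateopener**: a single low-cutoff FIT per decade (year 0), 50% uptake;
  only positives are invited to screening colonoscopy.

A positive FIT leads to diagnostic colonoscopy with 80% compliance;
refusers keep their FIT counted and receive no state change and no
re-invitation. The colonoscopy acts on the **true** state — adenomas found
incidentally at a colonoscopy triggered by a "false-positive" FIT are still
removed — which is precisely what makes very low cutoffs effective.
Adenoma removal returns the person to the no-neoplasm state unless the
lesion is missed (defaults: 26% non-advanced, 9% advanced, 5% preclinical
CRC, approximating meta-analytic miss rates; true miss rates are uncertain).
One FIT kit is counted per participation; screening and diagnostic
colonoscopies are pooled in a single colonoscopy counter.

**Drop-out mechanics.** Biennial participation is modelled as: accept the
first offer with `p_fit_first`; a participant of round *k* returns at round
*k+1* with probability `1 − dropout` (default 0.6); drop-out and first-round
refusal are absorbing (no sporadic re-entry). With the defaults this gives
round participations 50%, 30%, 18%, 10.8%, 6.5% — a mean biennial
participation of ≈23%, consistent with the ≈20% biennial participation
observed in the emulated population, and a single gateopener FIT uses
≈55% fewer kits than the biennial program. We considered the alternative
of solving a per-round retention so that cumulative drop-out over the whole
horizon equals 40% (retention 0.6^¼ per round); it implies a mean biennial
participation of ≈39% and a FIT-kit reduction of ≈75%, both far from the
observed figures, and was rejected.

Sensitivity presets: `adherence60` raises FIT-based uptake to 60%;
`dropout30` lowers drop-out to 30%.

## Outcomes

Prevented cases/deaths are cumulative 10-year differences versus the
matched no-screening arm; they may be negative and are kept as-is.
Efficiency ratios (colonoscopies or FITs per prevented case/death) are
undefined — reported as NaN and excluded from comparisons — when prevented
events are non-positive. Sexes are simulated separately and also reported
pooled (cohort-size-weighted), since headline comparisons are typically
quoted across ages with sexes pooled while stratified views need the split.
League tables are long-format with relative differences (integer percent)
against the conventional colonoscopy and biennial-FIT arms. Note that early
detection of preclinical cancer *increases* in-window case counts (the case
is diagnosed sooner) while decreasing deaths; prevented cases are driven by
adenoma removal, prevented deaths by both removal and the detection-mode
survival benefit.

## Synthetic data

### FIT cohort

The Hb generator models, per finding category, a zero-inflated mixture of
two log-normal components; values below the assay limit of detection
(1.7 μg/g) are floored to 0. Only thresholded exceedance probabilities
matter downstream, so the family is a vehicle, not a distributional claim —
but a *single* zero-inflated log-normal cannot follow the observed
exceedance curves (they are not probit-linear in log-cutoff; single-component
residuals reach ~5 pp for the lesion-free and preclinical-cancer groups),
hence the two-component mixture, which fits all aggregates within ≤0.5 pp.
Calibration decomposes the aggregate targets to per-state curves and fits
each state by bounded least squares from a small set of fixed starting
points; it is deterministic. Generated cohorts of the reference-study size
(n = 7398) reproduce the packaged characteristics within ±2 pp at all six
cutoffs (10-seed average, tested). The generator does not attempt
covariate structure beyond the category mixture and Hb marginals, and the
packaged characteristics are sex-agnostic.

### Natural-history parameters

The parameter generator emulates a previously unscreened German
screening-eligible population. Defaults (chosen once, with the reasoning
below, and not revisited):

| quantity | default (men, age 50) | age/sex structure | why |
|---|---|---|---|
| no → non-adv. adenoma | 0.011–0.013 /yr | ×e^{0.02(age−50)}; women ×0.75–0.85 | adenoma incidence in screening registries |
| non-adv. → advanced | 0.014–0.016 /yr | ×e^{0.02(age−50)} | slow progression of small adenomas |
| advanced → preclinical CRC | 0.028–0.032 /yr | ×e^{0.015(age−50)} | ~3%/yr malignant transformation of advanced adenomas |
| preclinical → clinical | 0.21–0.23 /yr | flat | mean preclinical sojourn ≈ 4.5 years |
| baseline prevalence (non-adv/adv/preclin) | ≈14% / 5% / 0.2% | ×1.25/1.45/2.0 per decade; women ×0.75–0.85 | screening-colonoscopy finding rates by age and sex |
| other-cause mortality | ≈0.004 /yr | ×e^{0.085(age−50)}; women ×0.65 | period life-table shape |
| CRC case fatality, year 1 | 0.11–0.13, ×0.85/yr thereafter | screen-detected via HR 0.45–0.55 | ≈65% five-year survival; stage-shift benefit of screen detection |

Each draw is uniform within its range from the given seed; zero-width
ranges make the set fully deterministic. 95% CI half-widths are ±15%
(transitions) and ±10% (prevalences); mortality and case fatality carry
degenerate bounds (bound = point), so replacing points by CI bounds
perturbs exactly the prevalence/transition set varied in sensitivity
analyses. Under CI perturbation the lesion-free baseline prevalence is set
to the complement of the perturbed lesion prevalences so vectors still sum
to 1. With these defaults, 10-year no-screening cumulative incidence is
≈1.9% and CRC mortality ≈0.6% for 60-year-old men — plausible for the
emulated population.

**What passing tests show, and don't.** The synthetic generator reproduces
the *structure* of the real inputs (state mixture, thresholded test
performance, age/sex gradients, CI bracketing), not their exact registry
values. Comparative results on synthetic parameters therefore support
orderings and signs — which strategy prevents more events, how outcomes
move with the cutoff — rather than exact absolute counts for any real
population.

## Numerical choices and problem sizes

* Expectation mode uses exact linear propagation; conservation of cohort
  size holds to machine precision and is asserted every cycle.
* Case-fatality lookups beyond the table use the last row (flat
  extrapolation), with a log notice.
* Parameter validation (probabilities in [0, 1], per-state outgoing sums
  ≤ 1, CI bracketing, prevalence sums = 1 within 1e-9) runs before every
  cycle; violations raise before any state is mutated.
* Arm-level random streams are derived from the global seed keyed by the
  arm's (strategy, age, sex) identity, so adding arms to a grid never
  changes existing arms.
* Standard problem sizes: cohorts of 100,000 per age/sex stratum, 10-year
  horizon, ages 50/60/70, both sexes (54 arms in the default grid);
  microsimulation/expectation cross-checks use 20 replicates at n = 100,000;
  FIT-cohort calibration closure uses 10 seeds at n = 7398.

## Known limitations

* The time lag between a positive FIT and the diagnostic colonoscopy is not
  modelled; surveillance colonoscopy after polypectomy, colonoscopy
  complications, and repeated gateopener rounds beyond the 10-year horizon
  are out of scope.
* Aggregate test characteristics are treated as sex- and age-invariant.
* Adenoma miss rates are defaults from the literature, not calibrated.
* Absolute outcome counts inherit the synthetic parameter set; only
  relative comparisons between strategies run on identical parameters are
  interpretable as findings.
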