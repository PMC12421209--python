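# Methods

This note documents the models, conventions and design choices behind
`jitaisim`: what the synthetic cohort emulates, how the trigger engine and the
personalized control charts are defined, which analysis conventions the
feasibility statistics follow, and where the design was genuinely open.

## Synthetic EMA cohort

### Generative model

Each person has parameters drawn once from population distributions
(`PopulationConfig`), then an EMA stream over the schedule grid (21 days × 6
two-hour windows between 08:00 and 20:00; one row per scheduled prompt).

* **Latent distress.** Per variable (negative affect, stress, loneliness,
  rumination), a stationary first-order autoregressive Gaussian process:
  x_t = μ + φ(x_{t−1} − μ) + ε_t, with ε_t ~ N(0, σ²(1−φ²)), so the marginal
  within-person SD is σ regardless of φ. AR(1) is the minimal process with the
  within-person serial dependence that intensive-longitudinal analyses
  presuppose; no generative model is prescribed by the study design itself.
* **Discretization.** Likert items are produced by round-half-up then clipping
  to [1, 7]. This map is monotone (raising a latent value never lowers the
  item) and exactly invertible nowhere — deliberately simple and testable.
* **Completion.** Independent Bernoulli(compliance) per prompt. Only marginal
  compliance is emulated; real missingness is likely state-dependent (see
  Limitations).
* **Support need.** The trinary item is "I have no worries" when the mean of
  the four latent values falls below `no_worries_threshold` (default 2.0);
  otherwise "yes" with probability logistic(a + b·m) of the latent mean m
  (defaults a = −5, b = 1, giving a "yes" base rate around 8–12% at typical
  distress levels), else "would not help". The true link between distress and
  felt support need is unknown; the slope is configurable down to zero.
* **Attention checks.** Shown with probability 1/7 on completed prompts;
  answered 5 unless a careless event (per-person probability ~Beta with mean
  0.015) draws uniformly from {1..7}\{5}.
* **Support seeking.** Latent N(μ_seek, σ_seek) per prompt (no serial
  dependence), discretized like the distress items.

### Population defaults (units: Likert points unless noted)

| parameter | default | rationale |
|---|---|---|
| μ population mean / SD | 3.0 / 0.8 | moderate average distress, marked between-person heterogeneity; yields a fixed-cutoff hit rate near 1/3 of EMAs |
| within-person SD mean / SD | 1.2 / 0.25 | between the typical within-person SDs of momentary distress items (~1.1–1.5) |
| AR coefficient mean / SD | 0.4 / 0.15 (clipped to [0, 0.95]) | moderate inertia typical of multi-per-day EMA sampling |
| compliance Beta mean / concentration | 0.85 / 3.83 | mean ~85% with between-person SD ~0.16 |
| careless Beta mean / concentration | 0.015 / 30 | careless responding rare (~1.5% of checks) |
| support-seeking μ mean / SD, σ | 2.7 / 0.6, 2.2 | observed-item mean near 2.8 and SD near 2.0 after discretization |

### Injectable intervention effects

At each *delivered* intervention, behaviour adoption is drawn with the
assigned condition's probability (defaults 0.23 fixed-cutoff / 0.22 SPC /
0.43 support-need). When adopted, the **next completed same-day EMA** gets its
latent distress reduced by `effect_delta` (default 0.6) and its latent
support seeking raised by `support_seek_shift` (default 2.1) before
re-discretization. The post-intervention items (appropriate timing on 1–7,
behaviour adoption yes/no) attach to the next completed EMA even when
scheduled prompts were missed in between; an evening helpfulness rating is
generated for each day with at least one delivery, keyed to the day's first
delivered condition.

Calibration: with the default adoption mix, `support_seek_shift = 2.1`
produces a delivered-vs-omitted standardized effect of ≈ 0.24 on the observed
support-seeking item in large cohorts — the shift exceeds the naive value
(marginal effect / adoption rate ≈ 1.9) because discretization and the
scale ceiling attenuate the latent shift. `effect_delta = 0.6` yields distress
change-score effects of |d| ≈ 0.10–0.15, small effects of the size such
interventions plausibly produce. Timing/helpfulness means per condition
(timing 3.0/2.3/4.4, helpfulness 3.5/3.6/4.65 for fixed/SPC/need, SD 1.8)
encode the qualitative ordering that self-identified need moments are rated
better than inferred-distress moments.

### Randomness

One master seed; every stage and person gets a child generator via
`SeedSequence(seed, spawn_key=(stage, person_index))`. Cohort subsets and
single stages therefore regenerate bit-identically regardless of what else
runs.

## Personalized control charts

Individuals (subgroup size 1) Shewhart charts, one per person per distress
variable, in a classical two-phase design:

* moving ranges between successive **completed** observations, ignoring gaps
  from missed prompts and overnight breaks (the definition indexes successive
  observations without exclusions);
* σ̂ = mean(MR)/d₂ with d₂ = 1.128 (2/√π, the expected range of two
  independent standard normals);
* UCL = phase-1 mean + L·σ̂ with L = 2, a one-sided in-control false-alarm
  rate of 2.28% per observation for Gaussian data;
* **growing window**: while the baseline phase lasts (days 1–7), each decision
  uses the chart fitted to all completed observations *strictly prior* to the
  current EMA; after day 7 the chart freezes on the full day-1..7 window;
* **strict exceedance**: a value signals iff value > UCL; ties do not trigger
  (an item equal to its UCL is not "exceeding" it);
* **UCL only**: the intervention concerns elevated distress; no lower limit,
  no CUSUM/EWMA, no recalibration after the freeze.

Open points resolved as package choices: (1) phase-1 estimation includes
observations recorded after delivered interventions (a config switch,
`include_post_delivery_baseline`, allows excluding them for sensitivity
analyses); (2) an exceedance is always judged against the pre-update chart —
the current observation never contributes to the limit it is compared with;
(3) the chart condition is evaluable only once all four charts have ≥ 7
completed baseline observations; with 2–6 observations a chart can be fitted
for inspection but the engine reports "insufficient baseline".

## Trigger engine

At every completed intervention-phase EMA the engine evaluates **all three**
criteria (needed for overlap accounting and omitted-control logging — the
evaluations are side-effect free), randomizes the condition (default equal ¼
probabilities; the realized delivery split reflects criterion base rates, not
assignment probabilities), and delivers iff the assigned condition's own
criterion is met and fewer than `max_per_day = 2` interventions were already
delivered that calendar day. Ordering: randomize → criterion → cap, so a
cap-suppressed decision is one that *would* have delivered; the cap counts
deliveries only, and resets at local midnight. Missed prompts in the
intervention phase yield placeholder decisions (`ema_missing`); condition-4
decisions with ≥ 1 criterion met are flagged `omitted_control`.

## Analysis conventions

* **Compliance**: completed/scheduled per person; feasibility iff ≥ 70% of
  persons reach ≥ 70%. The overall rate is the mean of person rates (equal to
  pooled completed/scheduled under the balanced schedule).
* **Careless rate**: shown-and-not-5 over shown; undefined (not 0) when no
  check was shown.
* **Descriptives**: between-person SD is the SD of person means (ddof = 1,
  undefined for a single person); mean within-person SD averages per-person
  SDs over persons with ≥ 2 observations.
* **Welch contrast**: explicit textbook formulas (t, Satterthwaite df,
  two-tailed p from the t distribution); Cohen d uses the (n−1)-weighted
  pooled SD. Binary adoption is analyzed as 0/1 means; p-values are reported
  unadjusted.
* **Change scores**: Δ = x(T+1) − x(T), negative = reduction, matching the
  convention that improvements appear as negative means. T+1 is the next
  *completed* EMA of the same person; pairs whose follow-up crosses midnight
  are excluded (counted separately). Strata: `delivered`; `omitted` (condition
  4, ≥ 1 criterion met); `cap_suppressed` (own criterion met, cap reached) —
  kept out of both main strata; `not_triggered` otherwise.
* **Helpfulness** contrasts use only days with exactly one delivery, since the
  rating is collected once per evening.

### A structural caution on delivered-vs-omitted contrasts

Even with zero injected effects the delivered and omitted strata are *not*
exchangeable under the default configuration: a moment satisfying k criteria
is delivered with probability k/4 but logged as omitted with probability 1/4,
so multi-criterion (more extreme) moments are overrepresented among
deliveries, and regression to the mean then produces a small systematic
difference in change scores (≈ −0.045 Likert points in 25-person cohorts)
that a naive t test will flag at above-nominal rates in large samples. This
is a property of the trial design's conditioning, not of the estimator. The
type-I calibration of the analysis machinery is therefore checked under a
single-active-criterion null configuration (support-need only: unreachable
cutoff, L = 50), in which the strata differ only by randomization; there the
empirical rejection rate is nominal. Users contrasting delivered vs omitted
moments in multi-criterion designs should be aware of this composition bias.

## What the generator does and does not emulate

It reproduces the data *structure* the analyses assume: per-person Likert
dynamics with serial dependence, trinary support need, marginal compliance,
rare careless responding, the post-intervention item attachment rule, and
injectable proximal effects with ground truth. It does **not** emulate
state-dependent missingness, time-of-day or weekday cycles, floor-inflated
item distributions, correlated residuals across the four items, learning or
reactivity effects, or any real-world content of the intervention. Passing
tests therefore validate the pipeline's logic and statistical calibration on
a known-truth world, not the behaviour of any real population.

## Problem sizes and tolerances

Monte-Carlo checks use: 200,000 draws for chart false-alarm calibration
(99% binomial interval), 1,000 random instances for the chart and Welch
oracle equivalences (1e-10), 100,000 draws for randomization frequencies,
500-person cohorts for parameter recovery (compliance within 3 SE; effect
size within ±0.1; adoption difference within ±0.05), and 1,000 replicate
25-person cohorts for the null type-I check (99% interval around 0.05).
Floating-point chart identities hold to 1e-12.

## Known limitations

* The engine loops per EMA in Python; cohorts of a few hundred persons run in
  seconds, but the design is clarity-first, not a large-scale simulator.
* Inference on change scores ignores within-person clustering; with
  observation-level randomization the impact is small, and multilevel models
  are deliberately out of scope.
* The evening helpfulness model keys to the day's first delivered condition
  only; multi-delivery days are generated but excluded from analysis by design.
* Between-person heterogeneity in adoption and effect sizes is not modeled
  (condition-level constants only).
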