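# Methods

## Measurement model

All procedures assume classical test theory with Gaussian error: an
observed score is a stable true score plus noise, `O = T + eps`,
`eps ~ N(0, TE^2)`, with a single typical error (TE) shared across the
population being tested. TE pools instrumentation noise and biological
noise; it is distinct from *biological variability*, the non-intervention
processes that genuinely change true scores over weeks (handled at the
group level, below).

### TE estimators

| Source | Estimator | df |
|---|---|---|
| k repeats, one individual | sample SD (denominator k−1) | k−1 |
| n-subject group test–retest | SD(test2 − test1) / √2 | n−1 |
| published CV% | CV · O / 100 | source n − 1, if known |

The √2 arises because a difference of two equally noisy observations has
variance TE² + TE² = 2·TE². Sample SDs use the n−1 denominator
throughout. The group estimator logs a heteroscedasticity hint when
|difference| and pair mean have Kendall tau > 0.5 — the single-TE
assumption is then suspect (error likely scales with the score) and a
log-scale analysis, which this package deliberately does not provide,
may be more appropriate. Incomplete test–retest pairs are dropped with a
logged count; n reflects complete pairs only. Units are carried as opaque
strings and never converted. Only the two-trial test–retest case is
supported; pooling TE across three or more trials per subject is out of
scope.

## Confidence intervals

True-score CI: `O ± m·TE`. Change CI: `(O_post − O_pre) ± m·√2·TE`.
The multiplier `m` is the standard-normal two-sided quantile at
(1+level)/2 when TE is treated as known, or the Student-t quantile with
df = n−1 when propagating the sampling uncertainty of a TE estimated from
n subjects ("adjusted"). This t rule reproduces the conventional
published multiplier grid at printed precision in 53 of 54 cells; the one
remaining cell (n=20, 95%, printed 2.10) sits one rounding ulp from
t's 2.093 and is treated as a typographical rounding artefact.
Full-precision quantiles are always used internally; 2-dp multipliers and
1-dp interval bounds are display conventions only. Intervals are
two-sided and symmetric; TE uncertainty is propagated only through the
df-adjusted multiplier (no second-order propagation).

The quick rule `change ± TE` spans ±1/√2 change-score SDs, so its exact
coverage is 2·Φ(1/√2) − 1 ≈ 0.5205; the returned interval records this
implied level rather than a nominal 50%. In the conservative success
case — the interval's lower bound exactly on the decision line — the
probability that the true change lies beyond the line is
Φ(1/√2) ≈ 0.760, which is what underwrites the rule's "better than 75%
in the long run" behaviour; both facts are asserted analytically and by
simulation in the test suite.

## Success classification

A smallest worthwhile change (SWC) is stored as a non-negative magnitude
plus a beneficial direction; this prevents double-negation bugs for
decrease-beneficial outcomes such as skinfold sums. The conventional
objective choice is 0.2 × baseline between-individual SD (Cohen's small
effect), computed by default over both arms' baseline values pooled.
An individual's intervention is *successful* when the whole change
interval lies **strictly** beyond the SWC on the beneficial side — a
bound exactly on the threshold does not count, and for decrease-beneficial
outcomes the signed comparison `upper < −swc` is used (an implementation
decision; comparing |change| would misclassify intervals straddling
zero). The verdict is deliberately binary; no harmful/trivial/unclear
trichotomy is offered. Under the ±TE rule the verdict is exactly
equivalent to "beneficially-signed observed change > SWC + TE", which is
what `required_observed_change` and the test-sensitivity screen report:
a test is flagged inadequate when TE exceeds the gap between the
expected improvement and the SWC.

## Proportion of response

Change-score variance in a control arm reflects measurement error plus
biological variability; in the intervention arm it additionally reflects
heterogeneous intervention effects. Hence

    sigma_IR = sqrt(SD_Int^2 − SD_Con^2)

over observed change scores, and intervention-attributable change is
modelled as N(mean intervention-arm change, sigma_IR) — centred on the
intervention arm's own mean, not on the between-arm mean difference,
which readers sometimes expect. The proportion of response is the tail
area of that normal beyond the SWC in the beneficial direction.

When SD_Con ≥ SD_Int the variance difference is non-positive: sigma_IR is
clamped to 0, a `degenerate` flag is set, a warning quoting the negative
variance difference is logged, and the proportion becomes a step function
(1 if the mean change is strictly beyond the SWC, else 0). This surfaces
"no evidence of response heterogeneity" rather than producing imaginary
numbers.

Uncertainty comes from a percentile bootstrap: subjects are resampled
with replacement within each arm independently (arm sizes fixed; whether
to resample arms jointly is underdetermined in the literature and
independent resampling is the choice here), the whole pipeline is
recomputed per replicate, and the CI is the (α/2, 1−α/2) quantile pair,
clipped to [0, 1]. Degenerate replicates contribute their 0/1 proportion
— discarding them would bias the interval — and their frequency is
reported. Defaults: 2 000 replicates, 95% level, mandatory explicit seed.

## Synthetic-data generator

`simulate_study` draws, per subject: a true baseline
N(baseline_mean, baseline_sd²); a biological drift N(0, bio_var_sd²)
applied identically and independently in both arms (exactly the
assumption that lets the control arm absorb error + drift); for
intervention subjects an effect N(effect_mean, effect_sd²) where
effect_sd is the true sigma_IR; and independent N(0, te²) observation
noise at pre and post. All noise is Gaussian, matching the framework's
own assumptions. A truth table (true scores, drifts, effects) is emitted
alongside the observed data: true scores are unknowable in real data, and
the simulator is precisely where they are knowable, enabling oracle
tests.

Defaults describe a 12-week two-arm supplementation trial with a
muscle-carnosine-like outcome (mmol/kg dry muscle): 10 subjects per arm,
baseline mean 20 and SD 10 (so the 0.2-SD SWC is 2.0), TE 0.52, drift SD
1.0 (control change SD ≈ √(1² + 2·0.52²) ≈ 1.24), effect mean 10.2,
effect SD 5.07, increase beneficial. The baseline mean of 20 is a
mid-range physiological muscle-carnosine value; location never enters
any estimator, as a test asserts.

What the generator does **not** emulate: non-Gaussian or heteroscedastic
error, autocorrelated repeats, dropout, arm-specific drift, or covariate
structure. Passing tests therefore demonstrate correctness of the
estimators under the framework's own assumptions, not robustness to their
violation in field data.

## Numerical and design choices

- Strict inequalities at all decision boundaries (an interval bound on
  the SWC, a degenerate mean exactly on the threshold → not
  successful / proportion 0).
- `required_observed_change` is the plain sum SWC + TE at full precision.
- Randomness funnels through `numpy.random.default_rng` with explicit
  seeds everywhere; same seed ⇒ bit-identical studies, bootstrap
  intervals and pipeline reports.
- Long (tidy) CSV is the canonical interchange layout
  (`subject_id,arm,time,outcome,value`); a wide one-row-per-subject
  import shim is provided because practitioner spreadsheets usually
  arrive that way.
- Monte-Carlo problem sizes in the test suite — 10 000 replicates for
  coverage, 200 replicates at n = 1 000/arm for sigma_IR recovery,
  50 × 2 000-replicate bootstraps at n = 200/arm for CI containment —
  were chosen to hold Monte-Carlo error comfortably inside the asserted
  tolerances while keeping the whole suite in seconds.

## Known limitations

- Single homoscedastic Gaussian TE; no log/percent error models,
  intraclass correlations or limits of agreement.
- No attribution of any one individual's change to the intervention —
  responder status at the individual level is treated as unknowable by
  design; only the group-level proportion is estimated.
- No covariate modelling of response moderators, and no crossover
  (repeated-intervention) designs.
- Two-sided symmetric intervals only; no Bayesian credible intervals or
  probabilistic magnitude labels.
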