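# Methods

## Effect measures

For a two-arm trial with control and experimental response rates `p_C`,
`p_E`, the package computes ARR = `p_E − p_C`, RR = `p_E/p_C`,
RRR = `RR − 1`, NNT = `1/ARR` and RNT = `1/p_C − 1/p_E`. The direction
convention is fixed throughout: *control* and *treatment* are explicit
roles, RNT is always control-reciprocal minus treatment-reciprocal, so
positive values favour the treatment. Equal rates give NNT = ∞ (a defined
sentinel, rendered "∞") and RNT = 0 exactly. RNT satisfies the identities
`RNT = ARR/(p_E p_C) = RRR/p_E`, which the test suite checks to 1e−12.

For right-censored time-to-event data, survival-rate versions evaluate the
Kaplan–Meier curves at a prespecified follow-up time τ
(`RNT_surv = 1/S_C(τ) − 1/S_E(τ)`, `NNT_surv = 1/(S_E(τ) − S_C(τ))`), and
RMST versions use the τ-normalised restricted means
(`RNT_RMST = τ(1/RMST_C − 1/RMST_E)`, `NNT_RMST = τ/(RMST_E − RMST_C)`).
`RNT_RMST` at τ is algebraically identical to the binary RNT applied to the
"rates" `RMST/τ`; this cross-module identity is asserted exactly in tests.
Survival-rate measures use only local information at τ — they flip sign at
a curve crossing and become unstable when both survival rates are small —
while the RMST measures integrate the whole follow-up profile and vary
smoothly in τ.

## Estimators

The Kaplan–Meier product-limit estimator is implemented directly (the
perturbation resampler needs a vectorised *weighted* variant anyway, so the
unweighted fit shares its conventions): events precede censorings at tied
times; evaluation beyond the largest observed time raises an error rather
than extrapolating; the pointwise variance is Greenwood's
`S(t)² Σ d_i/(n_i(n_i − d_i))`. When the last risk set is exhausted by
events the offending Greenwood term is dropped and the curve is flagged
(`var_truncated`), the variance then being a lower bound. RMST is the exact
area under the step function on [0, τ] with variance
`Σ_{t_i ≤ τ} A(t_i, τ)² d_i/(n_i(n_i − d_i))`, `A(t_i, τ)` the area under
the curve from `t_i` to τ. With no censoring these reduce exactly to the
empirical survival function, `p(1−p)/n`, the truncated sample mean, and its
plug-in variance `Var(min(T, τ))/n`; the suite asserts all four, and agrees
with lifelines (survival and RMST points, 1e−8) and with a frozen fixture
computed with R's `survival` package (RMST standard error, 1e−7).

## Confidence intervals

All intervals are two-sided level 1−α with the normal quantile `z_{1−α/2}`
computed from α (1.959964 at α = 0.05), never hard-coded.

* **Wald (binary RNT)** — delta method on the reciprocals:
  `RNT ± z √((1−p_C)/(n_C p_C³) + (1−p_E)/(n_E p_E³))`. Undefined at
  boundary rates (0 or 1); the error message points to the resampling
  methods.
* **NNT intervals** — the Wald CI of the rate (or survival-rate, or
  RMST) difference is inverted. If it excludes zero the reciprocal bounds
  form an ordinary interval; if it spans zero the confidence region is the
  union of two half-lines reported as `NNTB 1/upper to ∞ to NNTH
  −1/lower`, rendered losslessly by the CLI.
* **Bootstrap percentile (binary RNT)** — stratified by arm; resampling
  subjects with replacement within an arm is equivalent to drawing the
  replicate responder count from Binomial(n, p̂), which is how replicates
  are generated. Replicates with a zero-responder arm are redrawn (RNT is
  undefined there); a warning fires if over 1% of replicates needed a
  redraw. Percentiles use linear interpolation.
* **Exact-style (binary RNT)** — per-arm Clopper–Pearson bounds mapped
  through the decreasing transform `p ↦ 1/p` (roles of the bounds reverse)
  and combined by the MOVER square-and-add rule for a difference. This is
  deliberately conservative: simulated coverage at n = 20/arm,
  p = (0.3, 0.5) is ≈ 0.97 at nominal 0.95. Zero responders give a
  one-sided infinite bound, flagged.
* **Wald (survival)** — delta method with Greenwood variances:
  `RNT_surv ± z √(Var(S_C)/S_C⁴ + Var(S_E)/S_E⁴)` and
  `RNT_RMST ± τ z √(Var(RMST_C)/RMST_C⁴ + Var(RMST_E)/RMST_E⁴)`.
* **Perturbation resampling (survival)** — each replicate draws one
  standard-exponential weight per subject (non-negative, unit mean and
  variance) and recomputes the weighted KM curve or RMST per arm; the CI is
  the percentile interval of the replicated measure. Exponential
  multipliers are the standard choice for this scheme; weighting is per
  subject, applied to both the event and at-risk processes. Replicates
  where the measure is undefined are dropped with a warning; more than 10%
  undefined raises an error. Simulated times are continuous, so the
  weighted estimator processes subjects individually in time order (ties
  have probability zero; the unweighted fit aggregates ties).

Profiles (`effect_profile`) evaluate any subset of the four survival
measures over a τ grid (default: union of both arms' event times, thinned
to ≤ 200 points); per-τ failures become flagged missing rows, infinite NNT
values are retained, and survival-rate entries are flagged "unstable" when
either arm's estimated survival falls below 0.05, where direct inversion of
small rates becomes erratic.

## Synthetic trials

The simulator draws event times by inverting a piecewise-constant
cumulative hazard at standard-exponential draws; administrative and/or
random (uniform, exponential) right censoring is applied on top. Because
the survival function and its integral are analytic for piecewise
exponentials, every effect measure's true value is available in closed
form, making the estimators testable for consistency. One root seed spawns
per-component child streams (`numpy.random.SeedSequence`), so seeded runs
are bit-reproducible and adding a consumer does not shift existing draws.

Four presets encode canonical two-arm geometries; the hazards are this
package's own choices, picked so the qualitative claims hold with clear
margins in closed form (all rates per unit time):

| preset | control | treatment | horizon | geometry |
|---|---|---|---|---|
| a | 0.25 | 0.125 | 4 | proportional hazards, treatment better |
| b | 0.5 | 0.25 then 0.75 (break at 1) | 2 | curves meet exactly at the horizon |
| c | 0.5 | 0.15 then 1.2 (break at 1) | 2.5 | single crossing at t = 1.5 |
| d | 0.5 | 0.25/0.75/0.25/0.75 (breaks 0.5, 1, 1.5) | 2 | touches at t = 1 and t = 2 |

Presets apply administrative censoring at the horizon. What the generator
emulates is the randomized two-arm design itself — independent arms,
independent censoring, exchangeable subjects; it does not emulate covariate
heterogeneity, informative censoring, delayed entry or competing risks, so
passing tests demonstrate correctness of the estimators under the design
assumptions, not robustness to their violation on real trial data.

`coverage_experiment` simulates many trials from one configuration, builds
each requested CI, and reports empirical coverage of the closed-form truth,
mean width and failure counts. Default study sizes used by the test suite:
binary coverage at n = 500/arm over 2000 trials; survival coverage at
n = 200/arm over 500 trials with 500 perturbation replicates, where Wald
and perturbation CIs for RNT_surv both land within [0.92, 0.98] at nominal
0.95. Consistency checks compare the mean estimate over 30 trials of
n = 100 000/arm against the analytic value (within 1%); the averaging keeps
the Monte Carlo error of the check itself near 0.3%, well inside the
tolerance.

## Numerical and design choices

* Comparisons against reported values round half away from zero at the
  reported precision (clinical reporting convention); internal computation
  is full precision.
* One published trial reports arm sizes and response rates but not counts;
  the built-in fixture uses 26/105 and 28/96, the unique integer counts
  consistent with the reported 24.8% and 29.1%.
* Display precision defaults to 1 decimal for NNT-type and 2 for RNT-type
  measures, overridable (`--precision`, with `-1` for full precision).
  `unit_scale` re-expresses RNT per k responses (0.074 per response ↦ 7.4
  per 100) for the small values that arise when both rates are high.
* τ is in the data's own time units, which are caller-defined and
  unchecked; the CLI documents that `--tau` must match the data.
* Event-indicator dialects 1/0, TRUE/FALSE and event/censored are accepted
  by the reader; any other coding requires an explicit `event_value`.

## Limitations

Continuous endpoints are out of scope, as are covariate adjustment,
individual-level heterogeneity, meta-analytic pooling, competing risks,
left truncation and interval censoring. RNT values computed from different
clinical endpoints are not comparable with each other. The exact-CI
construction and the perturbation weighting scheme are standard choices
made here; other conservative constructions exist and may differ in detail.
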