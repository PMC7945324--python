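# rnt — reduction in number to treat for two-arm trials

Clinicians summarise randomized controlled trials with the number needed to
treat, NNT = 1/(p_E − p_C): the expected number of patients who must receive
the experimental treatment instead of control to gain one extra response.
NNT has two well-known defects. It depends only on the *difference* of the
response rates — trials with rates (0.1, 0.2) and (0.4, 0.5) both report
NNT = 10 although the first treatment doubles the response rate — and when
the rate difference is not significant its confidence interval takes the
irregular two-half-line form `[NNTB b to ∞ to NNTH h]`.

This package implements the **reduction in number to treat**, which reverses
the order of differencing and inverting:

    RNT = 1/p_C − 1/p_E = (p_E − p_C)/(p_E p_C) = RRR/p_E

RNT keeps the baseline (5 vs 0.5 in the example above), is zero exactly when
the arms are equal, lives on the whole real line, and always has an ordinary
interval as its Wald CI. For time-to-event endpoints two analogues are
provided: `RNT_surv(τ) = 1/S_C(τ) − 1/S_E(τ)` from Kaplan–Meier survival
rates, and `RNT_RMST(τ) = τ(1/RMST_C(τ) − 1/RMST_E(τ))` from restricted mean
survival times, together with their NNT counterparts
(`NNT_surv = 1/(S_E − S_C)`, `NNT_RMST = τ/(RMST_E − RMST_C)`).

The library covers:

* binary measures ARR, RR, RRR, NNT, RNT with Wald (delta-method),
  stratified bootstrap percentile, and conservative exact
  (Clopper–Pearson + MOVER) confidence intervals;
* Kaplan–Meier estimation with Greenwood variance, RMST with its
  Greenwood-type variance, delta-method Wald CIs and
  perturbation-resampling CIs for the four survival measures, and
  effect-measure profiles over a follow-up grid;
* a piecewise-exponential two-arm trial simulator with closed-form truths,
  four canonical survival-shape presets (proportional hazards, curves
  meeting at the horizon, interior crossing, double crossing), and a CI
  coverage-experiment driver.

## Worked example

The KCSG-LU05-04 lung-cancer trial randomized 211 patients to
chemoradiotherapy (81 responses) and 209 to chemoradiotherapy plus
consolidation (90 responses):

```console
$ rnt binary --control 211:81 --treatment 209:90
measure  point  ci                            method
ARR      0.05   [-0.05, 0.14]                 wald
RR       1.12                                 wald
RRR      0.12                                 wald
NNT      21.4   [NNTB 7.1 to ∞ to NNTH 21.2]  wald
RNT      0.28   [-0.29, 0.86]                 wald
```

On average 21.4 patients must receive the consolidation regimen per extra
response; because the ARR interval spans zero, the NNT interval is the
irregular benefit/harm form. The RNT of 0.28 (95% CI [−0.29, 0.86]) says the
treatment needs 0.28 fewer patients per response than control — with an
ordinary interval. For a survival endpoint:

```sh
rnt simulate --preset a --n 200 --seed 11 --out trial.csv
rnt survival --data trial.csv --control control --tau 1,2,3 --ci perturbation --seed 1
```

prints a tidy table of `RNT_surv`, `NNT_surv`, `RNT_RMST`, `NNT_RMST` with
percentile CIs at each τ. `rnt check` recomputes every built-in reference
example (two trials, toy cases, and the full RNT/NNT grid over baselines and
differences) and reports 62/62 reproduced.

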