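# disurv

Survival analysis for right-censored clinical data: the classical toolkit
(Kaplan–Meier curves, weighted log-rank tests, kernel-smoothed hazard
rates, Cox proportional-hazards regression with tie handling, contingency
tables) together with a **discrete-time individual survival predictor**
based on a single-hidden-layer neural network.

The package is aimed at clinical researchers and biostatisticians who work
with cohorts of the usual form — one row per subject with a follow-up time,
a censorship indicator (0 = censored, 1 = event) and covariates — and who
want both the standard population-level estimates and a per-patient
predicted survival curve from a model that is free of the proportionality
and linearity assumptions of the Cox model.

## Methods at a glance

**Kaplan–Meier.** With distinct event times `t_i`, `m_i` events and `n_i`
subjects at risk just before `t_i`, the product-limit estimate is
`S(t) = prod_{t_i <= t} (1 - m_i/n_i)`, with a 95% Greenwood band on the
log scale, the median survival time, the median follow-up time by reverse
Kaplan–Meier, and the number-at-risk table.

**Curve comparison.** Log-rank, Peto–Peto and Tarone–Ware tests accumulate
weighted observed-minus-expected events `w_i (m_Xi - e_Xi)` over the
pooled event times, with `e_Xi = n_Xi m_i / n_i` and the hypergeometric
variance; the statistic is χ² with k − 1 degrees of freedom, and for two
groups an odds ratio `(O_X/e_X)/(O_Y/e_Y)` is reported.

**Hazard rate.** A fixed-bandwidth kernel smoother
`h(t) = (1/b) Σ K((t - t_i)/b) ΔH(t_i)` convolves the Nelson–Aalen
increments `ΔH(t_i) = m_i/n_i` with the Epanechnikov kernel
`K(x) = (3/4)(1 - x²)`, switching to Gasser–Müller boundary kernels within
one bandwidth of 0 and of the largest observed time.

**Cox regression.** `h(t, X) = h0(t) exp(Σ β_i X_i)` fitted by
Newton–Raphson on the partial likelihood with Breslow, Efron or exact
(discrete) tie handling, Wald tests and confidence intervals per
coefficient, a likelihood-ratio goodness-of-fit test, AIC-guided stepwise
selection (backward/forward/both), stratified baselines, and the
Grambsch–Therneau proportional-hazards assumption test.

**Discrete-time network model.** The follow-up axis is cut into G
intervals holding equal numbers of events; each subject is encoded as a
length-G hazard-target vector (zeros while alive, then 1 for a death or
the cohort hazards `m_t/n_t` for a censoring); a logistic single-hidden-
layer network maps covariates to per-interval hazards, with the hidden
size selected by a 10-fold cross-validation (per iteration: one test fold,
one validation fold, eight training folds) under the interval-distance
accuracy `ACC = Σ (G - |T - T'|) / (G·N)`. Predicted hazards become an
individual survival curve through `S(t) = prod_{i<t} (1 - h_i)`.

## Worked example

Simulate a two-arm cohort from a known discrete hazard (baseline 0.12 per
interval, treatment log-odds effect 0.8, light censoring), then estimate
and compare the survival curves:

```sh
$ disurv simulate --n 300 --intervals 10 --baseline-hazard 0.12 \
    --effect 0.8 --censor-prob 0.03 --seed 7 --out cohort.csv
wrote 300 subjects (22.3% censored) to cohort.csv

$ disurv km --input cohort.csv --time-col time --status-col status \
    --group x --out-dir km_out
$ cat km_out/km_summary.json
{
  "0.0": { "n": 160, "events": 112, "median_survival": 5.0 },
  "1.0": { "n": 140, "events": 121, "median_survival": 3.0 },
  "median_followup": 10.0
}

$ disurv compare --input cohort.csv --time-col time --status-col status \
    --group x --test logrank --out-dir cmp_out
log-rank chi-square = 27.7342 on 1 df, p = 1.392e-07
odds ratio = 0.5417
```

The untreated arm (`x = 0`) reaches half survival at interval 5, the
treated arm at interval 3; the log-rank test rejects curve equality
decisively, and the odds ratio says the `x = 0` arm experiences roughly
half the relative death rate of the `x = 1` arm — consistent with the
positive log-hazard effect the cohort was generated with.

The other subcommands follow the same pattern: `hazard` (smoothed hazard
curves at a chosen `--bandwidth`), `cox` (coefficient table, LRT and
proportional-hazards diagnostics), `crosstab` (contingency table with
χ²/Fisher/McNemar), and `ann-train` / `ann-predict` for the discrete-time
network model. Every command accepts `--config key=value` files, writes
tidy CSV/JSON into `--out-dir`, and can export step plots as PNG, PDF or
EPS (`--plot-format`, `--bw-graphics`).

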