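# Methods

This note records the statistical conventions, numerical choices and known
limitations of the package, in the order of the analysis pipeline.

## Data model

A cohort is a table with one row per subject: a non-negative follow-up
time, a censorship status (0 = censored, 1 = event; other codings are
remapped at load time via `event_code`/`censor_code`), and arbitrary
numeric or categorical covariates. Rows whose time or status cannot be
parsed are dropped with their indices logged; a negative time or an
unrecognised status code is an error naming the row. Rows with missing
covariate values are dropped with a logged count — imputation is out of
scope and silently guessing a value would be worse than losing the row.
Zero follow-up times are legal: such a subject enters no risk set beyond
time 0 and, if censored at 0, influences nothing.

`stratify` turns a numeric column into ordered categories. The first
interval is closed at both ends and the remaining intervals are left-open
right-closed, so printed range lists such as "39 to 45, 45 to 55" resolve
a shared endpoint into the earlier stratum; a `closed="left"` switch flips
the convention.

## Synthetic cohorts

The generator draws subjects by a discrete-time geometric walk over
intervals 1..G: in each interval a subject at risk dies with its pattern
hazard, else is censored with a per-interval probability, else advances;
survivors past G are administratively censored at G. Hazards follow a
logistic model, `h = expit(logit(baseline_t) + Σ β_j x_j)`, so covariates
act on the log-odds of the per-interval event probability; for the small
hazards used in the regression studies this is numerically
indistinguishable from a log-hazard effect. The generator returns the true
per-pattern hazards and survival curves, which is what makes
parameter-recovery testing possible.

What the generator emulates: right censoring independent of the event
process, proportional (logistic-scale) covariate effects constant over
time, and event times on an interval grid — exactly the structure the
discrete-time encoding assumes. What it does not emulate: continuous
event-time dynamics within intervals (a `jitter_event_times` helper
spreads events uniformly over their interval when a continuous-time view
is needed, e.g. for the kernel smoother), informative censoring,
time-varying effects (built by hand where a test needs them) and covariate
measurement error. Passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not robustness
to violations of those assumptions.

## Kaplan–Meier

Risk sets count every subject with observed time ≥ t_i, so censorings tied
with an event time are still at risk at that time (events precede
censorings). The variance is Greenwood's sum; the default 95% band is
computed on the log-survival scale, `S · exp(±z · se(log S))`, matching
the default of the R `survival` package, with a plain
`S ± z·se` alternative. Once the curve hits 0 its variance is undefined
and the band is reported as NaN. The median is the smallest event time
with `S ≤ 0.5` — the left endpoint on an exact-0.5 plateau, chosen because
it is deterministic and respects step-function semantics. Median follow-up
is the median of the reverse Kaplan–Meier (status flipped), the standard
clinical convention for "how long were patients followed".

## Weighted curve comparison

At each pooled event time the per-group observed minus expected events and
the hypergeometric (co)variance of the 2×k table are accumulated with
scheme weights: 1 (log-rank), √n_i (Tarone–Ware), or the pooled
left-continuous Kaplan–Meier estimate S(t−) (Peto–Peto). The statistic is
the quadratic form of the first k−1 weighted sums against the summed
covariance `Σ w_i² V_i`; the weight enters the variance squared, the only
dimensionally coherent reading, and the k = 2 case then reduces exactly to
the familiar scalar formula. No continuity correction is applied. The
two-group odds ratio is the ratio of relative death rates
`(O_X/e_X)/(O_Y/e_Y)`, the quantity printed by R's `survdiff`; it is
reported as undefined when a group has zero expected events.

## Kernel-smoothed hazard

The estimator convolves Nelson–Aalen increments with an Epanechnikov
kernel at a fixed, user-chosen bandwidth (no automatic selection). Within
one bandwidth of 0 or of the largest observed time t_D, the symmetric
kernel is replaced by the second-order boundary kernel of the
linear-times-Epanechnikov family, `(a + bx)·(3/4)(1 − x²)` on `[−1, q]`,
with `a, b` solved from the moment conditions `∫K = 1`, `∫xK = 0`; at
`q = 1` it reduces to the interior kernel, and the right edge is handled
by reflection. When the bandwidth exceeds half the range, the closer edge
wins. The linear factor can dip negative, so the estimate is clipped at 0.
Default grid: 101 equally spaced points on [0, t_D]. The optional 95% band
uses the asymptotic variance `(1/b²) Σ K² m_i/(n_i(n_i − m_i))` with
normal quantiles; a time at which the risk set is exhausted (n_i = m_i)
contributes no variance. The curve maximum and its location are annotated
on every curve.

A caveat worth stating precisely: boundary kernels restore the moment
conditions at each *evaluation point*, not per *event*, so the integral of
the curve equals the total Nelson–Aalen mass only approximately when
events sit within a bandwidth of the support edges — and an event atom
exactly at t_D can be over-weighted by up to 50%. In the mass-conservation
study we therefore use the continuous-time cohort view (jittered event
times, declining hazard, follow-up extending past the bulk of events),
where the integral agrees with the Nelson–Aalen mass to well within 2%
(worst case ≈ 1.5% over 20 seeds at n = 1000, b = 1).

## Cox regression

The partial likelihood is maximised by Newton–Raphson from β = 0 with step
halving, convergence at relative log-likelihood change < 1e−9 and at most
25 iterations; non-convergence raises an error carrying the log-likelihood
trace. A coefficient walking beyond ±20 is treated as monotone likelihood:
the estimate is capped there with a warning (the likelihood is flat to
machine precision far earlier). Categorical covariates are reference-coded
against their first level in sorted order; a constant column is rejected
by name. Strata fit separate baseline hazards by partitioning the risk
sets; the coefficient vector is shared.

Tie handling: Breslow and Efron use the standard approximate likelihoods
with all risk-set sums computed from suffix cumulative sums. The exact
method uses the discrete (conditional-logistic) likelihood; its
denominator, the elementary symmetric function of the risk weights, and
the first two derivatives are computed by a knapsack-style dynamic
programme in O(|risk set| · d) per tied time, which is exact but best kept
to data sets where d is modest.

Inference: per-coefficient Wald tests and 95% normal-quantile intervals;
the headline goodness-of-fit statistic is the likelihood-ratio test
against the null model (the phrase "chi-square goodness of fit" is
ambiguous between LRT, Wald and score; the LRT is what the R survival
summary leads with). Stepwise search is guided by AIC — add/drop whole
covariates, stop when no single move lowers AIC — since a P-value-in /
P-value-out rule needs two extra thresholds nobody states.

The proportional-hazards diagnostic is the Grambsch–Therneau score test:
Schoenfeld residuals at each death are correlated with the centred
Kaplan–Meier transform of time, `g(t) = 1 − S_KM(t−)`; with total
information I, d deaths and U = Σ g_c r, the global statistic is
`(d/Σg_c²)·UᵀI⁻¹U` on p df and the per-variable statistic
`d·[I⁻¹U]_j²/([I⁻¹]_jj·Σg_c²)` on 1 df, which coincide for a single
covariate. Risk-set means use Breslow weighting regardless of the tie
method used in the fit — a conventional simplification. Calibration was
checked by simulation: under proportional hazards the global test rejects
at 4–6% nominal 5% (500 replicates of n = 1000), and a mid-study sign
reversal of the effect is detected with p < 0.01.

## Contingency analysis

Cross-tabulation and marginals are computed directly; proportions are
displayed as percentages ("percent" style) or on the unit scale ("unit"
style) — the style never affects counts or tests. Pearson's χ² (no Yates
correction by default, flag available), Fisher's exact test (two-sided by
probability ordering, the R convention) and McNemar's test
((b−c)²/(b+c) on the discordant cells, no continuity correction by
default, identical row/column labels enforced) are delegated to
scipy/statsmodels; the Fisher implementation is verified exhaustively
against hypergeometric enumeration for all 2×2 tables with total ≤ 30.

## Discrete-time network model

**Discretization.** Boundaries are placed at event-time quantiles so each
of the G intervals holds the same number of events (±1, remainder to the
earliest intervals); tied event times are never split, and when ties make
equal counts impossible the nearest achievable cuts are used with a
warning. Intervals are right-closed, with time 0 in the first; the last
boundary is the maximum follow-up time.

**Hazard-target encoding.** The default encoding is literal: entries are 0
through the subject's interval, then 1 for a death and the cohort hazards
m_t/n_t for a censoring. Note what squared-error training then estimates:
the conditional mean of the post-event 1s is the *cumulative* death
probability, not the per-interval hazard, so survival curves reconstructed
from a network trained on the literal targets are systematically too
steep. The `hazard_at_event=True` variant fixes both this and the
last-interval ambiguity (a death in interval G is otherwise encoded
identically to a survivor): a death contributes 1 *at* its interval and
the cohort hazard after it, making the target's conditional mean exactly
the discrete hazard (verified as an algebraic identity in the tests). The
recovery studies use this consistent variant; the literal encoding remains
the default for fidelity to the method as published.

**Cross-validation.** Subjects are shuffled once under the run seed into
10 folds of equal size (±1), without stratification by event status. In
iteration i, fold i is the test set, fold i+1 (mod 10) the validation set,
and the remaining eight folds train the network; cohort hazards for the
encoding are recomputed on the training folds only, as are the
standardisation constants (zero mean, unit spread) applied to the
covariates. The hidden size is chosen by mean validation-fold interval
accuracy; the reported `cv_accuracy` is the mean test-fold accuracy of the
winner, keeping selection and reporting on disjoint folds; the delivered
network is retrained on the full cohort at the selected size.

**Training.** Single hidden layer, logistic activations at both layers,
mean sum-of-squares loss, full-batch Adam (learning rate 0.05), at most
500 epochs, early stopping on validation loss with patience 20. The L2
weight penalty defaults to 1e−4: with the loss on the per-subject mean
scale, a penalty of 1e−3 measurably shrinks the predicted hazards toward
the pooled cohort hazard (roughly doubling the survival-curve error on
the recovery study) without any stability benefit at these network sizes.
The default hidden-size grid is {2, 4, 8, 12, 16, 20, 24, 32}.

**Prediction.** The forward pass yields per-interval hazards; survival at
the start of interval t is `prod_{i<t}(1 − h_i)`. The estimated survival
interval — needed by the accuracy score but not otherwise defined — is the
first interval whose end-of-interval survival drops below 0.5, or G if the
curve never does: the median-predicted-survival reading, which is
deterministic and agrees with the obvious answer on degenerate hazards.

## Problem sizes used in the test and acceptance runs

Exhaustive oracles: all censoring patterns of ≤ 8 subjects (Kaplan–Meier),
all 2×2 tables with total ≤ 30 (Fisher), 6-subject tied datasets × 4
coefficients × 3 tie methods (Cox). Calibration: 1000 null replicates of
two 200-subject arms (weighted tests); 500 replicates of n = 1000
(proportional-hazards test). Recovery: 200 cohorts of n = 2000 with a 0.7
log-hazard effect (Cox); one n = 2000, G = 8 cohort for the network
survival-curve error plus 20 seeds for risk ordering, with reduced hidden
grids ({2,4,8,16} and {4,8}) — the selection landscape is flat across
neighbouring sizes, so the reduced grids change nothing but the run time.

## Known limitations

- Time-dependent covariates and time-varying coefficients are not
  supported anywhere in the package.
- The exact tie method is exponential-free but still O(|risk set|·d) per
  tied time; for heavily tied large cohorts use Efron.
- The hazard smoother offers no automatic bandwidth selection, and its
  band is pointwise asymptotic, not simultaneous.
- The network model's literal target encoding is biased as a survival
  estimator by construction (see above); consistency requires the
  `hazard_at_event` variant.
- The Peto–Peto weight follows the pooled left-continuous Kaplan–Meier
  convention; other software uses slightly different modified estimators,
  so third-party Peto statistics may differ in the last decimal places.
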