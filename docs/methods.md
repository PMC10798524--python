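# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `riskcontext`.

## Task model

A choice set is a sequence of `n_trials` (default 240; a 171-trial
variant is supported) gain-only decisions between a safe amount paid with
certainty and a gamble paying either $0 or a risky gain, each with
probability 0.5. Trials are partitioned into 9–10 runs of 9–36 trials.
Run lengths are drawn uniformly from the bounded integer compositions of
`n_trials` (i.i.d. uniform lengths accepted when they sum correctly; the
run count is drawn uniformly among feasible counts). Each run has an EV
level on a quarter-dollar grid in [$2.25, $33]; consecutive levels differ
by a signed shift drawn uniformly from the admissible elements of
±{$5.00, $6.25, …, $15.00}. Within a run, `safe = round(L + u1, 2)` and
`risky_gain = round(2(L + u2), 2)` with u1, u2 independent uniform on
±$2, redrawn on the rare bound violation; realized amounts therefore lie
in [$0.25, $35] and [$0.50, $70]. The EV-level trajectory is constrained
only locally (no global balancing of shift signs or level coverage);
empirically positive and negative shifts occur near 50/50 except at the
level bounds.

Trial timing for SCR synthesis: 2 s forced viewing, ≤ 2 s response
window, 0.5 s inter-stimulus interval, 1 s outcome display, then a
uniform 1.5–4.5 s inter-trial interval to which the unused response
window is added. Reaction times are drawn uniform on [0.3 s, 2 s]; the
behavioral models never use them.

## Generative choice model

Each subject chooses by a logistic rule over normalized regressors:

```
η_t = (β_rg + d_rg) riskygain_t + (β_safe + d_safe) safe_t + β_mag magnitude_t
      + d_0 + β_prev outcome_{t−1} + β_pos posshift_t + β_neg negshift_t
      + β_earn earnings_t + β_exp expectation_t + β_int earnings_t·outcome_{t−1}
```

with P(gamble) = logistic(η_t), outcomes drawn fairly, and earnings
accumulating forward. Default fixed effects are the published estimates:
β_rg = 30.88, β_safe = −13.18, β_mag = −49.51, β_prev = −0.7,
β_pos = 5.3, β_neg = 0 (the published negative-shift effect is null),
β_earn = 0.37, β_exp = −0.26, β_int = 1.3. Between-subject variation
enters through correlated slope deviations (d_rg, d_safe), SD 2.5 each
with correlation −0.3, and an intercept d_0 with SD 0.3 — values chosen
to spread per-subject gamble rates over roughly 0.2–0.8, a typical range
for this task class. Context-coefficient SDs default to 0 so that the
cohort is drawn from exactly the hierarchical structure the two-step
models represent (random slopes on the current-trial amounts, a random
intercept, homogeneous context effects); per-coefficient SDs are
config-exposed for sensitivity analyses. Missed trials are injected
uniformly at random (default 0.5%, echoing the observed rate) and carry
no choice or outcome.

### Normalization

`money_scale` divides every dollar-valued regressor and defaults to the
dataset's maximum possible outcome (≈ $68–70 for the standard design);
`earnings_scale` divides cumulative earnings and the linear expectation
and defaults to expected total earnings (sum of per-trial EV levels), so
both global regressors run from 0 to ≈ 1 over the task. The money scale
is a reconstruction: a single dollar divisor equal to the maximum outcome
makes the published coefficients reproduce the printed probability
translations (logistic(−0.15·68/68) − 0.5 → −3.7 points;
logistic(4.8·15/68) − 0.5 → +24.2 points). Both scales are explicit
inputs, never re-derived after data are seen. Cumulative earnings at
trial t sum outcomes of trials 1..t−1 — the pre-decision information
set; the linear expectation at trial t is t times the task-mean EV level.
Trial 1, missed trials, and trials following a missed trial are excluded
(the previous outcome is undefined there).

## SCR synthesis and scoring

Traces are built at 200 samples/s as baseline (2 µS) + a slow sinusoidal
drift + white noise + superposed event responses. The canonical response
kernel is a difference of exponentials, rise 0.75 s, decay 2.0 s, onset
latency 1.0 s, scaled to unit peak (peak ≈ 2.2 s after event onset, well
inside the scoring window); any kernel peaking inside the window would
serve, and the constants are config-exposed. Outcome-locked amplitudes
follow `level + 0.12 · earnings_n` and decision-locked amplitudes
`level + 0.41 · posshift_n`, both on the sqrt/max-normalized scale, with
Gaussian amplitude noise and an independent per-event non-response
probability (defaults 0.45 outcome / 0.50 decision, giving the observed
"roughly half of trials respond" profile). Normalized amplitudes convert
to µS as a = n²·a_max with a subject maximum a_max = 0.4 µS, inside the
printed range of per-subject means.

Scoring: 16-tap windowed-sinc FIR low-pass at 25 Hz (unit DC gain; the
7.5-sample group delay is compensated by an integer 8-sample shift, a
2.5 ms residual that is negligible against the 4 s window), then
mean-value smoothing with a 3-sample Blackman window. The literal
3-point Blackman taper is [0, 1, 0] — an identity smoother — so the
weights used are the interior three points of a 5-point window,
[0.34, 1.0, 0.34], normalized to unit sum; edges renormalize over the
partial window. Trough-to-peak amplitude is the maximum rise above the
running minimum within the window (not max − min, so a decline after an
early peak cannot inflate the score); the outcome window is 0.5–4.5 s
post onset, the decision window runs from onset + 0.5 s to response +
0.5 s, mirroring the outcome window's response latency (the exact end
bound is config-exposed as the original choice is not recoverable).
Amplitudes below 0.02 µS score 0. Per subject, amplitudes are
square-rooted and divided by the maximum square-rooted amplitude, and a
subject is a responder iff strictly more than 25% of events score above
zero. In a realistic schedule the scoring window of one outcome can catch
the rising edge of the next trial's decision response; this superposition
is deliberate (it is a property of the task's timing), and the scoring
oracle tests therefore use widely spaced events.

## Estimation

**Binomial GLMM (`fit_binomial_glmm`).** Marginal likelihood by the
Laplace approximation: per-subject random-effect modes from a damped,
vectorized Newton solve (closed-form 1×1/2×2 inner systems), outer
L-BFGS-B over fixed effects and covariance parameters (log-SDs and an
atanh correlation keep the covariance positive definite; log-SDs bounded
in [−10, 4], so a variance collapsing to the boundary is flagged rather
than fatal). Convergence: relative objective change below 1e-12, up to
500 outer iterations; the reported gradient norm should be ≲ 1e-3 on the
objective scale. Standard errors come from the observed information in
the fixed effects at the optimum with covariance parameters held fixed —
the convention matching printed β/SE/p triplets — and p-values are
two-sided Wald. `aic = −2ℓ + 2k` counts fixed effects plus free
covariance parameters. With `random=None` the fit reduces exactly to
pooled logistic ML. Supported random structures are an intercept or two
correlated slopes, which covers every model in the suite.

The Laplace error of the marginal log-likelihood grows steeply with the
random-effect scale (empirically ≈ SD⁴ on small binary panels: ~7e-3 at
SD 0.5, ~6e-4 at SD 0.2 for 3 subjects × 20 trials), which the test
suite pins both ways: agreement with a 201-point adaptive Gauss–Hermite
oracle to 1e-3 at modest SD, and monotone error decay in SD.

**Gaussian LMM (`fit_linear_mixed`).** Subject random intercept by REML
through statsmodels MixedLM. A Gaussian offset is applied exactly by
subtracting it from the response. When the intercept variance collapses,
the mixed model *is* ordinary least squares and the exact OLS solution is
reported (the generic optimizer is numerically unreliable on that
boundary).

**Two-step offsets.** Stage-one predictions are computed prior to the
link function and enter stage two through the offset (coefficient fixed
at 1). By default the offset includes the subject-specific conditional
modes, matching the default prediction behavior of the reference
mixed-model ecosystem and hence the most plausible original procedure.
This choice has a measurable cost: the shrunken modes absorb
subject-level variation that overlaps the slowly varying global
regressors, so under a null with no context effects the Wald tests for
cumulative earnings and expectation reject at ≈ 1% instead of 5%
(previous outcome, positive shift, and the interaction stay near
nominal). Passing `include_random=False` uses fixed-effects-only offsets,
which restores ≈ 5% calibration for all five terms at the price of
noisier (honestly calibrated) estimates of the two weak global effects.
Both paths are tested; the default favors fidelity to the original
procedure, whose conservatism is documented rather than patched. Model
3c's offset comes from model 1 like every other context model; a config
switch substitutes model 3a's predictions, since the original description
is ambiguous on this point.

## Power

Two power questions are supported, and they differ sharply.
`simulate_power` re-simulates the full pipeline per replicate (cohort,
choices, stage-one fit, context fit) and counts Wald rejections at α,
reporting an exact Clopper–Pearson interval; 100 simulations is the
default because 88 rejections out of 100 reproduces the printed interval
[79.98%, 93.64%] exactly. Replicate fit failures are excluded and
counted; more than 10% aborts. Because stage one is re-estimated each
replicate, a small generative context effect is largely re-absorbed
before stage two sees it: at 62 subjects a generative previous-outcome
coefficient of −0.15 yields a mean stage-two estimate of only ≈ −0.05
and ≈ 4% power. `power_from_fit` instead answers the a-posteriori
question as originally posed — parametric bootstrap from the *fitted*
context model with the stage-one offset frozen as data, new random
effects drawn from the fitted covariance — which is far more optimistic
because no re-absorption occurs. An 88%-style figure is a frozen-offset
quantity; the full-pipeline figure is the honest design power for a
generative effect of that size under this conservative estimator.

## Problem sizes used by the test suite

Parameter recovery runs 20 replicates of 60 subjects × 240 trials; null
calibration runs 400 replicates at 20 subjects × 240 trials; the SCR
suite tests use 16–20 synthesized subjects; power demonstrations use
10–12 subjects and 20–25 simulations. These sizes were chosen so the
whole suite completes in minutes while keeping every check's Monte-Carlo
error well inside its assertion margins.

## What the generator does and does not emulate

It emulates the task's run/shift structure and dollar ranges, choice
behavior under the published coefficient pattern with subject
heterogeneity in current-trial sensitivities, realistic missingness,
event timing, and SCR amplitudes tied to earnings (outcome phase) and
positive shifts (decision phase) with non-response and measurement noise.
It does not emulate: SCR habituation or tonic drifts tied to arousal
state, heterogeneity of context effects across subjects (off by
default), reaction-time structure, position effects, or any dependence of
missingness on task state. Passing tests therefore certify the pipeline's
statistical machinery under the stated generative conditions, not the
full richness of real electrodermal or behavioral data.

## Known limitations

* Random structures beyond two correlated slopes are not implemented
  (none are needed for this suite).
* The Laplace likelihood is biased for large random-effect variances on
  short binary panels; an adaptive-quadrature path exists only as a test
  oracle, mirroring common practice.
* The two-step procedure is conservative by construction; its global-term
  tests under-reject with mode-inclusive offsets (see above), and its
  context estimates are lower bounds whenever context and current-trial
  regressors share variance.
* Money rounding is to whole cents; amounts are exact to two decimals but
  float-represented.
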