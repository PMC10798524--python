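# riskcontext

Tools for studying **temporal-context effects in risky monetary choice**,
with a matched skin-conductance (electrodermal) analysis. The package is
aimed at decision-science and psychophysiology researchers who want a
tested, fully synthetic-data-capable re-implementation of this analysis
style: structured task generation, hierarchical choice modeling with a
conservative two-step offset procedure, trough-to-peak SCR scoring, and
simulation-based power.

## The problem

In a gain-only gambling task (a guaranteed amount vs. a 50/50 gamble for
roughly double), choices are not static: they depend on context at three
timescales —

* **immediate**: the outcome of the previous trial (large outcomes reduce
  subsequent risk-taking),
* **neighborhood**: runs of trials share an expected-value (EV) level and
  are separated by signed EV shifts of $5–$15; risk-taking spikes on the
  trial right after a positive shift,
* **global**: cumulative earnings relative to a linear expectation
  (doing better than expected increases risk-taking, and interacts with
  the previous outcome).

Because option values are correlated across trials by design, trial-level
and history regressors cannot be estimated jointly. The analysis is a
**two-step offset procedure**: first fit the current-trial model

```
model 1:  choice_t ~ 0 + riskygain_t + safe_t + magnitude_t
                     + (0 + riskygain_t + safe_t | subject),  binomial
```

then freeze its linear predictions η̂ (computed before the link function)
as a per-observation *offset* — a linear-predictor term with coefficient
fixed at 1 — in every context model, e.g.

```
model 4b: choice_t ~ 0 + outcome_{t-1} + posshift_t + earnings_t
                     + earnings_t:outcome_{t-1} + expectation_t
                     + (1 | subject),  binomial, offset = η̂
```

All shared variance goes to the current-trial terms, so context estimates
are lower bounds. The binomial mixed models are estimated here by a
Laplace-approximated marginal likelihood (implemented in
`riskcontext.glmm`); Gaussian SCR models use REML.

Skin-conductance responses are scored as the trough-to-peak rise in a
0.5–4.5 s post-event window after 25 Hz FIR filtering and 3-sample
Blackman smoothing, floored at 0.02 µS, square-rooted and normalized by
each subject's maximum; subjects responding on ≤ 25% of events are
excluded as non-responders.

## Worked example

```python
import riskcontext as rc

sets, recs, params, norm = rc.simulate_cohort(n_subjects=20, seed=11)
feats = rc.build_cohort_features(sets, recs, norm)
report = rc.run_behavior_suite(feats)
print(report.fits["4b"].summary_frame().round(3))
```

prints (seed 11):

```
                       estimate     se      z      p
prev_outcome             -0.508  0.218 -2.332  0.020
pos_shift                 7.164  1.956  3.662  0.000
earnings                  0.054  0.486  0.111  0.912
earnings:prev_outcome     1.532  0.409  3.749  0.000
expectation              -0.307  0.496 -0.620  0.535
```

The cohort was generated with context coefficients (−0.7, 5.3, 0.37, 1.3,
−0.26): the fitted signs and magnitudes recover the generative pattern —
less risk-taking after large outcomes, more right after a positive EV
shift, and a positive earnings-by-previous-outcome interaction — with the
two weak global terms estimated noisily, as their small effect sizes
dictate. Translating fitted logit effects into probability changes at
indifference:

```python
rc.effect_to_probability(-0.15, 68/68)   # -> -3.74 percentage points
rc.effect_to_probability(4.8, 15/68)     # -> +24.25 percentage points
```

The `examples/` directory has one short narrative script per capability
(task design, synthetic cohorts, SCR scoring, the model suite, power).
A staged pipeline is also available from the shell:

```bash
riskcontext run --config examples/pipeline.yaml --out out/
```

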