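"""Synthesize an event-locked skin-conductance trace and score it.

Scoring follows the standard electrodermal recipe: a 16-tap FIR low-pass
at 25 Hz, 3-sample Blackman smoothing, trough-to-peak amplitude in a
0.5-4.5 s window after each outcome onset with a 0.02 uS floor, then a
square-root transform normalized by the subject's maximum response.
"""

import numpy as np

import riskcontext as rc

cs = rc.generate_choice_set(seed=3)
norm = rc.NormalizationScheme.from_choice_set(cs)
params = rc.sample_subject_params(seed=4)
rec = rc.simulate_choices(cs, params, norm, seed=5, miss_rate=0.0)
trace = rc.synthesize_scr_trace(rec, cs, params, norm, seed=6)

print(f"trace: {trace.duration / 60:.1f} min at {trace.fs:.0f} samples/s, "
      f"{len(trace.events)} event markers")

scored = rc.score_subject(trace, phase="outcome")
nonzero = scored[scored["raw"] > 0]
print(f"outcome-locked events: {len(scored)}; responses > 0: {len(nonzero)} "
      f"({scored['response_fraction'].iloc[0]:.0%})")
print(f"responder (needs > 25% responses): {bool(scored['responder'].iloc[0])}")
print(f"mean raw amplitude: {nonzero['raw'].mean():.3f} uS; "
      f"largest normalized amplitude: {scored['normalized'].max():.1f}")
print(
    "\nRaw amplitudes are trough-to-peak rises in microsiemens; the "
    "normalized column (sqrt, divided by the subject's maximum) is the "
    "within-subject response strength used by the SCR models."
)
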