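"""Generate one structured choice set and inspect its temporal structure.

The task is a sequence of 240 gain-only choices between a guaranteed
amount and a 50/50 gamble for roughly double. Trials are grouped into
9-10 runs sharing an expected-value (EV) level; runs are separated by
signed EV shifts of $5-$15 in $1.25 steps.
"""

import riskcontext as rc

cs = rc.generate_choice_set(seed=7)

print(f"trials: {len(cs)}, runs: {cs['run_id'].nunique()}")
print("run lengths:", cs.groupby("run_id").size().tolist())
print("EV levels:  ", cs.groupby("run_id")["ev_level"].first().round(2).tolist())
shifts = cs.loc[cs["shift"] != 0, "shift"]
print("shifts:     ", shifts.round(2).tolist())

# option expected values on a single trial
row = cs.iloc[0]
ev_risky, ev_safe = rc.option_evs(row.risky_gain, row.safe)
print(
    f"\ntrial 1: gamble ${row.risky_gain:.2f}/$0 at p=.5 (EV ${ev_risky:.2f}) "
    f"vs safe ${row.safe:.2f} (EV ${ev_safe:.2f})"
)
print(
    "Safe amounts track the run's EV level within $2; risky gains are "
    "double that, so values are strongly correlated within a run and jump "
    "at run boundaries — the structure that creates temporal context."
)
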