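"""Run one adaptive frequency-modulation staircase on a virtual listener.

The listener detects FM depth (log2 Hz) with a logistic psychometric
function; the two-stage 3-down/1-up staircase adapts depth exponentially
from 20 Hz and estimates the ~79%-correct point from the last six reversals.
"""

import numpy as np

from hearsim import (
    PsychometricSpec,
    default_battery,
    psychometric_probability,
    run_transformed_staircase,
    staircase_target_proportion,
)

battery = default_battery()
cfg = battery["FM_DT"].config

# true threshold 3.0 log2 Hz (8 Hz depth), moderate slope, 4I-2AFC guess rate
listener = PsychometricSpec(location=3.0, slope=0.5, guess_rate=0.5, lapse_rate=0.02)

result = run_transformed_staircase(listener, cfg, np.random.default_rng(1))

print(result.to_frame().head(10).to_string(index=False))
print(f"... {result.n_trials} trials, termination: {result.termination}")
print(f"threshold estimate : {result.threshold:.3f} {result.unit}")
print(f"true location      : {listener.location:.3f} log2 Hz")
pc = psychometric_probability(listener, result.threshold)
target = staircase_target_proportion(cfg.n_down, cfg.n_up)
print(f"p(correct) at estimate: {pc:.3f} (rule targets {target:.3f})")
print("The estimate sits near the listener's ~79%-correct point, the")
print("convergence target of a 3-down/1-up transformed staircase.")
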