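# hearsim

Simulation of a remotely administered auditory test battery and its
test-retest reliability analysis.

Remote, self-administered hearing batteries estimate peripheral and central
auditory function with adaptive psychophysical procedures — but how reliable
are those procedures between sessions, and what do their threshold rules
actually measure?  `hearsim` answers such questions in silico.  It is aimed
at auditory and psychometric researchers who want to study the measurement
properties of an adaptive battery (convergence points, estimator bias,
attenuation of test-retest correlation by trial-level noise, sensitivity of
Bland–Altman limits) without collecting human data.

## What it models

**Virtual listeners.** Responses follow a parametric psychometric function

    p(x) = γ + (1 − γ)(1 − λ) F((x − α)/β)

with location α (threshold), slope β, guess rate γ fixed by the response-set
size, lapse rate λ, and logistic F; yes/no detection adds a catch-trial
false-alarm rate.

**Adaptive procedures.** Each of the battery's tasks is implemented as a
deterministic engine over a listener's stochastic responses:

| task | procedure | threshold rule |
|---|---|---|
| pure-tone detection | modified Hughson–Westlake (start 50 dB SPL, +20 after a first miss, ±10 to 30 dB then ±5, catch trials every 5 then 3, abort after >3 false alarms) | last correctly detected level |
| frequency modulation | two-stage 3-down/1-up, exponential steps 2^(1/2) then 2^(1/10), start 20 Hz | mean of the 6 stage-2 reversals (log2 Hz) |
| spectrotemporal modulation | same paradigm, additive 2 dB steps, start 10 dB | mean of the last 6 reversals (dB) |
| speech reception threshold | 1-up/1-down, 5 dB steps, 20 trials | mean of reversal levels (dB SPL) |
| spatial release from masking | progressive track, 2 trials at each of 11 TMRs | 11 − number correct (dB TMR) |
| digits in noise | 1-up/1-down, +5/−2 dB, 25 trials, noise 65 dB | mean reversal level − 65 (dB TMR), two runs averaged |
| dichotic sentences | 6 trials + 6 more unless 100% | accuracy (%) |
| listening levels | dial adjustment vs a 55 dB SPL target | settled level (dB SPL) |

A k-down/1-up rule converges to the 2^(−1/k) point of the psychometric
function (≈79.4% for k=3); an unequal-step 1-up/1-down converges where
p·down = (1−p)·up (5/7 ≈ 71.4% for the digits task).
`staircase_target_proportion` returns these analytic targets.

**Synthetic studies.** Per measure, the true parameters at two timepoints
are bivariate Gaussian with means (μ+Δ, μ), SD σ and correlation ρ (Δ is
the session bias / practice effect).  Every virtual participant completes
all 19 battery measures at both timepoints; missingness can be injected
completely at random.

**Reliability analysis.** Per measure: a single-pass 3-SD outlier screen per
timepoint, pairwise-complete pairing, then the paired t-test, Pearson ρ,
and Bland–Altman bias with 95% limits of agreement (bias ± 1.96 SD of the
differences), rendered as a summary table, plus the per-task comfort index
(Yes + 0.5·Maybe over substantive respondents).

## Worked example

```sh
python examples/run_single_track.py
```

prints a trial-by-trial staircase log and ends with

```
... 34 trials, termination: completed
threshold estimate : 2.922 log2 Hz
true location      : 3.000 log2 Hz
p(correct) at estimate: 0.726 (rule targets 0.794)
```

— one FM run on a listener with true threshold 3.0 log2 Hz: the estimate
(2.92 log2 Hz) is a single noisy draw near the 79.4%-correct convergence
point; averaged over many runs the percent-correct at the estimate
approaches the target (see `examples/convergence_check.py`).  The
end-to-end pipeline is shown in `examples/simulate_and_analyze.py`, which
simulates a 30-listener cohort and prints the 19-row reliability report;
`examples/score_questionnaires.py` shows the questionnaire and comfort
scoring (e.g. a tally of 7 Yes / 0 Maybe / 0 No → 100% comfortable).

The same pipeline is scriptable from the shell:

```sh
hearsim simulate --out run1 --seed 1 --n-listeners 60
hearsim analyze  --study run1/study.csv --out run1
hearsim report   --study run1/study.csv --out run1
hearsim convergence-check --out run1 --seed 1
```

## Layout

- `src/hearsim/listener_models.py` — psychometric response models
- `src/hearsim/adaptive_tracks.py` — track engines and threshold estimators
- `src/hearsim/battery_scoring.py` — battery definition, questionnaire,
  comfort and composite scoring
- `src/hearsim/study_simulation.py` — cohort generator and missingness
- `src/hearsim/reliability.py` — outlier screen, t/ρ/Bland–Altman, report
- `src/hearsim/cli_io.py` — CSV/YAML round-trips, manifests, CLI
- `docs/methods.md` — model assumptions, defaults, and design choices
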