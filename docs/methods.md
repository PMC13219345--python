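# Methods

## The response model

Every simulated trial is a Bernoulli draw from a psychometric function
`p(x) = γ + (1 − γ)(1 − λ) F(s(x − α)/β)` with logistic `F`.  The logistic
family was chosen for its closed form and its ubiquity in psychophysical
modelling; the slope β is the scale of the logistic argument (not a
derivative), so `p` rises from γ to the ceiling `1 − λ(1 − γ)` over a few
multiples of β.  The sign `s` encodes whether larger stimulus values make
the trial easier (detection of a level, a modulation depth, a target-to-
masker ratio) or harder; this keeps one response engine for every task.

Guess rates are forced by response-set sizes rather than fitted: 0.5 for
the four-interval two-alternative tasks (the target can only occupy
interval 2 or 3), 1/6 per sentence for the closed set of six dichotic
sentences, 1/32 for a 4×8 colour-by-number speech grid, and 10⁻³ for
exact-order recall of a digit triplet.  The grid dimensions and digit
chance level are conventions of this package (the response screens admit
other readings) and are configurable.  The lapse default is 0.02, a
conventional small value.  Yes/no audiometry carries a separate
false-alarm rate that applies only on silent catch trials; it defaults to
0.01.

## Track engines and their estimators

**Reversal definition.** A reversal occurs when the *intended* direction of
the level change flips; steps clipped at a track bound do not themselves
create reversals, and the reversal value recorded is the level presented on
the trial whose response caused the flip.  The k-down counter resets after
every step and on any break in the streak (the standard transformed up-down
convention).

**Frequency modulation.** Two-stage 3-down/1-up with multiplicative steps
2^(1/2) (3 reversals) then 2^(1/10) (6 reversals), start 20 Hz, bounds
(0.001, 10⁴] Hz.  The listener is parameterised in log2 Hz and the engine
evaluates the psychometric function at log2 of the presented depth; the
threshold is the mean of the six stage-2 reversal values in log2 Hz,
mirroring the last-six-reversals rule used for spectrotemporal modulation
and matching the log2 Hz reporting scale.  The analytic convergence point
of the rule is the 2^(−1/3) ≈ 79.4% point; simulation shows the mean
percent-correct at returned thresholds sits 1–2 points below it because
threshold estimates scatter around the target and the psychometric function
is concave there — an estimator property, not a bug.

**Spectrotemporal modulation.** Same paradigm with additive 2 dB steps in
both stages (the single printed step size is taken literally; a
two-magnitude stage-1 can be configured), start 10 dB, floor 0 dB.

**Simple staircases.** 1-up/1-down for exactly n trials (20 for the speech
reception threshold with 5/5 dB steps; 25 for digits-in-noise with +5/−2 dB
around a fixed 65 dB noise).  The threshold is the mean of reversal levels
(minus the 65 dB reference for the digits task).  With zero reversals
(e.g. a run that only descends) the documented fallback is the final
presented level, flagged `no_reversals`.  Note the reversal-level mean of
an unequal-step staircase is intrinsically biased ~1.5–2 dB above the 5/7
drift-balance point, because up-excursions overshoot by the larger step;
the analytic 5/7 target describes the asymptotic proportion correct, not
the estimator's expectation.

**Hughson–Westlake audiometry.** Start 50 dB SPL; a first-trial miss jumps
+20 dB; ±10 dB steps until the level reaches 30 dB SPL, ±5 dB thereafter
(down on "yes", up on "no").  Catch trials are interleaved after every 5th
stimulus trial for the first 15 stimulus trials and after every 3rd
thereafter — the switch point is not specified by the procedure's source
and is configurable.  The run ends on a "yes" at the 0 dB floor, on three
consecutive "no" responses (applied globally, also configurable), on a
fourth catch false alarm (aborting without a threshold), or at a safety cap.
The threshold is the last correctly detected level; a run with no correct
response returns a not-measurable sentinel rather than a number, since
"last correct level" is undefined.  Safety caps (60 trials here, 100 for
staircases) exist because deterministic listeners would otherwise loop
forever; completed runs never hit them.

**Progressive track.** Two trials at each of 11 TMRs (+10 to −10 dB in 2 dB
steps, presented easy→hard); threshold = 11 − total correct, in dB TMR.
The constant 11 is treated as a dB value on the TMR scale.  For a listener
whose symmetric psychometric function is centred on the grid the estimator
is exactly unbiased for the 50% point, since expected correct counts above
and below centre cancel.

**Adjustment task.** The settled noise level is the listener's criterion
plus Gaussian jitter (default SD 5 dB), rounded to the 1 dB dial step and
clipped to the 0–85 dB dial; TMR = level − 55 dB (the fixed sentence
level).

**Dichotic sentences.** Six trials of two simultaneous sentences at 70 dB;
six more unless all twelve sentences were correct.  Scoring is
per-sentence (two opportunities per trial); per-trial scoring is available.

## Questionnaire and comfort scoring

The 10-item handicap questionnaire scores yes=4 / sometimes=2 / no=0; the
0–40 range and the even category boundaries (≤8 none, 10–24
mild-to-moderate, ≥26 severe) force this item scoring, and odd totals are
impossible by construction.  The comfort index is Yes + 0.5·Maybe; its
percentage excludes non-respondents from the denominator — the only reading
consistent with a task rated 100% tolerable by just seven respondents.

## The synthetic cohort

Latent truth: per measure, `(θ_T1, θ_T2)` is bivariate Gaussian with means
`(μ+Δ, μ)`, common SD σ and correlation ρ, on the measure's reporting
scale.  The session bias Δ enters the latent mean — practice changes true
performance, not response noise.  Default moments are the first-timepoint
column of the emulated study's summary table (e.g. handicap 12.4 ± 8.1 with
ρ 0.90, digits-in-noise −19.0 ± 3.1 dB TMR with ρ 0.57); they are realism
defaults, never treated as ground truth to be reproduced.  The latent θ
maps to the listener's ψ-function location α = θ (criterion level for the
adjustment task, per-sentence probability θ/100 for dichotic sentences,
item-endorsement probability θ/40 for the questionnaire, where each item
scores 2·Binomial(2, θ/40) so the expected total equals θ).

Measured values therefore carry task-specific offsets (a 3-down/1-up track
sits at the 79% point, ≈ α + 0.4β, not at α) and trial-level noise.  Both
are faithful to real adaptive testing: offsets cancel in every test-retest
statistic, while noise attenuates the observed Pearson ρ below the
generative value — by design, and verifiably (a property test shows
observed ρ is non-increasing in slope).

Missingness is completely at random: a comfort-skip rate (default 0.2,
matching 10–15 non-responses per task in a cohort of 60) and a technical
loss rate (default 0.005, under 1% of values).  Informative missingness and
enrolment attrition are not modelled.

Randomness: one top-level seed feeds named substreams per (listener,
measure, timepoint) — enlarging the cohort never perturbs existing
listeners' data, and identical seeds give byte-identical output tables.

**What the generator does not emulate:** audio rendering and calibration,
room acoustics, attention drift within a run, reaction times, ear-specific
asymmetries beyond separate left/right thresholds, informative dropout, or
demographic covariates.  Passing tests therefore establish the measurement
properties of the procedures and statistics under the stated response
model, not the behaviour of human listeners.

## Reliability analysis

Outlier removal keeps `|v − mean| ≤ 3·SD`, single pass, per measure, per
timepoint, before pairing; a zero-SD vector keeps everything, and fewer
than three values skip removal with a logged warning.  Listeners are then
restricted per measure to pairwise-complete pairs (consistent with a
summary table whose n varies by row).  Statistics: paired t
(`t = mean(d)·√n / SD(d)`, df n−1), Pearson ρ with the t-transform p-value,
Bland–Altman bias = mean(d) and limits of agreement bias ± 1.96·SD(d)
(1.96, not 2, because the limits are defined to cover 95% of differences).
All p-values are two-sided; rows are flagged at α = 0.05 with no
multiple-testing correction.  Degenerate inputs (zero-variance differences,
constant vectors) raise explicit undefined-statistic errors, which the
table builder records as missing cells rather than numbers.

## Problem sizes and numerical choices

Simulation-based checks use 200–1,000 runs per track property, 100
replicate datasets of n = 200 for limits-of-agreement coverage, and 50
replicate 60-listener studies for parameter recovery; these sizes put
Monte-Carlo error comfortably inside each tolerance (e.g. the binomial SE
of a proportion at n = 10,000 is 0.005) while keeping the whole suite fast.
Parameter recovery is evaluated with steepened listeners (slopes × 0.1,
dial jitter 0.5 dB, staircase caps raised to 300 trials) on the four
continuous, unclipped measures (speech reception, digits-in-noise, both FM
conditions): measures quantised in 5 dB steps, bounded dials (the masked
listening level clips at 85 dB for ~18% of draws), accuracy scores and the
questionnaire carry irreducible discretisation noise that no listener
steepness removes, so they test attenuation, not recovery.

## Known limitations

- The not-measurable sentinel (NaN) conflates "aborted for false alarms"
  with "never detected"; the termination field disambiguates.
- The spatial-release composite follows the defining formula
  colocated − separated; its sign convention differs across published
  tables, and a consumer needing the opposite sign should negate it.
- Observed test-retest correlations under default slopes are substantially
  attenuated for measures whose population SD is small relative to
  trial-level noise (digits-in-noise, listening levels); this mirrors real
  batteries and is the package's central object of study rather than a
  defect.
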