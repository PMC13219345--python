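"""Adaptive psychophysical procedures with full trial logging.

Four track engines cover the battery:

* :func:`run_hughson_westlake` — modified Hughson–Westlake yes/no audiometry
  with interleaved silent catch trials (pure-tone detection).
* :func:`run_transformed_staircase` — two-stage k-down/1-up transformed
  up-down staircase with per-stage step magnitudes, multiplicative
  (exponential) or additive steps (FM and spectrotemporal modulation).
* :func:`run_simple_staircase` — fixed-trial-count 1-up/1-down staircase
  with possibly unequal steps (speech reception threshold, digits in noise).
* :func:`run_progressive_track` — fixed schedule of progressively harder
  target-to-masker ratios; threshold derived from the total number correct
  (spatial release from masking).

plus :func:`run_adjustment` for the dial-adjustment listening-level task and
:func:`staircase_target_proportion` for the analytic convergence point of an
up-down rule.

A *reversal* is a trial at which the intended direction of the level change
(ignoring clipping at the track bounds) flips; steps that are merely clipped
at a bound do not create reversals.  Threshold estimators average stimulus
values at reversals, in the track's estimator domain (linear or log2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import UnsupportedRuleError, ValidationError
from .listener_models import (
    CriterionSpec,
    DetectionSpec,
    PsychometricSpec,
    draw_response,
)

# termination reasons
COMPLETED = "completed"
FALSE_ALARM_ABORT = "false_alarm_abort"
FLOOR_REACHED = "floor_reached"
CONSECUTIVE_NO = "consecutive_no"
MAX_TRIALS = "max_trials"
NO_REVERSALS = "no_reversals"

#: sentinel for "threshold not measurable"
NOT_MEASURABLE = float("nan")


@dataclass(frozen=True)
class TrialRecord:
    """One logged trial: 1-based index, presented stimulus value (NaN on
    silent catch trials), catch flag, response (correct/"yes" = True),
    reversal flag, and stage identifier."""

    index: int
    presented_value: float
    is_catch: bool
    response: bool
    reversal: bool
    stage: int | str


@dataclass
class TrackResult:
    """Outcome of one adaptive run.

    ``threshold`` is NaN when the run terminated without a measurable
    threshold (false-alarm abort, or no correct response / no reversals where
    the estimator needs them).  ``reversal_values`` holds ``(stage, value)``
    pairs with values already in the estimator domain.
    """

    threshold: float
    unit: str
    trials: list[TrialRecord]
    reversal_values: list[tuple[int | str, float]]
    termination: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Trial log as a table (one row per trial)."""
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "value": [t.presented_value for t in self.trials],
                "is_catch": [t.is_catch for t in self.trials],
                "response": [t.response for t in self.trials],
                "reversal": [t.reversal for t in self.trials],
                "stage": [t.stage for t in self.trials],
            }
        )

    def summary(self) -> dict:
        """JSON-ready summary of the run."""
        return {
            "threshold": None if math.isnan(self.threshold) else self.threshold,
            "unit": self.unit,
            "termination": self.termination,
            "n_trials": self.n_trials,
            "reversal_values": [float(v) for _, v in self.reversal_values],
            **self.metadata,
        }


# ---------------------------------------------------------------------------
# configurations


@dataclass(frozen=True)
class StaircaseConfig:
    """Two-stage (or n-stage) transformed up-down staircase.

    ``stages`` is an ordered list of ``(step magnitude, reversal quota)``;
    multiplicative mode multiplies/divides by the magnitude (exponential
    adaptation), additive mode adds/subtracts it.  ``estimator_domain``
    selects the scale on which reversal values are averaged (and on which
    the listener's psychometric function is evaluated): ``"linear"`` or
    ``"log2"``.
    """

    n_down: int = 3
    n_up: int = 1
    step_mode: str = "multiplicative"
    stages: tuple[tuple[float, int], ...] = ((2 ** 0.5, 3), (2 ** 0.1, 6))
    start_value: float = 20.0
    bounds: tuple[float, float] = (1e-3, 1e4)
    max_trials: int = 100
    estimator_domain: str = "linear"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.n_down < 1 or self.n_up < 1:
            raise ValidationError("n_down and n_up must be >= 1")
        if self.step_mode not in ("multiplicative", "additive"):
            raise ValidationError("step_mode must be multiplicative or additive")
        if not self.stages:
            raise ValidationError("at least one stage is required")
        for step, quota in self.stages:
            if quota < 1:
                raise ValidationError("stage reversal quota must be >= 1")
            if self.step_mode == "multiplicative" and step <= 1:
                raise ValidationError("multiplicative steps must exceed 1")
            if self.step_mode == "additive" and step <= 0:
                raise ValidationError("additive steps must be positive")
        lo, hi = self.bounds
        if not lo < self.start_value < hi:
            raise ValidationError("start_value must lie strictly inside bounds")
        if self.step_mode == "multiplicative" and lo <= 0:
            raise ValidationError("multiplicative mode requires positive bounds")
        if self.estimator_domain not in ("linear", "log2"):
            raise ValidationError("estimator_domain must be linear or log2")
        if self.max_trials < 1:
            raise ValidationError("max_trials must be >= 1")


@dataclass(frozen=True)
class SimpleStairConfig:
    """Fixed-length 1-up/1-down staircase with possibly unequal steps.

    ``reference_level`` (dB), when set, is subtracted from the reversal-mean
    threshold to express it as a target-to-masker ratio.
    """

    up_step: float = 5.0
    down_step: float = 5.0
    n_trials: int = 20
    start_value: float = 55.0
    bounds: tuple[float, float] = (0.0, 95.0)
    reference_level: float | None = None
    unit: str = "dB SPL"

    def __post_init__(self) -> None:
        if self.up_step <= 0 or self.down_step <= 0:
            raise ValidationError("steps must be positive")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        lo, hi = self.bounds
        if not lo <= self.start_value <= hi:
            raise ValidationError("start_value must lie within bounds")


@dataclass(frozen=True)
class HWConfig:
    """Modified Hughson–Westlake yes/no audiometry.

    Start at 50 dB SPL; a miss on the very first trial jumps the level up by
    ``first_miss_jump``; otherwise the level moves by ``coarse_step`` until it
    reaches ``fine_boundary``, after which it moves by ``fine_step`` (down on
    "yes", up on "no").  Silent catch trials are interleaved after every
    ``catch_every_initial`` stimulus trials for the first
    ``catch_switch_after`` stimulus trials and after every
    ``catch_every_later`` thereafter; more than ``false_alarm_limit`` catch
    false alarms aborts the run.
    """

    start: float = 50.0
    first_miss_jump: float = 20.0
    coarse_step: float = 10.0
    fine_boundary: float = 30.0
    fine_step: float = 5.0
    catch_every_initial: int = 5
    catch_every_later: int = 3
    catch_switch_after: int = 15
    false_alarm_limit: int = 3
    floor: float = 0.0
    ceiling: float = 90.0
    consecutive_no_limit: int = 3
    max_trials: int = 60
    unit: str = "dB SPL"

    def __post_init__(self) -> None:
        if self.floor >= self.ceiling:
            raise ValidationError("floor must be below ceiling")
        if not self.floor <= self.start <= self.ceiling:
            raise ValidationError("start must lie within [floor, ceiling]")
        if min(self.coarse_step, self.fine_step, self.first_miss_jump) <= 0:
            raise ValidationError("steps must be positive")
        if self.catch_every_initial < 1 or self.catch_every_later < 1:
            raise ValidationError("catch cadences must be >= 1")
        if self.consecutive_no_limit < 1:
            raise ValidationError("consecutive_no_limit must be >= 1")


@dataclass(frozen=True)
class ProgressiveConfig:
    """Linear progressive track: a fixed grid of target-to-masker ratios,
    ``trials_per_level`` trials at each, threshold = ``threshold_constant``
    minus the total number correct (in dB TMR)."""

    tmr_grid: tuple[float, ...] = (10, 8, 6, 4, 2, 0, -2, -4, -6, -8, -10)
    trials_per_level: int = 2
    step: float = 2.0
    threshold_constant: float = 11.0
    unit: str = "dB TMR"

    def __post_init__(self) -> None:
        if len(self.tmr_grid) < 2:
            raise ValidationError("tmr_grid needs at least two levels")
        diffs = np.diff(self.tmr_grid)
        if not np.allclose(np.abs(diffs), self.step):
            raise ValidationError("tmr_grid must be spaced by the configured step")
        if self.trials_per_level < 1:
            raise ValidationError("trials_per_level must be >= 1")

    @property
    def n_levels(self) -> int:
        return len(self.tmr_grid)

    @property
    def total_trials(self) -> int:
        return self.n_levels * self.trials_per_level


@dataclass(frozen=True)
class AdjustmentConfig:
    """Dial bounds/step for the listening-level adjustment task; the target
    sentence is fixed at ``target_level`` dB SPL."""

    bounds: tuple[float, float] = (0.0, 85.0)
    step: float = 1.0
    target_level: float = 55.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("dial step must be positive")
        if self.bounds[0] >= self.bounds[1]:
            raise ValidationError("dial bounds must be increasing")


ADJUSTMENT_CONDITIONS = (
    "masked",
    "comfortable",
    "uncomfortable",
    "confirm_uncomfortable",
)


@dataclass(frozen=True)
class AdjustmentResult:
    """Settled dial level (dB SPL) and the derived TMR (dB) for one
    adjustment condition."""

    level: float
    tmr: float
    condition: str


# ---------------------------------------------------------------------------
# engines


def _clip(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def run_transformed_staircase(
    listener: PsychometricSpec,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
) -> TrackResult:
    """Run an n-down/n-up transformed staircase with staged step magnitudes.

    The level decreases after ``n_down`` consecutive correct responses and
    increases after ``n_up`` consecutive incorrect ones (counters reset after
    every step and on any break in the streak).  A stage completes after its
    reversal quota; the run completes with the final stage's quota or stops
    at ``max_trials``.  The threshold is the mean of the final-stage reversal
    values taken in the estimator domain; with no final-stage reversals the
    threshold is the not-measurable sentinel (NaN).

    With ``estimator_domain="log2"`` the listener's psychometric function is
    evaluated at log2 of the presented value, i.e. the listener is
    parameterised on the log2 scale (the scale on which thresholds are
    reported for exponentially adapted tracks).
    """
    transform: Callable[[float], float]
    transform = math.log2 if cfg.estimator_domain == "log2" else float

    value = cfg.start_value
    stage = 0
    rev_in_stage = 0
    consec_correct = 0
    consec_incorrect = 0
    last_dir = 0
    trials: list[TrialRecord] = []
    reversals: list[tuple[int, float]] = []
    termination = MAX_TRIALS

    for i in range(1, cfg.max_trials + 1):
        correct = draw_response(listener, transform(value), rng)
        direction = 0
        if correct:
            consec_correct += 1
            consec_incorrect = 0
            if consec_correct >= cfg.n_down:
                direction = -1
                consec_correct = 0
        else:
            consec_incorrect += 1
            consec_correct = 0
            if consec_incorrect >= cfg.n_up:
                direction = +1
                consec_incorrect = 0

        is_rev = direction != 0 and last_dir != 0 and direction != last_dir
        trials.append(TrialRecord(i, value, False, correct, is_rev, stage))
        if is_rev:
            reversals.append((stage, transform(value)))
            rev_in_stage += 1
        if direction != 0:
            last_dir = direction

        done = False
        if is_rev and rev_in_stage >= cfg.stages[stage][1]:
            if stage == len(cfg.stages) - 1:
                termination = COMPLETED
                done = True
            else:
                stage += 1
                rev_in_stage = 0
        if done:
            break
        if direction != 0:
            step = cfg.stages[stage][0]
            if cfg.step_mode == "multiplicative":
                value = value * step ** direction
            else:
                value = value + step * direction
            value = _clip(value, *cfg.bounds)

    final_stage = len(cfg.stages) - 1
    finals = [v for s, v in reversals if s == final_stage]
    threshold = float(np.mean(finals)) if finals else NOT_MEASURABLE
    return TrackResult(
        threshold=threshold,
        unit=cfg.unit,
        trials=trials,
        reversal_values=reversals,
        termination=termination,
        metadata={"engine": "transformed_staircase"},
    )


def run_simple_staircase(
    listener: PsychometricSpec,
    cfg: SimpleStairConfig,
    rng: np.random.Generator,
) -> TrackResult:
    """Run a 1-up/1-down staircase for exactly ``cfg.n_trials`` trials.

    The level moves down by ``down_step`` after a correct response and up by
    ``up_step`` after an incorrect one.  The threshold is the mean of the
    levels presented at reversal trials, minus ``reference_level`` when set.
    If no reversal occurs the fallback threshold is the final presented level
    (minus reference) and the termination is flagged ``no_reversals``.
    """
    value = cfg.start_value
    last_dir = 0
    trials: list[TrialRecord] = []
    reversals: list[tuple[int, float]] = []

    for i in range(1, cfg.n_trials + 1):
        correct = draw_response(listener, value, rng)
        direction = -1 if correct else +1
        is_rev = last_dir != 0 and direction != last_dir
        trials.append(TrialRecord(i, value, False, correct, is_rev, 0))
        if is_rev:
            reversals.append((0, value))
        last_dir = direction
        step = cfg.down_step if correct else cfg.up_step
        value = _clip(value + direction * step, *cfg.bounds)

    ref = cfg.reference_level or 0.0
    if reversals:
        threshold = float(np.mean([v for _, v in reversals])) - ref
        termination = COMPLETED
    else:
        threshold = trials[-1].presented_value - ref
        termination = NO_REVERSALS
    unit = "dB TMR" if cfg.reference_level is not None else cfg.unit
    return TrackResult(
        threshold=threshold,
        unit=unit,
        trials=trials,
        reversal_values=reversals,
        termination=termination,
        metadata={"engine": "simple_staircase"},
    )


def run_hughson_westlake(
    listener: DetectionSpec,
    cfg: HWConfig,
    rng: np.random.Generator,
) -> TrackResult:
    """Run modified Hughson–Westlake audiometry on a yes/no detection
    listener.

    The threshold is the last correctly detected level; the run ends on a
    "yes" at the floor (``floor_reached``), on ``consecutive_no_limit``
    successive "no" responses (``consecutive_no``), on more than
    ``false_alarm_limit`` catch false alarms (``false_alarm_abort``, no
    threshold), or at ``max_trials``.  With no correct response ever, the
    threshold is the not-measurable sentinel.
    """
    if not isinstance(listener, DetectionSpec):
        raise ValidationError("run_hughson_westlake requires a DetectionSpec")

    level = cfg.start
    stim_count = 0
    since_catch = 0
    consec_no = 0
    false_alarms = 0
    last_correct: float | None = None
    trials: list[TrialRecord] = []
    termination = MAX_TRIALS
    i = 0

    while i < cfg.max_trials:
        cadence = (
            cfg.catch_every_initial
            if stim_count < cfg.catch_switch_after
            else cfg.catch_every_later
        )
        if since_catch >= cadence:
            i += 1
            since_catch = 0
            yes = draw_response(listener, None, rng, is_catch=True)
            trials.append(TrialRecord(i, NOT_MEASURABLE, True, yes, False, "catch"))
            if yes:
                false_alarms += 1
                if false_alarms > cfg.false_alarm_limit:
                    termination = FALSE_ALARM_ABORT
                    break
            continue

        i += 1
        stim_count += 1
        since_catch += 1
        fine = level <= cfg.fine_boundary
        yes = draw_response(listener, level, rng)
        trials.append(
            TrialRecord(i, level, False, yes, False, "fine" if fine else "coarse")
        )
        if yes:
            consec_no = 0
            last_correct = level
            if level <= cfg.floor:
                termination = FLOOR_REACHED
                break
            step = cfg.fine_step if fine else cfg.coarse_step
            level = _clip(level - step, cfg.floor, cfg.ceiling)
        else:
            consec_no += 1
            if consec_no >= cfg.consecutive_no_limit:
                termination = CONSECUTIVE_NO
                break
            step = cfg.first_miss_jump if stim_count == 1 else (
                cfg.fine_step if fine else cfg.coarse_step
            )
            level = _clip(level + step, cfg.floor, cfg.ceiling)

    if termination == FALSE_ALARM_ABORT or last_correct is None:
        threshold = NOT_MEASURABLE
    else:
        threshold = last_correct
    return TrackResult(
        threshold=threshold,
        unit=cfg.unit,
        trials=trials,
        reversal_values=[],
        termination=termination,
        metadata={"engine": "hughson_westlake", "false_alarms": false_alarms},
    )


def run_progressive_track(
    listener: PsychometricSpec,
    cfg: ProgressiveConfig,
    rng: np.random.Generator,
) -> TrackResult:
    """Run the fixed progressive schedule: ``trials_per_level`` trials at
    each grid TMR; threshold (dB TMR) = ``threshold_constant`` − total
    correct."""
    trials: list[TrialRecord] = []
    n_correct = 0
    i = 0
    for level_idx, tmr in enumerate(cfg.tmr_grid):
        for _ in range(cfg.trials_per_level):
            i += 1
            correct = draw_response(listener, float(tmr), rng)
            n_correct += int(correct)
            trials.append(TrialRecord(i, float(tmr), False, correct, False, level_idx))
    threshold = cfg.threshold_constant - n_correct
    return TrackResult(
        threshold=float(threshold),
        unit=cfg.unit,
        trials=trials,
        reversal_values=[],
        termination=COMPLETED,
        metadata={"engine": "progressive", "n_correct": n_correct},
    )


def run_adjustment(
    listener: CriterionSpec,
    condition: str,
    cfg: AdjustmentConfig,
    rng: np.random.Generator,
) -> AdjustmentResult:
    """Simulate the dial-adjustment task for one condition.

    The settled noise level is the listener's criterion for the condition
    plus Gaussian jitter (SD ``listener.adjustment_sd``), rounded to the dial
    step and clipped to the dial bounds; the TMR is the settled level minus
    the fixed 55 dB SPL sentence level.
    """
    if condition not in ADJUSTMENT_CONDITIONS:
        raise ValidationError(
            f"unknown adjustment condition {condition!r}; "
            f"expected one of {ADJUSTMENT_CONDITIONS}"
        )
    if condition not in listener.levels:
        raise ValidationError(f"listener has no criterion for condition {condition!r}")
    raw = listener.levels[condition] + rng.normal(0.0, listener.adjustment_sd)
    settled = round(raw / cfg.step) * cfg.step
    settled = _clip(settled, *cfg.bounds)
    return AdjustmentResult(
        level=float(settled),
        tmr=float(settled - cfg.target_level),
        condition=condition,
    )


def staircase_target_proportion(
    n_down: int,
    n_up: int = 1,
    up_step: float = 1.0,
    down_step: float = 1.0,
) -> float:
    """Analytic convergence probability of an up-down rule.

    Equal steps, k-down/1-up: the track converges where the probability of a
    down move equals that of an up move, ``p**k = 1/2``, i.e.
    ``p = 2**(-1/k)``.  Unequal-step 1-up/1-down: zero drift requires
    ``p * down_step = (1 - p) * up_step``, i.e.
    ``p = up_step / (up_step + down_step)``.  Other combinations raise
    :class:`~hearsim.errors.UnsupportedRuleError` rather than approximating.
    """
    if n_down < 1 or n_up < 1:
        raise ValidationError("n_down and n_up must be >= 1")
    if up_step <= 0 or down_step <= 0:
        raise ValidationError("steps must be positive")
    equal_steps = math.isclose(up_step, down_step)
    if equal_steps and n_up == 1:
        return 0.5 ** (1.0 / n_down)
    if n_down == 1 and n_up == 1:
        return up_step / (up_step + down_step)
    raise UnsupportedRuleError(
        f"no analytic target for {n_down}-down/{n_up}-up with steps "
        f"{up_step}/{down_step}"
    )
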