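"""Scoring rules and the battery definition.

The battery comprises 19 reported measures: a hearing-handicap questionnaire
total, four listening-level adjustment conditions, five pure-tone detection
thresholds, two frequency-modulation detection thresholds, spectrotemporal
modulation depth, a speech reception threshold, two masked speech thresholds
plus their spatial-release difference, dichotic sentence identification
accuracy, and a digits-in-noise threshold averaged over two runs.

This module defines the per-measure :class:`TaskSpec` table, the
questionnaire and comfort-index scoring rules, the composite measures
derived from track outputs, and the dichotic sentence identification
procedure (which is a fixed-trial accuracy task rather than an adaptive
track).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .adaptive_tracks import (
    AdjustmentConfig,
    HWConfig,
    ProgressiveConfig,
    SimpleStairConfig,
    StaircaseConfig,
)
from .errors import UndefinedStatisticError, ValidationError
from .listener_models import (
    HIGHER_EASIER,
    PsychometricSpec,
    draw_response,
    psychometric_probability,
)

# ---------------------------------------------------------------------------
# questionnaire scoring

_HHIES_ITEM_SCORES = {"yes": 4, "sometimes": 2, "no": 0}

#: category boundaries on the 0-40 total score (all totals are even, so the
#: 9/25 gaps are unreachable by construction)
HHIES_CATEGORIES = (
    (8, "none"),
    (24, "mild_to_moderate"),
    (40, "severe"),
)


def score_hhies(items: Sequence[str]) -> tuple[int, str]:
    """Score a 10-item hearing-handicap questionnaire response.

    Items are ``"yes"`` (4 points), ``"sometimes"`` (2) or ``"no"`` (0);
    totals range 0-40.  Returns ``(total, category)`` with categories
    ``none`` (0-8), ``mild_to_moderate`` (10-24) and ``severe`` (26-40).
    """
    if len(items) != 10:
        raise ValidationError(f"expected 10 items, got {len(items)}")
    try:
        total = sum(_HHIES_ITEM_SCORES[item] for item in items)
    except KeyError as exc:
        raise ValidationError(f"invalid item response {exc.args[0]!r}") from exc
    for upper, category in HHIES_CATEGORIES:
        if total <= upper:
            return total, category
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# comfort index


@dataclass(frozen=True)
class ComfortTally:
    """Counts of post-task comfort answers: Yes / Maybe / No, plus missing
    answers (``no_response``), which are excluded from the percentage."""

    yes: int
    maybe: int
    no: int
    no_response: int = 0

    def __post_init__(self) -> None:
        if min(self.yes, self.maybe, self.no, self.no_response) < 0:
            raise ValidationError("tally counts must be non-negative")


def comfort_percentage(tally: ComfortTally) -> tuple[float, float]:
    """Comfort index and percentage for one task.

    The index is ``Yes + 0.5 * Maybe``; the percentage divides the index by
    the number of substantive respondents (Yes + Maybe + No), excluding
    non-respondents.  Raises if nobody responded.
    """
    respondents = tally.yes + tally.maybe + tally.no
    if respondents == 0:
        raise UndefinedStatisticError("comfort percentage undefined with no respondents")
    index = tally.yes + 0.5 * tally.maybe
    return index, 100.0 * index / respondents


# ---------------------------------------------------------------------------
# composites


def spatial_release(colocated: float, separated: float) -> float:
    """Spatial release from masking: colocated minus separated threshold
    (dB TMR).  Positive values mean spatial separation helped."""
    return colocated - separated


def din_average(run1: float, run2: float) -> float:
    """Digits-in-noise dependent variable: mean TMR of the two runs."""
    return (run1 + run2) / 2.0


def pt_binaural_average(left: float, right: float) -> float:
    """1 kHz pure-tone composite: mean of the left- and right-ear
    detection thresholds."""
    return (left + right) / 2.0


def derive_composites(measures: Mapping[str, float]) -> dict[str, float]:
    """Compute every composite whose components are present.

    NaN components propagate to the composite (missingness is preserved,
    never silently dropped).
    """
    out: dict[str, float] = {}
    if "SRM_C" in measures and "SRM_S" in measures:
        out["SRM"] = spatial_release(measures["SRM_C"], measures["SRM_S"])
    if "DIN_run1" in measures and "DIN_run2" in measures:
        out["DIN"] = din_average(measures["DIN_run1"], measures["DIN_run2"])
    if "PT_L1k" in measures and "PT_R1k" in measures:
        out["PT_1k"] = pt_binaural_average(measures["PT_L1k"], measures["PT_R1k"])
    return out


# ---------------------------------------------------------------------------
# dichotic sentence identification


@dataclass(frozen=True)
class DSIResult:
    """Accuracy (%) over all presented sentences, with trial bookkeeping."""

    accuracy: float
    n_trials: int
    n_sentences: int
    n_correct: int


def run_dsi(
    listener: PsychometricSpec,
    rng: np.random.Generator,
    presentation_level: float = 70.0,
    base_trials: int = 6,
    extension_trials: int = 6,
    sentences_per_trial: int = 2,
) -> DSIResult:
    """Run the dichotic sentence identification task.

    Each trial presents two simultaneous sentences (one per ear) at a fixed
    level; each sentence is identified independently with the listener's
    probability at that level.  Six trials are administered; unless all
    sentences in those trials are correct, six additional trials follow.
    Accuracy is correct sentences over all presented sentences, in percent.
    """
    p = psychometric_probability(listener, presentation_level)
    n_correct = 0
    n_sentences = 0
    for _ in range(base_trials * sentences_per_trial):
        n_sentences += 1
        n_correct += int(rng.random() < p)
    n_trials = base_trials
    if n_correct < n_sentences:  # not 100% on the first block
        for _ in range(extension_trials * sentences_per_trial):
            n_sentences += 1
            n_correct += int(rng.random() < p)
        n_trials += extension_trials
    return DSIResult(
        accuracy=100.0 * n_correct / n_sentences,
        n_trials=n_trials,
        n_sentences=n_sentences,
        n_correct=n_correct,
    )


# ---------------------------------------------------------------------------
# battery definition


@dataclass(frozen=True)
class TaskSpec:
    """How one reported measure is produced.

    ``engine`` names the procedure (``hughson_westlake``, ``staircase``,
    ``simple_staircase``, ``progressive``, ``adjustment``, ``hhies``,
    ``dsi`` or ``derived``); ``config`` is the engine configuration;
    ``listener`` holds the response-model defaults used when a latent
    threshold is turned into a virtual listener (slope, guess, lapse,
    false-alarm rate, adjustment SD, adjustment condition).  ``runs`` > 1
    averages repeated runs (digits in noise); ``components`` names the
    source measures of a derived composite.
    """

    measure: str
    engine: str
    units: str
    better: str  # "lower" or "higher" is better performance
    config: Any = None
    listener: Mapping[str, Any] = field(default_factory=dict)
    components: tuple[str, ...] = ()
    runs: int = 1

    def __post_init__(self) -> None:
        if self.better not in ("lower", "higher"):
            raise ValidationError("better must be 'lower' or 'higher'")
        if self.runs < 1:
            raise ValidationError("runs must be >= 1")


#: guess rates forced by response-set sizes: two candidate intervals in the
#: four-interval task, a 4x8 colour-by-number response grid, a closed set of
#: six sentences, and exact-order recall of a digit triplet.
GUESS_4I2AFC = 0.5
GUESS_CRM = 1.0 / 32.0
GUESS_DSI = 1.0 / 6.0
GUESS_DIGITS = 1e-3

MEASURES = (
    "HHIE_S",
    "CLL_M",
    "CLL_C",
    "CLL_U",
    "CLL_CU",
    "PT_L1k",
    "PT_R1k",
    "PTdc_500",
    "PTdc_2k",
    "PTdc_4k",
    "FM_DC",
    "FM_DT",
    "STM",
    "SRT",
    "SRM_C",
    "SRM_S",
    "SRM",
    "DSI",
    "DIN",
)

_CLL_CONDITION = {
    "CLL_M": "masked",
    "CLL_C": "comfortable",
    "CLL_U": "uncomfortable",
    "CLL_CU": "confirm_uncomfortable",
}


def default_battery(
    slope_scale: float = 1.0,
    adjustment_sd: float = 5.0,
    lapse_rate: float = 0.02,
) -> dict[str, TaskSpec]:
    """The default 19-measure battery.

    ``slope_scale`` multiplies every psychometric slope (smaller = steeper =
    less response noise), ``adjustment_sd`` is the within-listener dial SD of
    the adjustment task, ``lapse_rate`` the shared lapse default.  Each
    measure id appears exactly once.
    """
    if slope_scale <= 0:
        raise ValidationError("slope_scale must be positive")

    fm_cfg = StaircaseConfig(
        n_down=3,
        n_up=1,
        step_mode="multiplicative",
        stages=((2 ** 0.5, 3), (2 ** 0.1, 6)),
        start_value=20.0,
        bounds=(1e-3, 1e4),
        estimator_domain="log2",
        unit="log2 Hz",
    )
    stm_cfg = StaircaseConfig(
        n_down=3,
        n_up=1,
        step_mode="additive",
        stages=((2.0, 3), (2.0, 6)),
        start_value=10.0,
        bounds=(0.0, 40.0),
        estimator_domain="linear",
        unit="dB",
    )
    srt_cfg = SimpleStairConfig(
        up_step=5.0, down_step=5.0, n_trials=20, start_value=55.0,
        bounds=(0.0, 95.0), reference_level=None, unit="dB SPL",
    )
    din_cfg = SimpleStairConfig(
        up_step=5.0, down_step=2.0, n_trials=25, start_value=65.0,
        bounds=(0.0, 95.0), reference_level=65.0, unit="dB SPL",
    )
    hw_cfg = HWConfig()
    srm_cfg = ProgressiveConfig()
    adj_cfg = AdjustmentConfig()

    battery: dict[str, TaskSpec] = {}
    battery["HHIE_S"] = TaskSpec("HHIE_S", "hhies", "points", "lower")
    for mid, cond in _CLL_CONDITION.items():
        battery[mid] = TaskSpec(
            mid, "adjustment", "dB SPL", "higher", adj_cfg,
            {"condition": cond, "adjustment_sd": adjustment_sd},
        )
    for mid in ("PT_L1k", "PT_R1k", "PTdc_500", "PTdc_2k", "PTdc_4k"):
        battery[mid] = TaskSpec(
            mid, "hughson_westlake", "dB SPL", "lower", hw_cfg,
            {"slope": 3.0 * slope_scale, "guess": 0.0,
             "lapse": lapse_rate, "false_alarm": 0.01},
        )
    for mid in ("FM_DC", "FM_DT"):
        battery[mid] = TaskSpec(
            mid, "staircase", "log2 Hz", "lower", fm_cfg,
            {"slope": 0.5 * slope_scale, "guess": GUESS_4I2AFC, "lapse": lapse_rate},
        )
    battery["STM"] = TaskSpec(
        "STM", "staircase", "dB", "lower", stm_cfg,
        {"slope": 1.0 * slope_scale, "guess": GUESS_4I2AFC, "lapse": lapse_rate},
    )
    battery["SRT"] = TaskSpec(
        "SRT", "simple_staircase", "dB SPL", "lower", srt_cfg,
        {"slope": 4.0 * slope_scale, "guess": GUESS_CRM, "lapse": lapse_rate},
    )
    for mid in ("SRM_C", "SRM_S"):
        battery[mid] = TaskSpec(
            mid, "progressive", "dB TMR", "lower", srm_cfg,
            {"slope": 2.0 * slope_scale, "guess": GUESS_CRM, "lapse": lapse_rate},
        )
    battery["SRM"] = TaskSpec(
        "SRM", "derived", "dB TMR", "higher", components=("SRM_C", "SRM_S"),
    )
    battery["DSI"] = TaskSpec(
        "DSI", "dsi", "% correct", "higher", None,
        {"guess": GUESS_DSI, "lapse": lapse_rate},
    )
    battery["DIN"] = TaskSpec(
        "DIN", "simple_staircase", "dB TMR", "lower", din_cfg,
        {"slope": 1.5 * slope_scale, "guess": GUESS_DIGITS, "lapse": lapse_rate},
        runs=2,
    )

    assert tuple(battery) == MEASURES
    return battery
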