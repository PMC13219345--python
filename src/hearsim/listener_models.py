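"""Virtual listeners: probabilistic response models for adaptive tracks.

A virtual listener stands in for a human participant.  Its behaviour on a
single trial is a Bernoulli draw from a psychometric function

    p(x) = gamma + (1 - gamma) * (1 - lam) * F(s * (x - alpha) / beta)

where ``x`` is the adaptive stimulus parameter (dB SPL, dB TMR, dB depth, or
log2 Hz depth depending on the task), ``alpha`` is the location (threshold),
``beta > 0`` the spread, ``gamma`` the guess rate set by the response-set
size, ``lam`` a small lapse rate, ``F`` a sigmoid (logistic by default), and
``s = +1`` when larger stimulus values are easier (detection-type tasks) or
``-1`` when they are harder (e.g. a masker level).  The output is bounded in
``[gamma, 1 - lam * (1 - gamma)]``.

Yes/no detection tasks additionally carry a level-independent false-alarm
rate that applies only on silent catch trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError

#: larger stimulus values make the trial easier (detection-type tasks)
HIGHER_EASIER = "higher_easier"
#: larger stimulus values make the trial harder (masker-level-type tasks)
HIGHER_HARDER = "higher_harder"

_DIRECTIONS = (HIGHER_EASIER, HIGHER_HARDER)
_FORMS = ("logistic",)


@dataclass(frozen=True)
class PsychometricSpec:
    """Response model of one virtual listener on one task.

    Parameters
    ----------
    location
        Threshold parameter ``alpha`` in task units.
    slope
        Spread parameter ``beta`` (> 0), the scale of the logistic argument,
        in the same units as ``location``.
    guess_rate
        Lower asymptote ``gamma`` in ``[0, 1)``; fixed by the response-set
        size (0.5 for four-interval two-alternative tasks, 1/6 for a closed
        set of six sentences, ...).
    lapse_rate
        Lapse probability ``lam`` in ``[0, 0.5)``.
    direction
        ``"higher_easier"`` or ``"higher_harder"``.
    form
        Sigmoid family; only ``"logistic"`` is implemented.
    """

    location: float
    slope: float
    guess_rate: float = 0.0
    lapse_rate: float = 0.02
    direction: str = HIGHER_EASIER
    form: str = "logistic"

    def __post_init__(self) -> None:
        if not math.isfinite(self.location):
            raise ValidationError("location must be finite")
        if not (self.slope > 0 and math.isfinite(self.slope)):
            raise ValidationError(f"slope must be positive, got {self.slope}")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValidationError(f"guess_rate must be in [0, 1), got {self.guess_rate}")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValidationError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")
        if self.direction not in _DIRECTIONS:
            raise ValidationError(f"direction must be one of {_DIRECTIONS}")
        if self.form not in _FORMS:
            raise ValidationError(f"unsupported psychometric form {self.form!r}")

    @property
    def ceiling(self) -> float:
        """Upper asymptote ``1 - lapse_rate * (1 - guess_rate)``."""
        return 1.0 - self.lapse_rate * (1.0 - self.guess_rate)


@dataclass(frozen=True)
class DetectionSpec:
    """Yes/no detection listener: a psychometric function plus catch-trial
    false-alarm behaviour.

    ``false_alarm_rate`` is the probability of responding "yes" on a silent
    catch trial; it is independent of stimulus level and applies only to
    catch trials.
    """

    psychometric: PsychometricSpec
    false_alarm_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.false_alarm_rate < 1.0:
            raise ValidationError(
                f"false_alarm_rate must be in [0, 1), got {self.false_alarm_rate}"
            )


@dataclass(frozen=True)
class CriterionSpec:
    """Listener model for the sound-level adjustment (comfortable listening
    levels) task: a criterion level per condition plus within-listener
    adjustment variability.

    ``levels`` maps condition name (``masked``, ``comfortable``,
    ``uncomfortable``, ``confirm_uncomfortable``) to the listener's criterion
    noise level in dB SPL.  The settled dial value is the criterion plus
    Gaussian jitter with SD ``adjustment_sd``, rounded to the dial step and
    clipped to the dial bounds.
    """

    levels: Mapping[str, float]
    adjustment_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.adjustment_sd < 0:
            raise ValidationError("adjustment_sd must be >= 0")
        for cond, lvl in self.levels.items():
            if not math.isfinite(lvl):
                raise ValidationError(f"criterion level for {cond!r} must be finite")


@dataclass(frozen=True)
class RespondentSpec:
    """Questionnaire behaviour of one virtual participant.

    ``hhies_trait`` is a latent hearing-handicap scalar on the questionnaire's
    0-40 total-score scale; it maps to per-item endorsement probabilities (see
    :func:`hearsim.study_simulation` for the item model).
    ``comfort_propensities`` are the probabilities of answering Yes / Maybe /
    No to the post-task comfort question (they must sum to 1), and
    ``nonresponse_rate`` is the probability that the answer is missing.
    """

    hhies_trait: float = 0.0
    comfort_propensities: tuple[float, float, float] = (0.85, 0.10, 0.05)
    nonresponse_rate: float = 0.0

    def __post_init__(self) -> None:
        p = self.comfort_propensities
        if len(p) != 3 or any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValidationError(
                "comfort_propensities must be three non-negative values summing to 1"
            )
        if not 0.0 <= self.nonresponse_rate <= 1.0:
            raise ValidationError("nonresponse_rate must be in [0, 1]")


def _logistic(z):
    return expit(z)


def psychometric_probability(spec: PsychometricSpec, x):
    """Probability of a correct (or "yes") response at stimulus value ``x``.

    Vectorised over ``x``.  Monotone non-decreasing in ``x`` for
    ``higher_easier`` specs and non-increasing for ``higher_harder`` specs;
    bounded in ``[guess_rate, spec.ceiling]``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("stimulus value must be finite")
    sign = 1.0 if spec.direction == HIGHER_EASIER else -1.0
    z = sign * (x - spec.location) / spec.slope
    g, lam = spec.guess_rate, spec.lapse_rate
    p = g + (1.0 - g) * (1.0 - lam) * _logistic(z)
    return float(p) if p.ndim == 0 else p


def draw_response(
    spec: PsychometricSpec | DetectionSpec,
    x: float | None,
    rng: np.random.Generator,
    is_catch: bool = False,
) -> bool:
    """Draw one Bernoulli response from a listener.

    For forced-choice specs the return value means correct/incorrect; for
    detection specs it means yes/no.  On a catch trial (``is_catch``) the
    "yes" probability is the detection spec's false-alarm rate and ``x`` is
    ignored; catch trials require a :class:`DetectionSpec`.
    """
    if is_catch:
        if not isinstance(spec, DetectionSpec):
            raise ValidationError("catch trials require a DetectionSpec listener")
        return bool(rng.random() < spec.false_alarm_rate)
    psycho = spec.psychometric if isinstance(spec, DetectionSpec) else spec
    p = psychometric_probability(psycho, x)
    return bool(rng.random() < p)


def spec_with_probability_at(
    p_target: float,
    x: float,
    slope: float,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.02,
    direction: str = HIGHER_EASIER,
) -> PsychometricSpec:
    """Construct a logistic spec whose total response probability equals
    ``p_target`` at stimulus value ``x``.

    Solves ``F = (p - gamma) / ((1 - gamma)(1 - lam))`` and places the
    location so that the logistic argument equals ``logit(F)`` at ``x``.
    ``p_target`` must lie strictly between the guess rate and the ceiling.
    """
    ceiling = 1.0 - lapse_rate * (1.0 - guess_rate)
    if not guess_rate < p_target < ceiling:
        raise ValidationError(
            f"p_target must lie in ({guess_rate}, {ceiling}), got {p_target}"
        )
    f = (p_target - guess_rate) / ((1.0 - guess_rate) * (1.0 - lapse_rate))
    logit = math.log(f / (1.0 - f))
    sign = 1.0 if direction == HIGHER_EASIER else -1.0
    location = x - sign * slope * logit
    return PsychometricSpec(
        location=location,
        slope=slope,
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# serialisation: one row per listener per task

_POP_COLUMNS = [
    "listener",
    "task",
    "location",
    "slope",
    "guess_rate",
    "lapse_rate",
    "direction",
    "false_alarm_rate",
]


def population_to_frame(
    population: Mapping[str, Mapping[str, PsychometricSpec | DetectionSpec]],
) -> pd.DataFrame:
    """Flatten ``{listener id: {task: spec}}`` into a one-row-per-listener-
    per-task table (CSV-ready)."""
    rows = []
    for lid, tasks in population.items():
        for task, spec in tasks.items():
            fa = np.nan
            if isinstance(spec, DetectionSpec):
                fa = spec.false_alarm_rate
                spec = spec.psychometric
            rows.append(
                {
                    "listener": lid,
                    "task": task,
                    "location": spec.location,
                    "slope": spec.slope,
                    "guess_rate": spec.guess_rate,
                    "lapse_rate": spec.lapse_rate,
                    "direction": spec.direction,
                    "false_alarm_rate": fa,
                }
            )
    return pd.DataFrame(rows, columns=_POP_COLUMNS)


def population_from_frame(frame: pd.DataFrame):
    """Inverse of :func:`population_to_frame`."""
    population: dict[str, dict[str, PsychometricSpec | DetectionSpec]] = {}
    for row in frame.itertuples(index=False):
        spec: PsychometricSpec | DetectionSpec = PsychometricSpec(
            location=row.location,
            slope=row.slope,
            guess_rate=row.guess_rate,
            lapse_rate=row.lapse_rate,
            direction=row.direction,
        )
        if not pd.isna(row.false_alarm_rate):
            spec = DetectionSpec(spec, float(row.false_alarm_rate))
        population.setdefault(str(row.listener), {})[str(row.task)] = spec
    return population
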