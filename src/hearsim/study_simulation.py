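"""Synthetic two-timepoint study generator.

A cohort of virtual participants is drawn from a population model with the
statistical structure that the test-retest analysis assumes: for each
measure, the true underlying task parameter at the two timepoints,
``(theta_T1, theta_T2)``, is bivariate Gaussian with means
``(mu + delta, mu)``, common SD ``sigma`` and correlation ``rho``.  ``delta``
is the session bias (practice effect, expressed as T1 minus T2: positive
values mean worse first-session performance on lower-is-better scales).  The
latent model lives on each measure's reporting scale (log2 Hz for frequency
modulation, dB or points elsewhere), so ``rho`` stays interpretable.

Every virtual participant then completes the full battery at both
timepoints with independent trial-level response noise, yielding a
long-format study table; administration-error missingness can be injected
afterwards, completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .adaptive_tracks import (
    run_adjustment,
    run_hughson_westlake,
    run_progressive_track,
    run_simple_staircase,
    run_transformed_staircase,
)
from .battery_scoring import (
    TaskSpec,
    default_battery,
    run_dsi,
    score_hhies,
    spatial_release,
)
from .errors import ValidationError
from .listener_models import (
    HIGHER_EASIER,
    CriterionSpec,
    DetectionSpec,
    PsychometricSpec,
    RespondentSpec,
    spec_with_probability_at,
)

STUDY_COLUMNS = ["listener", "timepoint", "measure", "value", "unit", "comfort"]
TIMEPOINTS = ("T1", "T2")
LATENT_COLUMNS = ["listener", "measure", "theta_t1", "theta_t2"]


@dataclass(frozen=True)
class MeasureMoments:
    """Population moments of one measure: mean and SD of the latent
    parameter, test-retest correlation ``retest_rho`` and session bias
    ``session_bias`` (T1 minus T2)."""

    mean: float
    sd: float
    retest_rho: float
    session_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if not -1.0 <= self.retest_rho <= 1.0:
            raise ValidationError("retest_rho must lie in [-1, 1]")


# Default population moments: the first-timepoint column of the reliability
# report this generator emulates (means, SDs, correlations and biases of a
# 60-listener cohort of older adults).  Realism defaults, not ground truths.
_DEFAULT_MOMENTS: dict[str, MeasureMoments] = {
    "HHIE_S": MeasureMoments(12.4, 8.1, 0.90, 0.95),
    "CLL_M": MeasureMoments(68.0, 17.3, 0.30, 1.30),
    "CLL_C": MeasureMoments(46.0, 20.7, 0.21, -1.42),
    "CLL_U": MeasureMoments(60.0, 12.4, 0.23, -1.00),
    "CLL_CU": MeasureMoments(61.0, 13.9, 0.15, 0.98),
    "PT_L1k": MeasureMoments(36.0, 16.0, 0.62, 6.03),
    "PT_R1k": MeasureMoments(37.0, 15.9, 0.45, 6.90),
    "PTdc_500": MeasureMoments(19.0, 14.5, 0.35, 3.75),
    "PTdc_2k": MeasureMoments(29.0, 16.9, 0.69, 3.56),
    "PTdc_4k": MeasureMoments(26.0, 17.2, 0.60, 3.00),
    "FM_DC": MeasureMoments(0.6, 1.8, 0.55, 0.54),
    "FM_DT": MeasureMoments(2.7, 1.0, 0.58, 0.11),
    "STM": MeasureMoments(1.9, 0.8, 0.54, 0.13),
    "SRT": MeasureMoments(46.0, 10.1, 0.54, 2.60),
    "SRM_C": MeasureMoments(3.8, 2.0, 0.36, 0.02),
    "SRM_S": MeasureMoments(2.5, 3.9, 0.57, 1.05),
    "DSI": MeasureMoments(80.3, 21.3, 0.68, -3.33),
    "DIN": MeasureMoments(-19.0, 3.1, 0.57, 0.18),
}

# Per-task comfort percentages (fractions) used to set Yes/Maybe/No
# propensities; tasks not listed get no comfort question.
_DEFAULT_COMFORT: dict[str, float] = {
    "CLL_M": 0.867, "CLL_C": 0.867, "CLL_U": 0.867, "CLL_CU": 0.867,
    "PT_L1k": 0.953, "PT_R1k": 0.953, "PTdc_500": 0.953,
    "PTdc_2k": 0.953, "PTdc_4k": 0.953,
    "FM_DC": 0.97, "FM_DT": 0.97, "STM": 0.97,
    "SRT": 0.79, "SRM_C": 0.79, "SRM_S": 0.79,
    "DSI": 0.985, "DIN": 1.0,
}


def comfort_propensities(pct: float) -> tuple[float, float, float]:
    """Map an expected comfort fraction to (Yes, Maybe, No) probabilities
    with expected index ``Yes + 0.5*Maybe`` equal to ``pct``."""
    if not 0.0 <= pct <= 1.0:
        raise ValidationError("comfort fraction must lie in [0, 1]")
    maybe = min(0.1, 2.0 * (1.0 - pct))
    yes = pct - 0.5 * maybe
    no = max(0.0, 1.0 - yes - maybe)
    return (yes, maybe, no)


@dataclass(frozen=True)
class PopulationConfig:
    """Generative parameters of the synthetic cohort."""

    n_listeners: int = 60
    measures: Mapping[str, MeasureMoments] = field(
        default_factory=lambda: dict(_DEFAULT_MOMENTS)
    )
    comfort: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMFORT)
    )
    nonresponse_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 2:
            raise ValidationError("n_listeners must be >= 2")
        if not 0.0 <= self.nonresponse_rate <= 1.0:
            raise ValidationError("nonresponse_rate must lie in [0, 1]")


@dataclass(frozen=True)
class MissingnessConfig:
    """Completely-at-random administration-error missingness:
    ``admin_skip_rate`` blanks comfort answers, ``technical_loss_rate``
    blanks task values."""

    admin_skip_rate: float = 0.2
    technical_loss_rate: float = 0.005

    def __post_init__(self) -> None:
        for rate in (self.admin_skip_rate, self.technical_loss_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("missingness rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# latent profiles


def draw_latent_profiles(
    cfg: PopulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw true per-listener, per-measure task parameters for both
    timepoints.

    Returns a frame with columns ``listener, measure, theta_t1, theta_t2``.
    ``theta_t1`` has mean ``mu + session_bias`` and ``theta_t2`` mean ``mu``;
    both share SD ``sigma`` with correlation ``retest_rho``.  Derived
    measures (composites) are not drawn.

    Each (measure, listener) pair draws from its own named substream of
    ``seed`` (default ``cfg.seed``), so enlarging the cohort never perturbs
    the latents of existing listeners.
    """
    if seed is None:
        seed = cfg.seed
    listeners = [f"L{i:03d}" for i in range(1, cfg.n_listeners + 1)]
    rows = []
    for mi, (measure, m) in enumerate(cfg.measures.items()):
        rho_c = math.sqrt(1 - m.retest_rho ** 2)
        for li, lid in enumerate(listeners):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(7001, mi, li))
            )
            z1, z2 = rng.standard_normal(2)
            rows.append({
                "listener": lid,
                "measure": measure,
                "theta_t1": float(m.mean + m.session_bias + m.sd * z1),
                "theta_t2": float(m.mean + m.sd * (m.retest_rho * z1 + rho_c * z2)),
            })
    return pd.DataFrame(rows, columns=LATENT_COLUMNS)


# ---------------------------------------------------------------------------
# running the battery


def _listener_from_theta(task: TaskSpec, theta: float):
    """Turn a latent parameter into the listener object its engine needs."""
    lk = task.listener
    if task.engine == "adjustment":
        return CriterionSpec({lk["condition"]: theta}, lk["adjustment_sd"])
    if task.engine == "hughson_westlake":
        psycho = PsychometricSpec(
            location=theta, slope=lk["slope"], guess_rate=lk["guess"],
            lapse_rate=lk["lapse"], direction=HIGHER_EASIER,
        )
        return DetectionSpec(psycho, lk["false_alarm"])
    if task.engine == "dsi":
        guess, lapse = lk["guess"], lk["lapse"]
        ceiling = 1.0 - lapse * (1.0 - guess)
        p = min(max(theta / 100.0, guess + 0.01), ceiling - 0.005)
        return spec_with_probability_at(p, x=70.0, slope=1.0,
                                        guess_rate=guess, lapse_rate=lapse)
    if task.engine == "simple_staircase" and task.config.reference_level is not None:
        # staircase runs on the raw presentation level; theta is a TMR
        location = theta + task.config.reference_level
    else:
        location = theta
    return PsychometricSpec(
        location=location, slope=lk["slope"], guess_rate=lk["guess"],
        lapse_rate=lk["lapse"], direction=HIGHER_EASIER,
    )


def _hhies_items(theta: float, rng: np.random.Generator) -> list[str]:
    """Item model: endorsement probability increases with the latent trait
    ``theta`` on the 0-40 scale so that the expected total equals theta
    (per item, P(yes) = q^2, P(sometimes) = 2q(1-q) with q = theta/40)."""
    q = min(max(theta / 40.0, 0.0), 1.0)
    items = []
    for _ in range(10):
        r = rng.random()
        if r < q * q:
            items.append("yes")
        elif r < q * q + 2 * q * (1 - q):
            items.append("sometimes")
        else:
            items.append("no")
    return items


def _run_measure(task: TaskSpec, theta: float, rng: np.random.Generator) -> float:
    if task.engine == "hhies":
        total, _ = score_hhies(_hhies_items(theta, rng))
        return float(total)
    listener = _listener_from_theta(task, theta)
    if task.engine == "adjustment":
        return run_adjustment(listener, task.listener["condition"], task.config, rng).level
    if task.engine == "hughson_westlake":
        return run_hughson_westlake(listener, task.config, rng).threshold
    if task.engine == "staircase":
        return run_transformed_staircase(listener, task.config, rng).threshold
    if task.engine == "simple_staircase":
        vals = [
            run_simple_staircase(listener, task.config, rng).threshold
            for _ in range(task.runs)
        ]
        return float(np.mean(vals))
    if task.engine == "progressive":
        return run_progressive_track(listener, task.config, rng).threshold
    if task.engine == "dsi":
        return run_dsi(listener, rng).accuracy
    raise ValidationError(f"unknown engine {task.engine!r}")


def _draw_comfort(pct: float | None, nonresponse: float,
                  rng: np.random.Generator) -> str | float:
    if pct is None:
        return np.nan
    respondent = RespondentSpec(
        comfort_propensities=comfort_propensities(pct),
        nonresponse_rate=nonresponse,
    )
    if rng.random() < respondent.nonresponse_rate:
        return np.nan
    yes, maybe, _no = respondent.comfort_propensities
    r = rng.random()
    if r < yes:
        return "Yes"
    if r < yes + maybe:
        return "Maybe"
    return "No"


def simulate_study(
    profiles: pd.DataFrame,
    battery: Mapping[str, TaskSpec],
    seed: int = 0,
    comfort: Mapping[str, float] | None = None,
    nonresponse_rate: float = 0.2,
) -> pd.DataFrame:
    """Run the full battery on every latent profile at both timepoints.

    Returns the long-format study table (one record per listener x timepoint
    x measure, with a comfort answer where the task asks one).  All trial
    noise flows from ``seed`` through per-(listener, measure, timepoint)
    substreams, so adding a listener never perturbs another listener's data
    and identical seeds give identical tables.
    """
    if comfort is None:
        comfort = dict(_DEFAULT_COMFORT)
    by_listener = {
        lid: grp.set_index("measure") for lid, grp in profiles.groupby("listener")
    }
    primitive = [m for m, t in battery.items() if t.engine != "derived"]
    derived = [m for m, t in battery.items() if t.engine == "derived"]
    for m in primitive:
        missing = [lid for lid, g in by_listener.items() if m not in g.index]
        if missing:
            raise ValidationError(
                f"measure {m!r} has no latent parameter for listener(s) "
                f"{missing[:3]}"
            )
    measure_index = {m: k for k, m in enumerate(battery)}

    rows = []
    for li, lid in enumerate(sorted(by_listener)):
        prof = by_listener[lid]
        values: dict[tuple[str, str], float] = {}
        for m in primitive:
            task = battery[m]
            for ti, tp in enumerate(TIMEPOINTS):
                theta = prof.loc[m, "theta_t1" if tp == "T1" else "theta_t2"]
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(li, measure_index[m], ti))
                )
                value = _run_measure(task, float(theta), rng)
                cmf = _draw_comfort(comfort.get(m), nonresponse_rate, rng)
                values[(m, tp)] = value
                rows.append({"listener": lid, "timepoint": tp, "measure": m,
                             "value": value, "unit": task.units, "comfort": cmf})
        for m in derived:
            task = battery[m]
            for tp in TIMEPOINTS:
                comps = [values.get((c, tp), np.nan) for c in task.components]
                value = spatial_release(*comps) if m == "SRM" else float(np.mean(comps))
                rows.append({"listener": lid, "timepoint": tp, "measure": m,
                             "value": value, "unit": task.units, "comfort": np.nan})
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def inject_missingness(
    table: pd.DataFrame,
    cfg: MissingnessConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Independently blank task values (technical loss) and comfort answers
    (administration skips), completely at random.  The input table is left
    unmodified."""
    out = table.copy()
    n = len(out)
    lose_value = rng.random(n) < cfg.technical_loss_rate
    lose_comfort = rng.random(n) < cfg.admin_skip_rate
    out.loc[lose_value, "value"] = np.nan
    out.loc[lose_comfort, "comfort"] = np.nan
    return out


# ---------------------------------------------------------------------------
# configuration serialisation


def population_to_dict(cfg: PopulationConfig) -> dict:
    return {
        "n_listeners": cfg.n_listeners,
        "nonresponse_rate": cfg.nonresponse_rate,
        "seed": cfg.seed,
        "measures": {
            m: {"mean": mm.mean, "sd": mm.sd, "retest_rho": mm.retest_rho,
                "session_bias": mm.session_bias}
            for m, mm in cfg.measures.items()
        },
        "comfort": dict(cfg.comfort),
    }


def population_from_dict(data: Mapping) -> PopulationConfig:
    """Build a population config from a parsed YAML/JSON mapping.

    Unrecognised measure ids (not in the default battery) are rejected by
    name; omitted measures keep their defaults.
    """
    measures = dict(_DEFAULT_MOMENTS)
    for mid, fields in (data.get("measures") or {}).items():
        if mid not in _DEFAULT_MOMENTS:
            raise ValidationError(f"unknown measure id {mid!r} in population config")
        base = measures[mid]
        measures[mid] = replace(base, **fields)
    comfort = dict(_DEFAULT_COMFORT)
    for mid, pct in (data.get("comfort") or {}).items():
        if mid not in _DEFAULT_COMFORT:
            raise ValidationError(f"unknown measure id {mid!r} in comfort config")
        comfort[mid] = float(pct)
    return PopulationConfig(
        n_listeners=int(data.get("n_listeners", 60)),
        measures=measures,
        comfort=comfort,
        nonresponse_rate=float(data.get("nonresponse_rate", 0.2)),
        seed=int(data.get("seed", 0)),
    )


def load_population_yaml(path) -> PopulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return population_from_dict(data)


def save_population_yaml(cfg: PopulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(population_to_dict(cfg), fh, sort_keys=False)
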