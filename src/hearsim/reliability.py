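"""Test-retest reliability analysis and the tabular report.

Per measure: a single-pass 3-SD outlier screen per timepoint, restriction to
pairwise-complete listeners, then three complementary statistics on the
T1/T2 pairs — a paired (repeated-measures) t-test for systematic session
effects, a Pearson correlation for within-subject consistency, and
Bland–Altman bias with 95% limits of agreement (bias ± 1.96 SD of the
paired differences) for absolute agreement.  Two-sided p-values throughout;
significance flagged at alpha = 0.05 with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .battery_scoring import ComfortTally, TaskSpec, comfort_percentage
from .errors import UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96  # 95% limits of agreement
ALPHA = 0.05

RELIABILITY_COLUMNS = [
    "measure", "unit", "n",
    "t1_mean", "t1_sd", "t2_mean", "t2_sd",
    "t", "t_p", "rho", "rho_p",
    "bias", "loa_lower", "loa_upper",
]


@dataclass(frozen=True)
class ReliabilityRow:
    """One measure's reliability summary (all statistics on the measure's
    reporting scale)."""

    measure: str
    unit: str
    n: int
    t1_mean: float
    t1_sd: float
    t2_mean: float
    t2_sd: float
    t: float
    t_p: float
    rho: float
    rho_p: float
    bias: float
    loa_lower: float
    loa_upper: float


def remove_outliers(values, k: float = 3.0) -> np.ndarray:
    """Single-pass k-SD outlier screen.

    Returns a boolean keep-mask over ``values``: keep v iff
    ``|v - mean| <= k * SD`` with mean/SD computed once over all finite
    values.  Non-finite values are never kept.  With fewer than 3 finite
    values, or zero SD, everything finite is kept (removal is skipped with a
    logged warning in the former case).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        logger.warning("fewer than 3 finite values; skipping outlier removal")
        return finite
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    if sd == 0:
        return finite
    keep = finite & (np.abs(v - mean) <= k * sd)
    return keep


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired t-test of x against y.

    ``t = mean(d) / (SD(d)/sqrt(n))`` with ``d = x - y`` and the sample SD
    (n-1 denominator); df = n-1; two-sided p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 2:
        raise ValidationError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value via the t
    transform on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement.

    ``bias = mean(d)`` with ``d = x - y``;
    ``LoA = bias ± 1.96 * SD(d)`` (sample SD).  Returns
    ``(bias, loa_lower, loa_upper)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("Bland-Altman needs paired vectors with n >= 2")
    d = x - y
    bias = float(d.mean())
    half = LOA_MULTIPLIER * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValidationError("Fisher interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


# ---------------------------------------------------------------------------
# the report


def build_reliability_table(
    study: pd.DataFrame,
    battery: Mapping[str, TaskSpec],
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Build the per-measure reliability table from a long-format study.

    For each battery measure: the outlier screen runs per timepoint (before
    pairing), listeners are restricted to pairwise-complete ones, and all
    row statistics are computed on those pairs.  Measures with fewer than 3
    complete pairs yield a row of missing statistics (logged).
    """
    for tp in ("T1", "T2"):
        if tp not in set(study["timepoint"]):
            raise ValidationError(f"study table lacks timepoint {tp}")
    rows = []
    for measure, task in battery.items():
        wide = (
            study[study["measure"] == measure]
            .pivot(index="listener", columns="timepoint", values="value")
            .reindex(columns=["T1", "T2"])
        )
        for tp in ("T1", "T2"):
            col = wide[tp].to_numpy()
            keep = remove_outliers(col, k=outlier_sd)
            wide.loc[~keep, tp] = np.nan
        complete = wide.dropna()
        n = len(complete)
        if n < 3:
            logger.warning("measure %s has %d complete pairs; row left empty",
                           measure, n)
            rows.append({"measure": measure, "unit": task.units, "n": n,
                         **{c: np.nan for c in RELIABILITY_COLUMNS[3:]}})
            continue
        x = complete["T1"].to_numpy()
        y = complete["T2"].to_numpy()
        try:
            t, _, t_p = paired_ttest(x, y)
        except UndefinedStatisticError:
            t, t_p = np.nan, np.nan
        try:
            rho, rho_p = pearson_corr(x, y)
        except UndefinedStatisticError:
            rho, rho_p = np.nan, np.nan
        bias, lo, hi = bland_altman(x, y)
        rows.append({
            "measure": measure, "unit": task.units, "n": n,
            "t1_mean": x.mean(), "t1_sd": x.std(ddof=1),
            "t2_mean": y.mean(), "t2_sd": y.std(ddof=1),
            "t": t, "t_p": t_p, "rho": rho, "rho_p": rho_p,
            "bias": bias, "loa_lower": lo, "loa_upper": hi,
        })
    return pd.DataFrame(rows, columns=RELIABILITY_COLUMNS)


def pairwise_complete(
    study: pd.DataFrame,
    battery: Mapping[str, TaskSpec],
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """The study records that survive the outlier screen and pairwise-
    complete restriction of :func:`build_reliability_table` (useful for
    idempotence checks and downstream analyses)."""
    kept = []
    for measure in battery:
        wide = (
            study[study["measure"] == measure]
            .pivot(index="listener", columns="timepoint", values="value")
            .reindex(columns=["T1", "T2"])
        )
        for tp in ("T1", "T2"):
            keep = remove_outliers(wide[tp].to_numpy(), k=outlier_sd)
            wide.loc[~keep, tp] = np.nan
        complete = wide.dropna().index
        sub = study[(study["measure"] == measure) & study["listener"].isin(complete)]
        kept.append(sub)
    return pd.concat(kept, ignore_index=True)


def comfort_tallies(study: pd.DataFrame) -> dict[str, ComfortTally]:
    """Per-measure comfort tallies pooled over timepoints.  Records whose
    task asks no comfort question (all answers missing) are skipped."""
    tallies = {}
    for measure, grp in study.groupby("measure", sort=False):
        c = grp["comfort"]
        counts = c.value_counts()
        yes, maybe, no = (int(counts.get(k, 0)) for k in ("Yes", "Maybe", "No"))
        n_missing = int(c.isna().sum())
        if yes + maybe + no == 0:
            continue
        tallies[measure] = ComfortTally(yes, maybe, no, n_missing)
    return tallies


def render_report(
    table: pd.DataFrame,
    tallies: Mapping[str, ComfortTally] | None = None,
) -> str:
    """Render the reliability table (and optional comfort summary) as a
    markdown report mirroring the summary-table layout: one row per task
    with n, per-timepoint mean (SD), t (p), rho (p), bias and LoA, with
    ``*`` marking p < 0.05."""

    def _sig(p: float) -> str:
        return "*" if (p == p and p < ALPHA) else ""

    lines = [
        "# Test-retest reliability",
        "",
        "| Task | N | T1 Mean (SD) | T2 Mean (SD) | t (p) | rho (p) | Bias | LoA |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for row in table.itertuples(index=False):
        if row.n < 3 or not np.isfinite(row.t1_mean):
            lines.append(f"| {row.measure} ({row.unit}) | {row.n} | - | - | - | - | - | - |")
            continue
        lines.append(
            f"| {row.measure} ({row.unit}) | {row.n} "
            f"| {row.t1_mean:.1f} ({row.t1_sd:.1f}) "
            f"| {row.t2_mean:.1f} ({row.t2_sd:.1f}) "
            f"| {row.t:.2f} ({row.t_p:.3f}){_sig(row.t_p)} "
            f"| {row.rho:.2f} ({row.rho_p:.3f}){_sig(row.rho_p)} "
            f"| {row.bias:.2f} "
            f"| ({row.loa_lower:.1f}, {row.loa_upper:.1f}) |"
        )
    lines.append("")
    lines.append(f"`*` significant at alpha = {ALPHA}.")
    if tallies:
        lines += ["", "## Task comfort", "",
                  "| Task | Yes | Maybe | No | No response | Comfort % |",
                  "|---|---|---|---|---|---|"]
        for measure, tally in tallies.items():
            _, pct = comfort_percentage(tally)
            lines.append(
                f"| {measure} | {tally.yes} | {tally.maybe} | {tally.no} "
                f"| {tally.no_response} | {pct:.1f} |"
            )
    return "\n".join(lines) + "\n"
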