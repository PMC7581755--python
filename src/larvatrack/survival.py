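"""Survival and metamorphosis rates, and larval longevity with censoring.

Count tables record, per replicate container, the number of healthy
larvae and of metamorphosed polyps at each sampled age.  The survival
rate at an age is the number of healthy larvae divided by the initial
number at age 0; the metamorphosis rate is the polyp count divided by
the same initial number.  Minimum, half and maximum larval longevity are
the ages at which the survival curve first drops through 95 %, 50 % and
5 % — thresholds that bound the pelagic larval duration when, as here,
larvae stay competent until death.  Thresholds never crossed within the
experiment are right-censored at its duration (reported as "> D days").

Expected table columns: ``replicate, age_days, n_initial, n_healthy,
n_polyps`` (polyp counts cumulative; a ``treatment`` column is carried
through when present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (95.0, 50.0, 5.0)


class CrossingTime(NamedTuple):
    """Age (days) at a survival threshold crossing; censored means never crossed."""

    days: float
    censored: bool = False

    def __str__(self) -> str:
        return f"> {self.days:g} days" if self.censored else f"{self.days:g} days"


@dataclass
class LongevityMetrics:
    """Minimum / half / maximum larval longevity (95, 50 and 5 % survival)."""

    t_min: CrossingTime
    t_half: CrossingTime
    t_max: CrossingTime
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS


def _validate_counts(table: pd.DataFrame) -> None:
    for col in ("replicate", "age_days", "n_initial", "n_healthy"):
        if col not in table.columns:
            raise ValueError(f"count table lacks column {col!r}")
    if (table["n_initial"] <= 0).any():
        raise ValueError("n_initial must be positive")
    bad = table["n_healthy"] > table["n_initial"]
    if bad.any():
        age = table.loc[bad, "age_days"].iloc[0]
        raise ValueError(
            f"n_healthy exceeds n_initial (first at age {age}): invalid count table"
        )
    if (table["n_healthy"] < 0).any():
        raise ValueError("n_healthy must be non-negative")


def survival_rate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate, per-age survival rate (%).

    Adds a ``survival_pct`` column: 100 * n_healthy / n_initial.
    """
    _validate_counts(table)
    out = table.copy()
    out["survival_pct"] = 100.0 * out["n_healthy"] / out["n_initial"]
    return out


def metamorphosis_rate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate, per-age metamorphosis rates (%).

    ``metamorphosis_pct`` is the raw 100 * n_polyps / n_initial;
    ``cumulative_metamorphosis_pct`` is its running maximum within each
    replicate, because tiny fresh polyps are detected with delay and can
    be confused with damaged larvae, making raw polyp counts dip.
    """
    _validate_counts(table)
    if "n_polyps" not in table.columns:
        raise ValueError("count table lacks column 'n_polyps'")
    out = table.copy()
    out["metamorphosis_pct"] = 100.0 * out["n_polyps"] / out["n_initial"]
    out = out.sort_values(["replicate", "age_days"])
    out["cumulative_metamorphosis_pct"] = out.groupby("replicate")[
        "metamorphosis_pct"
    ].cummax()
    return out


def longevity_metrics(
    ages: Sequence[float],
    survival_pct: Sequence[float],
    experiment_duration: float | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    interpolate: bool = True,
) -> LongevityMetrics:
    """Longevity crossings of one replicate's survival curve.

    For each threshold the first downward crossing is located, by linear
    interpolation between the bracketing sampled ages (default) or at
    the first sampled age at or below the threshold
    (``interpolate=False``).  The curve is deliberately NOT monotonized
    first — counting noise can transiently raise counts, and only the
    first crossing defines longevity.  A threshold never reached is
    censored at ``experiment_duration`` (default: the last sampled age).
    """
    ages = np.asarray(ages, dtype=float)
    surv = np.asarray(survival_pct, dtype=float)
    if len(ages) == 0 or len(ages) != len(surv):
        raise ValueError("ages and survival values must align and be non-empty")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    if ages[0] != 0 or abs(surv[0] - 100.0) > 1e-9:
        raise ValueError("survival curve must start at 100% at age 0")
    if experiment_duration is None:
        experiment_duration = float(ages[-1])

    def crossing(threshold: float) -> CrossingTime:
        below = np.flatnonzero(surv < threshold)
        if len(below) == 0:
            # exact touch without dropping below still counts as reaching it
            touch = np.flatnonzero(surv == threshold)
            if len(touch) > 0:
                return CrossingTime(float(ages[touch[0]]), False)
            return CrossingTime(float(experiment_duration), True)
        i = below[0]
        if i == 0:  # cannot happen given surv[0] = 100 > threshold <= 95
            return CrossingTime(float(ages[0]), False)
        if surv[i - 1] == threshold:
            return CrossingTime(float(ages[i - 1]), False)
        if not interpolate:
            return CrossingTime(float(ages[i]), False)
        frac = (surv[i - 1] - threshold) / (surv[i - 1] - surv[i])
        return CrossingTime(float(ages[i - 1] + frac * (ages[i] - ages[i - 1])), False)

    t_min, t_half, t_max = (crossing(th) for th in thresholds)
    return LongevityMetrics(t_min=t_min, t_half=t_half, t_max=t_max,
                            thresholds=tuple(thresholds))


def longevity_by_replicate(
    table: pd.DataFrame,
    experiment_duration: float | None = None,
    interpolate: bool = True,
) -> dict[object, LongevityMetrics]:
    """Longevity metrics for every replicate of a count table."""
    rates = survival_rate(table).sort_values(["replicate", "age_days"])
    out = {}
    for rep, grp in rates.groupby("replicate"):
        out[rep] = longevity_metrics(
            grp["age_days"].to_numpy(),
            grp["survival_pct"].to_numpy(),
            experiment_duration=experiment_duration,
            interpolate=interpolate,
        )
    return out


class ReplicateSummary(NamedTuple):
    """Mean +/- SD of a longevity metric over non-censored replicates."""

    mean: float
    sd: float
    n: int
    n_censored: int
    censored_bound: float | None  # the bound when every replicate is censored

    @property
    def all_censored(self) -> bool:
        return self.n == 0


def aggregate_replicates(values: Sequence[CrossingTime | float]) -> ReplicateSummary:
    """Summarise one longevity metric across replicates.

    Censored replicates are excluded from the mean and SD and reported
    in ``n_censored``; when every replicate is censored the summary
    carries the largest censoring bound instead.  SD is NaN for a single
    usable replicate.
    """
    if len(values) == 0:
        raise ValueError("at least one replicate required")
    usable, bounds = [], []
    for v in values:
        if isinstance(v, CrossingTime):
            (bounds if v.censored else usable).append(v.days)
        else:
            usable.append(float(v))
    if not usable:
        return ReplicateSummary(float("nan"), float("nan"), 0, len(bounds),
                                max(bounds))
    arr = np.asarray(usable, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return ReplicateSummary(float(arr.mean()), sd, len(arr), len(bounds), None)
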