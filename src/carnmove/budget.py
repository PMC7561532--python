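"""Behavioral time budgets: proportion of steps and hours per day spent
in each movement behavior, per season and light period.

``EXAMPLE_BEHAVIOR_COUNTS`` is a bundled worked example: 2-h step counts
per behavior (encamped, foraging, traveling) summed over a population of
GPS-collared coyotes, by season and light period. Proportions within a
period are counts over the period total; hours per day multiply the
proportion by the period's mean daily duration.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "EXAMPLE_BEHAVIOR_COUNTS",
    "BEHAVIORS",
    "proportions_from_counts",
    "hours_per_day",
    "season_totals",
    "budget_table",
    "round_half_up",
]

BEHAVIORS = ("encamped", "foraging", "traveling")

#: (season, light) -> counts for (encamped, foraging, traveling)
EXAMPLE_BEHAVIOR_COUNTS = {
    ("snow_free", "diurnal"): (1032, 1165, 1065),
    ("snow_free", "crepuscular"): (658, 826, 1100),
    ("snow_free", "nocturnal"): (698, 596, 645),
    ("snow", "diurnal"): (274, 258, 333),
    ("snow", "crepuscular"): (295, 189, 214),
    ("snow", "nocturnal"): (251, 130, 125),
}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given precision (display rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def proportions_from_counts(counts) -> np.ndarray:
    """Per-behavior proportions within one (season, light) period."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty period")
    return counts / total


def hours_per_day(proportion: float, period_duration_h: float) -> float:
    """Hours per day in a behavior = proportion x mean period duration."""
    return proportion * period_duration_h


def season_totals(counts_by_period: dict) -> dict[str, np.ndarray]:
    """Pool counts over light periods within each season, then normalize."""
    seasons = sorted({season for season, _ in counts_by_period})
    out = {}
    for season in seasons:
        pooled = np.zeros(len(BEHAVIORS))
        for (s, _), counts in counts_by_period.items():
            if s == season:
                pooled += np.asarray(counts, dtype=float)
        out[season] = proportions_from_counts(pooled)
    return out


def budget_table(
    counts_by_period: dict | None = None,
    period_durations: dict | None = None,
) -> pd.DataFrame:
    """Assemble the full time-budget table.

    ``period_durations`` maps (season, light) — or just light — to mean
    daily duration in hours; omitted durations leave the hours column
    NaN. Proportions carry full precision plus a 2-dp display column.
    """
    counts_by_period = counts_by_period or EXAMPLE_BEHAVIOR_COUNTS
    rows = []
    for (season, light), counts in counts_by_period.items():
        props = proportions_from_counts(counts)
        if period_durations and (season, light) in period_durations:
            duration = period_durations[(season, light)]
        elif period_durations and light in period_durations:
            duration = period_durations[light]
        else:
            duration = np.nan
        for behavior, n, p in zip(BEHAVIORS, counts, props):
            rows.append(
                {
                    "season": season,
                    "light": light,
                    "behavior": behavior,
                    "n": int(n),
                    "proportion": p,
                    "proportion_2dp": round_half_up(p, 2),
                    "hours_per_day": hours_per_day(p, duration),
                }
            )
    return pd.DataFrame(rows)


def counts_from_decoded(decoded: pd.DataFrame) -> dict:
    """Tally decoded steps into (season, light) -> per-behavior counts.

    ``decoded`` needs season, light, and a 1-based ``state`` column whose
    labels map onto encamped/foraging/traveling in ascending order.
    """
    out = {}
    for (season, light), grp in decoded.groupby(["season", "light"], sort=True):
        counts = [int((grp["state"] == i + 1).sum()) for i in range(len(BEHAVIORS))]
        out[(str(season), str(light))] = tuple(counts)
    return out
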