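"""GPS track cleaning, rarefaction, burst extraction, and step geometry.

All coordinates are handled in a projected CRS in meters. Tables with
longitude/latitude columns are projected to UTM (zone chosen from the
data centroid) on read, since step lengths and home-range areas are
metric throughout the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Burst",
    "filter_speed",
    "rarefy",
    "extract_bursts",
    "steps_from_burst",
    "net_squared_displacement",
    "utm_project",
]


@dataclass
class Burst:
    """A regular-interval run of fixes for one animal.

    ``fixes`` has one row per nominal slot (columns: timestamp, x, y,
    source, missing); missing slots carry NaN coordinates until imputed.
    """

    animal_id: str
    fixes: pd.DataFrame
    interval_h: float = 2.0

    @property
    def n_slots(self) -> int:
        return len(self.fixes)

    @property
    def length_days(self) -> float:
        return (self.n_slots - 1) * self.interval_h / 24.0

    @property
    def n_missing(self) -> int:
        return int(self.fixes["missing"].sum())

    def validate(self, min_days: float = 8.0, max_consecutive_missing: int = 4) -> None:
        if self.length_days < min_days:
            raise ValueError(f"burst spans {self.length_days:.1f} d < {min_days} d")
        run = _max_missing_run(self.fixes["missing"].to_numpy())
        if run > max_consecutive_missing:
            raise ValueError(f"burst has a run of {run} missing slots")


def _max_missing_run(missing: np.ndarray) -> int:
    best = cur = 0
    for m in missing:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# speed filter


def _speeds_kmh(df: pd.DataFrame) -> np.ndarray:
    """Speed of each consecutive segment, km/h (length n-1)."""
    dt_h = df["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    dx = df["x"].diff().to_numpy()[1:]
    dy = df["y"].diff().to_numpy()[1:]
    dist_km = np.hypot(dx, dy) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt_h > 0, dist_km / dt_h, np.inf)


def _speed_between(df: pd.DataFrame, i: int, j: int) -> float:
    dt_h = (df["timestamp"].iloc[j] - df["timestamp"].iloc[i]).total_seconds() / 3600.0
    dist_km = float(np.hypot(df["x"].iloc[j] - df["x"].iloc[i], df["y"].iloc[j] - df["y"].iloc[i])) / 1000.0
    return dist_km / dt_h if dt_h > 0 else np.inf


def filter_speed(
    fixes: pd.DataFrame,
    flag_threshold: float = 10.0,
    remove_threshold: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop biologically impossible fixes; flag merely improbable ones.

    A fix is removed when a neighboring segment implies a travel speed
    above ``remove_threshold`` km/h; removal is iterated until no
    violation remains. Fixes on segments in (``flag_threshold``,
    ``remove_threshold``] km/h are retained but marked ``speed_flag``
    for review — a reproducible proxy for manual outlier inspection.

    Returns (kept fixes with a ``speed_flag`` column, removed fixes).
    """
    fixes = fixes.sort_values(["id", "timestamp"], kind="mergesort").reset_index(drop=True)
    kept_parts, removed_parts = [], []
    for animal, grp in fixes.groupby("id", sort=False):
        grp = grp.reset_index(drop=True)
        obs = grp[~grp["x"].isna()].reset_index(drop=True)
        if len(obs) < 2:
            warnings.warn(f"animal {animal}: fewer than 2 observed fixes; speed filter skipped")
            grp["speed_flag"] = False
            kept_parts.append(grp)
            continue
        df = obs
        removed_rows = []
        while True:
            v = _speeds_kmh(df)
            viol = v > remove_threshold
            if not viol.any():
                break
            # count of violating segments adjacent to each fix
            score = np.zeros(len(df), dtype=int)
            score[:-1] += viol
            score[1:] += viol
            if score.max() >= 2:
                drop_idx = list(np.nonzero(score >= 2)[0])
            else:
                # lone violating segment: drop the endpoint whose removal
                # leaves the slower bridge
                seg = int(np.argmax(viol))
                i, j = seg, seg + 1
                bridge_if_drop_i = _speed_between(df, i - 1, j) if i > 0 else 0.0
                bridge_if_drop_j = _speed_between(df, i, j + 1) if j < len(df) - 1 else 0.0
                drop_idx = [i if bridge_if_drop_i <= bridge_if_drop_j else j]
            removed_rows.append(df.iloc[drop_idx])
            df = df.drop(df.index[drop_idx]).reset_index(drop=True)
        v = _speeds_kmh(df)
        review = (v > flag_threshold) & (v <= remove_threshold)
        flag = np.zeros(len(df), dtype=bool)
        flag[:-1] |= review
        flag[1:] |= review
        df = df.copy()
        df["speed_flag"] = flag
        kept_parts.append(df)
        if removed_rows:
            removed_parts.append(pd.concat(removed_rows))
    kept = pd.concat(kept_parts).reset_index(drop=True)
    removed = (
        pd.concat(removed_parts).reset_index(drop=True)
        if removed_parts
        else fixes.iloc[0:0].copy()
    )
    return kept, removed


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(
    fixes: pd.DataFrame,
    target_interval_h: float = 2.0,
    rounding_grain_min: float = 15.0,
) -> pd.DataFrame:
    """Thin each animal's fixes to an approximate target interval.

    Greedy forward selection from the first fix: from the last kept fix,
    keep the earliest fix whose gap rounds (at the rounding grain) to
    exactly the target interval; when no such fix exists — a missed
    fix on a regular schedule — keep the earliest fix whose rounded gap
    is a whole multiple of the target, preserving slot alignment. The
    procedure is deterministic and idempotent.
    """
    if fixes.empty:
        return fixes.copy()
    grain_h = rounding_grain_min / 60.0
    parts = []
    for _, grp in fixes.groupby("id", sort=False):
        grp = grp.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        t = grp["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
        keep = [0]
        i = 0
        n = len(grp)
        while True:
            anchor = t[keep[-1]]
            exact = None
            multiple = None
            for j in range(keep[-1] + 1, n):
                gap = t[j] - anchor
                rounded = round(gap / grain_h) * grain_h
                if abs(rounded - target_interval_h) < 1e-9:
                    exact = j
                    break
                ratio = rounded / target_interval_h
                if multiple is None and rounded > 0 and abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
                    multiple = j
                if rounded > target_interval_h + grain_h and multiple is not None:
                    break
            nxt = exact if exact is not None else multiple
            if nxt is None:
                break
            keep.append(nxt)
        parts.append(grp.iloc[keep])
    return pd.concat(parts).reset_index(drop=True)


# ---------------------------------------------------------------------------
# burst extraction


def extract_bursts(
    fixes: pd.DataFrame,
    interval_h: float = 2.0,
    min_days: float = 8.0,
    max_consecutive_missing: int = 4,
) -> list[Burst]:
    """Cut rarefied fixes into analysis bursts.

    A burst is a maximal run of nominal ``interval_h`` slots with no more
    than ``max_consecutive_missing`` empty slots in a row; runs shorter
    than ``min_days`` are discarded. Leading/trailing missing slots are
    trimmed so bursts start and end on observed fixes.
    """
    bursts: list[Burst] = []
    for animal, grp in fixes.groupby("id", sort=False):
        grp = grp.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        obs = grp[~grp["missing"].astype(bool)].reset_index(drop=True)
        if obs.empty:
            continue
        t0 = obs["timestamp"].iloc[0]
        slot_of = ((obs["timestamp"] - t0).dt.total_seconds() / 3600.0 / interval_h).round().astype(int)
        n_slots = int(slot_of.iloc[-1]) + 1
        grid = pd.DataFrame(
            {
                "timestamp": t0 + pd.to_timedelta(np.arange(n_slots) * interval_h, unit="h"),
                "x": np.nan,
                "y": np.nan,
                "source": "observed",
                "missing": True,
            }
        )
        grid.loc[slot_of.to_numpy(), ["x", "y"]] = obs[["x", "y"]].to_numpy()
        grid.loc[slot_of.to_numpy(), "source"] = obs["source"].to_numpy()
        grid.loc[slot_of.to_numpy(), "missing"] = False

        missing = grid["missing"].to_numpy()
        # split wherever a run of > max_consecutive_missing occurs
        segments = []
        start = 0
        run = 0
        for i, m in enumerate(missing):
            if m:
                run += 1
                if run == max_consecutive_missing + 1:
                    segments.append((start, i - max_consecutive_missing))
                    start = i + 1
            else:
                if run > max_consecutive_missing:
                    start = i
                run = 0
        segments.append((start, len(missing)))
        for lo, hi in segments:
            seg = grid.iloc[lo:hi]
            present = ~seg["missing"].to_numpy()
            if not present.any():
                continue
            first = int(np.argmax(present))
            last = len(present) - 1 - int(np.argmax(present[::-1]))
            seg = seg.iloc[first : last + 1].reset_index(drop=True)
            burst = Burst(animal_id=str(animal), fixes=seg, interval_h=interval_h)
            if burst.length_days >= min_days:
                bursts.append(burst)
    return bursts


# ---------------------------------------------------------------------------
# step geometry


def steps_from_burst(burst: Burst) -> pd.DataFrame:
    """Step lengths, bearings, and turning angles along a burst.

    A step joins consecutive present slots. The turning angle is the
    signed bearing change from the previous step, wrapped to (-pi, pi];
    it is undefined (NaN) for the first step, after any gap, and after a
    zero-length step (bearing undefined). ``imputed`` marks steps that
    touch an imputed fix.
    """
    df = burst.fixes
    present = ~df["missing"].to_numpy()
    idx = np.nonzero(present)[0]
    rows = []
    prev_bearing = np.nan
    prev_end = -10
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a != 1:
            prev_bearing = np.nan  # gap: bearing chain broken
            prev_end = b
            continue
        dx = df["x"].iloc[b] - df["x"].iloc[a]
        dy = df["y"].iloc[b] - df["y"].iloc[a]
        length = float(np.hypot(dx, dy))
        bearing = float(np.arctan2(dy, dx)) if length > 0 else np.nan
        if np.isnan(prev_bearing) or a != prev_end:
            turn = np.nan
        else:
            turn = _wrap(bearing - prev_bearing) if not np.isnan(bearing) else np.nan
        rows.append(
            {
                "animal_id": burst.animal_id,
                "t_start": df["timestamp"].iloc[a],
                "t_end": df["timestamp"].iloc[b],
                "x_start": df["x"].iloc[a],
                "y_start": df["y"].iloc[a],
                "x_end": df["x"].iloc[b],
                "y_end": df["y"].iloc[b],
                "length": length,
                "bearing": bearing,
                "turn_angle": turn,
                "imputed": df["source"].iloc[a] == "imputed" or df["source"].iloc[b] == "imputed",
            }
        )
        prev_bearing = bearing
        prev_end = b
    return pd.DataFrame(rows)


def _wrap(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    return np.pi - (np.pi - theta) % (2.0 * np.pi)


def net_squared_displacement(fixes: pd.DataFrame) -> pd.DataFrame:
    """Squared displacement (m^2) of each fix from the first observed fix."""
    obs = fixes[~fixes["x"].isna()].reset_index(drop=True)
    if obs.empty:
        raise ValueError("no observed fixes")
    x0, y0 = obs["x"].iloc[0], obs["y"].iloc[0]
    nsd = (obs["x"] - x0) ** 2 + (obs["y"] - y0) ** 2
    return pd.DataFrame({"timestamp": obs["timestamp"], "nsd": nsd})


# ---------------------------------------------------------------------------
# projection (lon/lat -> UTM)


def utm_project(lon, lat, zone: int | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    """Project WGS84 lon/lat to UTM meters (standard series expansion).

    The zone defaults to that of the centroid so a whole track shares one
    zone. Returns (easting, northing, zone). Accuracy ~1 mm within a zone.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if zone is None:
        zone = int((np.mean(lon) + 180.0) // 6.0) + 1
    lon0 = np.radians(-183.0 + 6.0 * zone)
    a = 6378137.0
    f = 1.0 / 298.257223563
    e2 = f * (2 - f)
    k0 = 0.9996
    phi = np.radians(lat)
    lam = np.radians(lon) - lon0
    N = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = e2 / (1 - e2) * np.cos(phi) ** 2
    A = lam * np.cos(phi)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    easting = k0 * N * (
        A + (1 - T + C) * A**3 / 6 + (5 - 18 * T + T**2 + 72 * C - 58 * e2 / (1 - e2)) * A**5 / 120
    ) + 500000.0
    northing = k0 * (
        M
        + N
        * np.tan(phi)
        * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * e2 / (1 - e2)) * A**6 / 720
        )
    )
    northing = np.where(lat < 0, northing + 10000000.0, northing)
    return easting, northing, zone
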