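"""Climatic season and diel light condition for each fix.

Season follows an elevation-dependent calendar rule for seasonal snow
cover: snow from December 10 to April 15 below 300 m and from
November 20 to May 1 at or above 300 m (windows inclusive, wrapping the
new year). Light condition is derived from the sun's position: *day*
runs from 2 h after sunrise to 2 h before sunset, *night* from 2 h
after sunset to 2 h before sunrise, and the two 4-h windows centered on
sunrise and sunset are *crepuscular* (closed, so boundary instants are
crepuscular). Sunrise/sunset use the standard -0.833 deg solar
altitude, computed from the NOAA solar-position equations.
"""

from __future__ import annotations

import warnings
from datetime import date as date_cls
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = [
    "season",
    "solar_events",
    "light_condition",
    "assign_temporal",
    "light_period_durations",
    "SNOW",
    "SNOW_FREE",
    "DIURNAL",
    "CREPUSCULAR",
    "NOCTURNAL",
]

SNOW = "snow"
SNOW_FREE = "snow_free"
DIURNAL = "diurnal"
CREPUSCULAR = "crepuscular"
NOCTURNAL = "nocturnal"

LOW_SNOW_WINDOW = ((12, 10), (4, 15))
HIGH_SNOW_WINDOW = ((11, 20), (5, 1))
ELEVATION_SPLIT_M = 300.0
CREP_HALF_WIDTH_H = 2.0


def _in_window(month: int, day: int, window) -> bool:
    (m1, d1), (m2, d2) = window
    key, start, end = (month, day), (m1, d1), (m2, d2)
    if start <= end:
        return start <= key <= end
    return key >= start or key <= end


def season(when, elevation_m: float, thresholds=None) -> str:
    """Snow / snow-free season of a fix given its DEM elevation.

    ``thresholds`` may override ``(low_window, high_window, split_m)``.
    """
    if elevation_m is None or (isinstance(elevation_m, float) and np.isnan(elevation_m)):
        raise ValueError(f"missing DEM elevation for fix at {when}")
    low_win, high_win, split = thresholds or (LOW_SNOW_WINDOW, HIGH_SNOW_WINDOW, ELEVATION_SPLIT_M)
    when = pd.Timestamp(when)
    win = low_win if elevation_m < split else high_win
    return SNOW if _in_window(when.month, when.day, win) else SNOW_FREE


# ---------------------------------------------------------------------------
# solar position (NOAA general solar-position equations)


def _solar_parameters(day_of_year: int, hours_utc: float, leap: bool):
    year_len = 366.0 if leap else 365.0
    g = 2.0 * np.pi / year_len * (day_of_year - 1 + (hours_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return eqtime, decl


def solar_events(lat: float, lon: float, date) -> tuple[datetime, datetime]:
    """UTC sunrise and sunset for a date and location (zenith 90.833 deg).

    Raises for latitudes poleward of the polar circles, where the sun
    may not rise or set.
    """
    if abs(lat) >= 66.5:
        raise ValueError(f"latitude {lat} is polar; sunrise/sunset undefined on some dates")
    if isinstance(date, (datetime, pd.Timestamp)):
        date = pd.Timestamp(date).date()
    assert isinstance(date, date_cls)
    doy = date.timetuple().tm_yday
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    phi = np.radians(lat)
    zenith = np.radians(90.833)

    def event_minutes(rise: bool) -> float:
        # one fixed-point refinement of the fractional-year evaluation time
        minutes = 720.0
        for _ in range(3):
            eqtime, decl = _solar_parameters(doy, minutes / 60.0, leap)
            cos_ha = np.cos(zenith) / (np.cos(phi) * np.cos(decl)) - np.tan(phi) * np.tan(decl)
            cos_ha = np.clip(cos_ha, -1.0, 1.0)
            ha = np.degrees(np.arccos(cos_ha))
            if not rise:
                ha = -ha
            minutes = 720.0 - 4.0 * (lon + ha) - eqtime
        return float(minutes)

    base = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    sunrise = base + timedelta(minutes=event_minutes(rise=True))
    sunset = base + timedelta(minutes=event_minutes(rise=False))
    return sunrise, sunset


def light_condition(when, sunrise: datetime, sunset: datetime) -> str:
    """Classify an instant against one day's sunrise/sunset pair.

    Instants within 2 h of either event (inclusive) are crepuscular;
    between the crepuscular windows and bounded by them, daytime lies
    after sunrise and nighttime after sunset.
    """
    when = pd.Timestamp(when)
    if when.tzinfo is None:
        when = when.tz_localize("UTC")
    sunrise = pd.Timestamp(sunrise)
    sunset = pd.Timestamp(sunset)
    half = pd.Timedelta(hours=CREP_HALF_WIDTH_H)
    if abs(when - sunrise) <= half or abs(when - sunset) <= half:
        return CREPUSCULAR
    if sunrise + half < when < sunset - half:
        return DIURNAL
    return NOCTURNAL


def _classify_with_neighbors(when: pd.Timestamp, lat: float, lon: float) -> str:
    """Light class using events of the surrounding days (UTC-wrap safe)."""
    half = pd.Timedelta(hours=CREP_HALF_WIDTH_H)
    events = []
    for shift in (-1, 0, 1):
        d = (when + pd.Timedelta(days=shift)).date()
        events.append(solar_events(lat, lon, d))
    for sr, ss in events:
        if abs(when - pd.Timestamp(sr)) <= half or abs(when - pd.Timestamp(ss)) <= half:
            return CREPUSCULAR
    for sr, ss in events:
        if pd.Timestamp(sr) + half < when < pd.Timestamp(ss) - half:
            return DIURNAL
    return NOCTURNAL


def assign_temporal(fixes: pd.DataFrame, lat: float, lon: float, elevations) -> pd.DataFrame:
    """Add ``season`` and ``light`` columns to a track table.

    ``elevations`` gives each fix's DEM elevation (m), aligned with the
    rows of ``fixes``.
    """
    fixes = fixes.reset_index(drop=True).copy()
    elevations = np.asarray(elevations, dtype=float)
    seasons = [
        season(t, e) for t, e in zip(fixes["timestamp"], elevations)
    ]
    lights = []
    for t in fixes["timestamp"]:
        t = pd.Timestamp(t)
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        lights.append(_classify_with_neighbors(t, lat, lon))
    fixes["season"] = seasons
    fixes["light"] = lights
    return fixes


def light_period_durations(lat: float, lon: float, date) -> dict[str, float]:
    """Hours of diurnal / crepuscular / nocturnal time on one date.

    The two crepuscular windows total 8 h unless they overlap (very long
    or very short days), in which case the overlap is counted once and a
    warning is emitted; the three durations always sum to 24 h.
    """
    sunrise, sunset = solar_events(lat, lon, date)
    day_h = (sunset - sunrise).total_seconds() / 3600.0
    crep = 4.0 * CREP_HALF_WIDTH_H
    # windows overlap when the two events are closer (mod 24 h) than 4 h
    gap = min(abs(day_h), 24.0 - abs(day_h))
    if gap < 2.0 * CREP_HALF_WIDTH_H:
        overlap = 2.0 * CREP_HALF_WIDTH_H - gap
        warnings.warn("crepuscular windows overlap; clamping")
        crep -= overlap
    diurnal = max(0.0, day_h - 2.0 * CREP_HALF_WIDTH_H)
    nocturnal = max(0.0, 24.0 - diurnal - crep)
    return {DIURNAL: diurnal, CREPUSCULAR: crep, NOCTURNAL: nocturnal}
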