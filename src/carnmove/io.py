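"""Track table I/O.

A track table is a pandas DataFrame with one row per fix:

    id        animal identifier (str)
    timestamp UTC datetime (ISO-8601 in CSV)
    x, y      projected coordinates in meters (NaN when missing)
    source    "observed" or "imputed"
    missing   bool

Extra columns (true_state, season, light, state, ...) pass through
untouched so every pipeline stage reads and writes the same format.
"""

from __future__ import annotations

import pandas as pd

TRACK_COLUMNS = ["id", "timestamp", "x", "y", "source", "missing"]


def ensure_track_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw relocation table into track-frame form."""
    df = df.copy()
    if "id" not in df or "timestamp" not in df:
        raise ValueError("track table needs 'id' and 'timestamp' columns")
    df["id"] = df["id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "source" not in df:
        df["source"] = "observed"
    if "missing" not in df:
        df["missing"] = df["x"].isna() | df["y"].isna()
    df = df.sort_values(["id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df


def read_tracks(path) -> pd.DataFrame:
    return ensure_track_frame(pd.read_csv(path))


def write_tracks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)
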