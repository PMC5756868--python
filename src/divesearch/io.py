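"""File I/O: track / dive / depth CSV dialects and key-value config files.

Track CSV: bird_id, timestamp (ISO-8601 UTC), lon, lat.
Dive CSV:  bird_id, timestamp[, max_depth_m].
Depth CSV: bird_id, timestamp, depth_m.
Annotated output CSV: bird_id, trip_id, timestamp, x, y, state, method, valid.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _parse_times(series: pd.Series, path, col: str) -> np.ndarray:
    parsed = pd.to_datetime(series, utc=True, errors="coerce", format="mixed")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: unparseable {col} at data row {row}: {series.iloc[row]!r}")
    return parsed.astype("int64").to_numpy() / 1e9


def read_tracks(
    path,
    bird_col: str = "bird_id",
    time_col: str = "timestamp",
    lon_col: str = "lon",
    lat_col: str = "lat",
) -> pd.DataFrame:
    """Read raw GPS fixes, sorted by (bird, time), duplicates collapsed.

    Duplicate (bird, timestamp) rows keep the first occurrence; the number
    dropped is logged. Unparseable timestamps or coordinates raise with the
    offending row named.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty track file")
    for c in (bird_col, time_col, lon_col, lat_col):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    out = pd.DataFrame(
        {
            "bird_id": df[bird_col].astype(str),
            "t": _parse_times(df[time_col], path, time_col),
        }
    )
    for name, col in (("lon", lon_col), ("lat", lat_col)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: unparseable {col} at data row {row}")
        out[name] = vals.to_numpy(float)
    if out[["lon", "lat"]].isna().any().any():
        raise ValueError(f"{path}: missing coordinates")
    out = out.sort_values(["bird_id", "t"], kind="stable")
    n0 = len(out)
    out = out.drop_duplicates(subset=["bird_id", "t"], keep="first").reset_index(drop=True)
    if len(out) < n0:
        log.warning("%s: dropped %d duplicate-timestamp fixes", path, n0 - len(out))
    return out


def read_dives(path, bird_col: str = "bird_id", time_col: str = "timestamp") -> pd.DataFrame:
    """Read dive-onset events: one row per dive, columns bird_id, t_onset."""
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "bird_id": df[bird_col].astype(str),
            "t_onset": _parse_times(df[time_col], path, time_col),
        }
    ).sort_values(["bird_id", "t_onset"], kind="stable", ignore_index=True)


def read_depth(path) -> pd.DataFrame:
    """Read a raw depth series: bird_id, timestamp, depth_m."""
    df = pd.read_csv(path)
    out = pd.DataFrame(
        {
            "bird_id": df["bird_id"].astype(str),
            "t": _parse_times(df["timestamp"], path, "timestamp"),
            "depth": pd.to_numeric(df["depth_m"]).to_numpy(float),
        }
    )
    if (out["depth"] < 0).any():
        raise ValueError(f"{path}: negative depths")
    return out.sort_values(["bird_id", "t"], kind="stable", ignore_index=True)


def _iso(t: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.round(np.asarray(t)).astype("int64"), unit="s", utc=True).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )


def write_tracks(fixes: pd.DataFrame, path) -> None:
    pd.DataFrame(
        {
            "bird_id": fixes["bird_id"],
            "timestamp": _iso(fixes["t"].to_numpy()),
            "lon": fixes["lon"],
            "lat": fixes["lat"],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_dives(dives: pd.DataFrame, path) -> None:
    pd.DataFrame(
        {"bird_id": dives["bird_id"], "timestamp": _iso(dives["t_onset"].to_numpy())}
    ).to_csv(path, index=False)


def write_annotations(traj: pd.DataFrame, states: np.ndarray, method: str, path) -> None:
    """Write an annotated trajectory CSV (one method)."""
    pd.DataFrame(
        {
            "bird_id": traj["bird_id"],
            "trip_id": traj.get("trip_id", ""),
            "timestamp": _iso(traj["t"].to_numpy()),
            "x": traj["x"].round(2),
            "y": traj["y"].round(2),
            "state": states,
            "method": method,
            "valid": traj.get("valid", True),
        }
    ).to_csv(path, index=False)


def read_config(path) -> dict:
    """Plain key = value config file; numbers parsed, '#' comments allowed."""
    cfg: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            cfg[key] = int(val)
        except ValueError:
            try:
                cfg[key] = float(val)
            except ValueError:
                cfg[key] = val
    return cfg
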