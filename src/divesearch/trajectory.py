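"""Trajectory processing: projection, regularization, metrics, filters.

A trajectory is a pandas DataFrame, one row per fix, sorted by
(bird_id, t), with at least:

    bird_id   str      animal identifier
    t         float    UTC unix time, seconds
    x, y      float    planar coordinates, meters (UTM)
    lon, lat  float    geographic coordinates, degrees

and, once derived, per-fix movement metrics

    step_len   m       distance fix i -> i+1
    speed      m/s     backward speed, ||p_i - p_{i-1}|| / dt
    accel      m/s^2   change in backward speed between consecutive fixes
    turn       rad     signed heading change at i, in (-pi, pi], CCW positive
    tortuosity -       straight-line over along-track distance, 9-fix window
    dist_colony m
    segment    int     contiguous run between temporal gaps
    trip_id    str     foraging trip (split at colony visits)
    valid      bool    passes colony-distance and daylight filters

Metrics that need fixes outside the track window are NaN ("undefined"),
never zero-filled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import geo

log = logging.getLogger(__name__)

#: seconds; gaps longer than this are never interpolated across
DEFAULT_MAX_GAP_S = 1800.0


def project_tracks(fixes: pd.DataFrame, zone: int = 30) -> pd.DataFrame:
    """Add planar UTM coordinates (x, y) to raw lon/lat fixes."""
    out = fixes.copy()
    bad = (out["lat"].abs() > 90) | (out["lon"].abs() > 180)
    if bad.any():
        raise ValueError(f"{bad.sum()} fixes with out-of-range lon/lat")
    lon0 = geo.utm_zone_lon0(zone)
    if (np.abs(out["lon"] - lon0) > 12).any():
        log.warning("some fixes are far outside UTM zone %d validity", zone)
    out["x"], out["y"] = geo.project(out["lon"].to_numpy(), out["lat"].to_numpy(), zone)
    out.attrs["utm_zone"] = zone
    return out


def interpolate_time(
    traj: pd.DataFrame,
    interval_s: float = 120.0,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    zone: int | None = None,
) -> pd.DataFrame:
    """Resample each bird's track to a fixed time step by linear interpolation.

    Positions are interpolated in planar coordinates between bracketing raw
    fixes; gaps longer than ``max_gap_s`` split the track into separate
    segments and no synthetic fixes are placed inside them. Lon/lat of
    interpolated fixes are recovered by inverse projection.
    """
    zone = zone if zone is not None else traj.attrs.get("utm_zone", 30)
    pieces = []
    for bird, g in traj.groupby("bird_id", sort=False):
        g = g.sort_values("t")
        if len(g) < 2:
            raise ValueError(f"bird {bird!r}: need >= 2 fixes to interpolate")
        t = g["t"].to_numpy(dtype=float)
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        gap_starts = np.flatnonzero(np.diff(t) > max_gap_s)
        bounds = np.concatenate(([0], gap_starts + 1, [len(t)]))
        for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            if b - a < 2:
                continue
            ts, xs, ys = t[a:b], x[a:b], y[a:b]
            n_out = int(np.floor((ts[-1] - ts[0]) / interval_s)) + 1
            tq = ts[0] + interval_s * np.arange(n_out)
            pieces.append(
                pd.DataFrame(
                    {
                        "bird_id": bird,
                        "segment": seg,
                        "t": tq,
                        "x": np.interp(tq, ts, xs),
                        "y": np.interp(tq, ts, ys),
                    }
                )
            )
    if not pieces:
        raise ValueError("no segment with >= 2 fixes")
    out = pd.concat(pieces, ignore_index=True)
    out["lon"], out["lat"] = geo.unproject(out["x"].to_numpy(), out["y"].to_numpy(), zone)
    out.attrs["utm_zone"] = zone
    out.attrs["interval_s"] = interval_s
    return out


def rediscretize_space(traj: pd.DataFrame, step_m: float = 500.0) -> pd.DataFrame:
    """Resample each bird/segment path to equal along-track spacing.

    Output points sit exactly ``step_m`` apart along the piecewise-linear
    input path; timestamps are interpolated proportionally along each input
    segment. Used by first-passage-time analysis, which needs spacing in
    space rather than time.
    """
    if step_m <= 0:
        raise ValueError("step_m must be positive")
    group_cols = ["bird_id", "segment"] if "segment" in traj.columns else ["bird_id"]
    pieces = []
    for key, g in traj.groupby(group_cols, sort=False):
        g = g.sort_values("t")
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        t = g["t"].to_numpy(dtype=float)
        seg_len = np.hypot(np.diff(x), np.diff(y))
        s = np.concatenate(([0.0], np.cumsum(seg_len)))
        total = s[-1]
        if total < step_m:
            log.warning("path shorter than step (%.1f m < %.1f m): single point", total, step_m)
            sq = np.array([0.0])
        else:
            sq = np.arange(0.0, total + 1e-9, step_m)
        key = key if isinstance(key, tuple) else (key,)
        df = pd.DataFrame(
            {
                "x": np.interp(sq, s, x),
                "y": np.interp(sq, s, y),
                "t": np.interp(sq, s, t),
            }
        )
        for col, val in zip(group_cols, key):
            df[col] = val
        pieces.append(df)
    out = pd.concat(pieces, ignore_index=True)[group_cols + ["t", "x", "y"]]
    out.attrs["step_m"] = step_m
    out.attrs.update({k: v for k, v in traj.attrs.items() if k != "interval_s"})
    return out


def _metrics_one(x: np.ndarray, y: np.ndarray, t: np.ndarray, w: int):
    n = len(x)
    nan = np.full(n, np.nan)
    step = nan.copy()
    dx, dy = np.diff(x), np.diff(y)
    d = np.hypot(dx, dy)
    step[:-1] = d

    speed = nan.copy()
    dt = np.diff(t)
    speed[1:] = d / dt

    accel = nan.copy()
    accel[1:] = np.diff(np.concatenate(([np.nan], speed[1:]))) / dt
    # accel_i defined for i >= 2 (needs speed at i and i-1)
    accel[:2] = np.nan

    turn = nan.copy()
    heading = np.arctan2(dy, dx)
    if n >= 3:
        dh = np.diff(heading)
        dh = np.mod(dh + np.pi, 2 * np.pi) - np.pi
        dh[dh == -np.pi] = np.pi  # signed angle in (-pi, pi]
        turn[1:-1] = dh
        # turn undefined where either adjacent step has zero length
        zero_in = d[:-1] == 0
        zero_out = d[1:] == 0
        turn[1:-1][zero_in | zero_out] = np.nan

    tort = nan.copy()
    if n >= 2 * w + 1:
        csum = np.concatenate(([0.0], np.cumsum(d)))
        for i in range(w, n - w):
            along = csum[i + w] - csum[i - w]
            chord = np.hypot(x[i + w] - x[i - w], y[i + w] - y[i - w])
            tort[i] = chord / along if along > 0 else np.nan
    return step, speed, accel, turn, tort


def compute_metrics(traj: pd.DataFrame, tort_window: int = 4) -> pd.DataFrame:
    """Populate per-fix movement metrics, per bird and temporal segment."""
    group_cols = ["bird_id", "segment"] if "segment" in traj.columns else ["bird_id"]
    out = traj.sort_values(group_cols + ["t"]).reset_index(drop=True).copy()
    for col in ("step_len", "speed", "accel", "turn", "tortuosity"):
        out[col] = np.nan
    for _, idx in out.groupby(group_cols, sort=False).indices.items():
        idx = np.sort(idx)
        g = out.iloc[idx]
        res = _metrics_one(
            g["x"].to_numpy(float), g["y"].to_numpy(float), g["t"].to_numpy(float), tort_window
        )
        for col, vals in zip(("step_len", "speed", "accel", "turn", "tortuosity"), res):
            out.loc[out.index[idx], col] = vals
    out.attrs.update(traj.attrs)
    return out


def apply_filters(
    traj: pd.DataFrame,
    colony_lonlat: tuple[float, float],
    radius_m: float = 5000.0,
    twilight_deg: float = -6.0,
    zone: int | None = None,
) -> pd.DataFrame:
    """Mark fixes near the colony or at night as invalid.

    Invalid fixes stay in the frame (they still break search chains) but are
    excluded from classification and from every rate denominator. Night is
    solar elevation below ``twilight_deg`` (default civil twilight, -6 deg).
    """
    if colony_lonlat is None:
        raise ValueError("colony coordinates required")
    zone = zone if zone is not None else traj.attrs.get("utm_zone", 30)
    out = traj.copy()
    cx, cy = geo.project(colony_lonlat[0], colony_lonlat[1], zone)
    out["dist_colony"] = np.hypot(out["x"] - cx, out["y"] - cy)
    elev = geo.solar_elevation(
        out["t"].to_numpy(float), out["lon"].to_numpy(float), out["lat"].to_numpy(float)
    )
    out["valid"] = (out["dist_colony"] >= radius_m) & (elev >= twilight_deg)
    out.attrs.update(traj.attrs)
    out.attrs["colony_lonlat"] = tuple(colony_lonlat)
    return out


def assign_trips(traj: pd.DataFrame, radius_m: float = 5000.0, min_run: int = 3) -> pd.DataFrame:
    """Split each bird's track into trips at colony visits.

    A visit is a run of at least ``min_run`` consecutive fixes within the
    colony radius; trips are the stretches between visits. Temporal-gap
    segments also bound trips. Search chains never span trip boundaries.
    """
    if "dist_colony" not in traj.columns:
        raise ValueError("run apply_filters first (dist_colony missing)")
    out = traj.copy()
    trip_ids = np.empty(len(out), dtype=object)
    group_cols = ["bird_id", "segment"] if "segment" in out.columns else ["bird_id"]
    for key, idx in out.groupby(group_cols, sort=False).indices.items():
        idx = np.sort(idx)
        near = (out["dist_colony"].to_numpy(float)[idx] < radius_m).astype(int)
        # label runs of >= min_run near-colony fixes as visits
        visit = np.zeros(len(idx), dtype=bool)
        i = 0
        while i < len(idx):
            if near[i]:
                j = i
                while j < len(idx) and near[j]:
                    j += 1
                if j - i >= min_run:
                    visit[i:j] = True
                i = j
            else:
                i += 1
        trip_no = np.cumsum(np.concatenate(([0], np.diff(visit.astype(int)) == -1)))
        key = key if isinstance(key, tuple) else (key,)
        base = "_".join(str(k) for k in key)
        for k, (pos, vis, tn) in enumerate(zip(idx, visit, trip_no)):
            trip_ids[pos] = f"{base}_v" if vis else f"{base}_trip{tn}"
    out["trip_id"] = trip_ids
    out.attrs.update(traj.attrs)
    return out


def preprocess(
    fixes: pd.DataFrame,
    colony_lonlat: tuple[float, float],
    zone: int = 30,
    interval_s: float = 120.0,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    colony_radius_m: float = 5000.0,
    twilight_deg: float = -6.0,
    tort_window: int = 4,
) -> pd.DataFrame:
    """Full standard pipeline: project, regularize, metrics, filters, trips."""
    traj = project_tracks(fixes, zone)
    traj = interpolate_time(traj, interval_s, max_gap_s, zone)
    traj = compute_metrics(traj, tort_window)
    traj = apply_filters(traj, colony_lonlat, colony_radius_m, twilight_deg, zone)
    return assign_trips(traj, colony_radius_m)
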