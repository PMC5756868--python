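"""First passage time (FPT) analysis and classification.

FPT at a path point is the time the animal takes to cross a circle of
radius r centered there, measured from the last backward crossing to the
first forward crossing; the variance of log FPT across the track peaks at
the spatial scale of area-restricted search. Computed on the spatially
rediscretized track (equal along-path spacing) so that it reflects path
geometry rather than fix rate.

Classification: per bird, the radius r* maximizing S(r) = var(ln FPT) is
selected over a radius ladder (default 50 m to 12 km); the highest-FPT
sixth of points at r* seed a search area formed by the union of circles of
radius r* around them, and every valid temporal fix inside that union is
labeled search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import TrajectoryAnnotator, check_trajectory, valid_mask
from .trajectory import rediscretize_space

log = logging.getLogger(__name__)


def default_radii() -> np.ndarray:
    """Radius ladder from 50 m to 12,000 m (500-m rungs plus the 50-m toe)."""
    return np.concatenate(([50.0], np.arange(500.0, 12000.1, 500.0)))


def _segment_crossing(x, y, t, cx, cy, j, k, r):
    """Exact crossing time of circle (c, r) on the linear segment j -> k.

    The segment is entered inside the circle (|p_j - c| < r <= |p_k - c|);
    positions are linear in time along the segment, so the crossing solves
    a quadratic in the interpolation parameter.
    """
    px, py = x[j] - cx, y[j] - cy
    vx, vy = x[k] - x[j], y[k] - y[j]
    a = vx * vx + vy * vy
    b = 2 * (px * vx + py * vy)
    c = px * px + py * py - r * r
    disc = max(b * b - 4 * a * c, 0.0)
    s = (-b + np.sqrt(disc)) / (2 * a)
    return t[j] + s * (t[k] - t[j])


def _fpt_one(x: np.ndarray, y: np.ndarray, t: np.ndarray, r: float) -> np.ndarray:
    n = len(x)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    dist = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    for i in range(n):
        far = dist[i] >= r
        fwd = np.flatnonzero(far[i + 1:])
        back = np.flatnonzero(far[:i][::-1])
        if len(fwd) == 0 or len(back) == 0:
            continue  # circle never crossed before trip end/start
        kf = i + 1 + fwd[0]  # first point at/beyond r going forward
        kb = i - 1 - back[0]  # first point at/beyond r going backward
        t_fwd = _segment_crossing(x, y, t, x[i], y[i], kf - 1, kf, r)
        t_back = _segment_crossing(x, y, t, x[i], y[i], kb + 1, kb, r)
        out[i] = t_fwd - t_back
    return out


def fpt_values(traj_spatial: pd.DataFrame, r: float) -> np.ndarray:
    """Per-point first passage times (s) at radius ``r``.

    ``traj_spatial`` is a spatially rediscretized trajectory; points whose
    circle is not crossed before the start/end of their segment are NaN.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    group_cols = [c for c in ("bird_id", "segment") if c in traj_spatial.columns]
    out = np.full(len(traj_spatial), np.nan)
    for _, idx in traj_spatial.groupby(group_cols, sort=False).indices.items():
        idx = np.sort(idx)
        g = traj_spatial.iloc[idx]
        out[idx] = _fpt_one(
            g["x"].to_numpy(float), g["y"].to_numpy(float), g["t"].to_numpy(float), r
        )
    return out


@dataclass
class FptProfile:
    """Variance-of-log-FPT profile for one bird."""

    radii: np.ndarray
    s_var: np.ndarray  # S(r) = var(ln FPT); NaN where all FPT undefined
    r_star: float
    fpt_at_r_star: np.ndarray  # per spatial point
    extras: dict = field(default_factory=dict)


def fpt_select_radius(traj_spatial: pd.DataFrame, radii=None) -> FptProfile:
    """Compute S(r) over the radius ladder and pick r* = argmax S(r).

    One bird at a time (callers loop over birds; pooling birds or colonies
    is never done). Radii where FPT is defined nowhere are dropped with a
    warning; an all-flat profile (straight track) emits a warning and
    returns the smallest radius.
    """
    radii = default_radii() if radii is None else np.asarray(radii, float)
    if len(radii) < 2:
        raise ValueError("need at least 2 radii")
    s = np.full(len(radii), np.nan)
    cache = {}
    for k, r in enumerate(radii):
        vals = fpt_values(traj_spatial, r)
        cache[r] = vals
        good = np.isfinite(vals) & (vals > 0)
        if good.sum() < 2:
            log.warning("radius %.0f m: FPT undefined everywhere; dropped", r)
            continue
        s[k] = np.var(np.log(vals[good]))
    if not np.isfinite(s).any():
        raise ValueError("FPT undefined at every radius")
    if np.nanmax(s) < 1e-12:
        log.warning("log-FPT variance ~0 at all radii (straight track?); no ARS scale")
    k_star = int(np.nanargmax(s))
    r_star = float(radii[k_star])
    return FptProfile(radii=radii, s_var=s, r_star=r_star, fpt_at_r_star=cache[r_star])


def fpt_classify(
    traj: pd.DataFrame,
    traj_spatial: pd.DataFrame,
    profile: FptProfile,
    sextile: float = 1 / 6,
) -> np.ndarray:
    """Label temporal fixes by membership in the amalgamated search area.

    Seeds are the ceil(n/6) defined spatial points with the largest FPT(r*)
    (boundary ties broken toward the earlier point); the search area is the
    union of circles of radius r* around the seeds.
    """
    vals = profile.fpt_at_r_star
    defined = np.flatnonzero(np.isfinite(vals))
    n_seed = int(np.ceil(len(defined) * sextile))
    # sort by (-FPT, index): equal FPT -> earlier point wins
    order = sorted(defined, key=lambda i: (-vals[i], i))
    seeds = np.array(order[:n_seed], dtype=int)
    sx = traj_spatial["x"].to_numpy(float)[seeds]
    sy = traj_spatial["y"].to_numpy(float)[seeds]

    states = np.full(len(traj), "excluded", dtype=object)
    ok = valid_mask(traj)
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    inside = np.zeros(len(traj), dtype=bool)
    if len(seeds):
        for a in range(0, len(traj), 2048):
            b = min(a + 2048, len(traj))
            d2 = (x[a:b, None] - sx[None, :]) ** 2 + (y[a:b, None] - sy[None, :]) ** 2
            inside[a:b] = (d2 <= profile.r_star**2).any(axis=1)
    states[ok] = np.where(inside[ok], "search", "travel")
    return states


class FPTAnnotator(TrajectoryAnnotator):
    """First-passage-time annotator (per-bird radius selection).

    ``fit`` rediscretizes each bird's track to ``step_m`` spacing and
    computes its FPT profile; ``predict`` labels the temporal fixes.
    Fitted attributes: ``profiles_`` (bird -> FptProfile), ``spatial_``.
    """

    method = "fpt"

    def __init__(self, radii=None, step_m: float = 500.0, sextile: float = 1 / 6):
        self.radii = radii
        self.step_m = step_m
        self.sextile = sextile

    def fit(self, traj: pd.DataFrame, y=None):
        check_trajectory(traj, need_metrics=False)
        self.spatial_ = rediscretize_space(traj, self.step_m)
        self.profiles_ = {}
        for bird, g in self.spatial_.groupby("bird_id", sort=False):
            self.profiles_[bird] = fpt_select_radius(g, self.radii)
        return self

    def predict(self, traj: pd.DataFrame) -> np.ndarray:
        states = np.full(len(traj), "excluded", dtype=object)
        for bird, profile in self.profiles_.items():
            sel = (traj["bird_id"] == bird).to_numpy()
            if not sel.any():
                continue
            g_spatial = self.spatial_[self.spatial_["bird_id"] == bird]
            states[sel] = fpt_classify(traj[sel], g_spatial, profile, self.sextile)
        return states
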