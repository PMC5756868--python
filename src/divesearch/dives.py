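"""Dive-event extraction from depth series and matching to GPS fixes.

A dive event is a maximal contiguous excursion of the depth record above a
threshold (1 m by default); its timestamp is the onset, the first sample of
the excursion. Events are matched to the temporally nearest trajectory fix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def detect_dives(depth: pd.DataFrame, threshold_m: float = 1.0) -> pd.DataFrame:
    """Extract dive onsets from a depth series.

    Parameters
    ----------
    depth : DataFrame with columns bird_id, t (unix s), depth (m, >= 0).
    threshold_m : depth that must be exceeded (strictly) to count as diving.

    Returns
    -------
    DataFrame with columns bird_id, t_onset — one row per maximal contiguous
    run of samples deeper than the threshold. Runs separated by any
    sub-threshold sample are distinct events.
    """
    events = []
    for bird, g in depth.groupby("bird_id", sort=False):
        g = g.sort_values("t")
        below = g["depth"].to_numpy(float) > threshold_m
        starts = np.flatnonzero(np.diff(np.concatenate(([0], below.astype(int)))) == 1)
        t = g["t"].to_numpy(float)
        for s in starts:
            events.append((bird, t[s]))
    return pd.DataFrame(events, columns=["bird_id", "t_onset"])


def match_dives(traj: pd.DataFrame, dives: pd.DataFrame) -> pd.DataFrame:
    """Assign each dive to the trajectory fix nearest in time.

    Ties between two equidistant fixes go to the earlier one. Dives more
    than half a fix interval beyond the track's time span, or whose nearest
    fix is invalid (night/colony), are flagged unmatched; unmatched counts
    are logged and those dives are excluded from all rate denominators.

    Returns a copy of ``dives`` with columns ``fix_index`` (positional index
    into ``traj``; -1 when out of span) and ``matched`` (bool).
    """
    interval = traj.attrs.get("interval_s", 120.0)
    out = dives.copy().reset_index(drop=True)
    out["fix_index"] = -1
    out["matched"] = False
    has_valid = "valid" in traj.columns
    for bird, g in out.groupby("bird_id", sort=False):
        sel = traj["bird_id"] == bird
        tt = traj.loc[sel, "t"].to_numpy(float)
        pos = np.flatnonzero(sel.to_numpy())
        if len(tt) == 0:
            continue
        order = np.argsort(tt, kind="stable")
        tt_sorted = tt[order]
        for i, t0 in zip(g.index, g["t_onset"].to_numpy(float)):
            if t0 < tt_sorted[0] - interval / 2 or t0 > tt_sorted[-1] + interval / 2:
                continue
            j = np.searchsorted(tt_sorted, t0)
            cand = [k for k in (j - 1, j) if 0 <= k < len(tt_sorted)]
            # nearest fix; exact tie -> earlier fix
            best = min(cand, key=lambda k: (abs(tt_sorted[k] - t0), tt_sorted[k]))
            fix = pos[order[best]]
            out.loc[i, "fix_index"] = fix
            ok = bool(traj["valid"].iloc[fix]) if has_valid else True
            out.loc[i, "matched"] = ok
    n_un = int((~out["matched"]).sum())
    if n_un:
        log.info("%d of %d dives unmatched or on invalid fixes", n_un, len(out))
    return out
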