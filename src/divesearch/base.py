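"""Shared estimator interface for behavioral annotators.

Every annotation method is a scikit-learn-style estimator over a processed
trajectory frame (see :mod:`divesearch.trajectory`): ``fit`` learns whatever
the method needs (scales, cluster centers, model parameters), ``predict``
returns one state per fix from {'search', 'travel', 'rest', 'excluded'}.
Invalid fixes (night / colony) are always 'excluded'; valid fixes always get
a real state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

STATE_SET = ("search", "travel", "rest", "excluded")

_METRIC_COLS = ("step_len", "speed", "accel", "turn", "tortuosity")


def check_trajectory(traj: pd.DataFrame, need_metrics: bool = True) -> pd.DataFrame:
    if not isinstance(traj, pd.DataFrame):
        raise TypeError("trajectory must be a pandas DataFrame")
    required = {"bird_id", "t", "x", "y"}
    missing = required - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory missing columns: {sorted(missing)}")
    if need_metrics and not set(_METRIC_COLS) <= set(traj.columns):
        raise ValueError("trajectory metrics not computed (run compute_metrics)")
    return traj


def valid_mask(traj: pd.DataFrame) -> np.ndarray:
    if "valid" in traj.columns:
        return traj["valid"].to_numpy(bool)
    return np.ones(len(traj), dtype=bool)


class TrajectoryAnnotator(BaseEstimator):
    """Base class: fit on a trajectory, predict per-fix behavioral states."""

    #: short method name used in reports
    method: str = "base"

    def fit(self, traj: pd.DataFrame, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, traj: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit_predict(self, traj: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(traj, y).predict(traj)

    def _blank_states(self, traj: pd.DataFrame) -> np.ndarray:
        states = np.full(len(traj), "excluded", dtype=object)
        return states
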