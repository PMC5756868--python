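"""Speed–tortuosity threshold classification.

A fix is search if it meets any one of three expert-derived conditions on
its movement metrics (speed and acceleration backward-looking, tortuosity
over the 9-fix window):

1. tortuosity < 0.9 and speed > 1 m/s
2. 1.5 m/s < speed < 9 m/s
3. tortuosity >= 0.9 and acceleration < -4 m/s^2

Comparisons are applied exactly as stated (strict vs inclusive). A
condition cannot fire when one of its metrics is undefined; valid fixes that
are not search are labeled travel (the rule set has no rest state).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import TrajectoryAnnotator, check_trajectory, valid_mask


class ThresholdAnnotator(TrajectoryAnnotator):
    """Stateless rule-based annotator; ``fit`` is a no-op."""

    method = "thresholds"

    def __init__(
        self,
        tort_split: float = 0.9,
        speed_min_1: float = 1.0,
        speed_lo_2: float = 1.5,
        speed_hi_2: float = 9.0,
        accel_max_3: float = -4.0,
    ):
        self.tort_split = tort_split
        self.speed_min_1 = speed_min_1
        self.speed_lo_2 = speed_lo_2
        self.speed_hi_2 = speed_hi_2
        self.accel_max_3 = accel_max_3

    def fit(self, traj: pd.DataFrame, y=None):
        check_trajectory(traj)
        self.n_features_in_ = 3
        return self

    def predict(self, traj: pd.DataFrame) -> np.ndarray:
        check_trajectory(traj)
        speed = traj["speed"].to_numpy(float)
        tort = traj["tortuosity"].to_numpy(float)
        accel = traj["accel"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            c1 = (tort < self.tort_split) & (speed > self.speed_min_1)
            c2 = (speed > self.speed_lo_2) & (speed < self.speed_hi_2)
            c3 = (tort >= self.tort_split) & (accel < self.accel_max_3)
        search = c1 | c2 | c3
        states = self._blank_states(traj)
        ok = valid_mask(traj)
        states[ok] = np.where(search[ok], "search", "travel")
        return states
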