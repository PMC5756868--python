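"""Expectation–maximization binary clustering (EMbC) on (speed, |turn|).

Each feature is split by a delimiter into low/high, defining four bins:
LL (low speed, low turn), LH (low speed, high turn), HL (high speed, low
turn), HH (high speed, high turn). A bivariate Gaussian is maintained per
bin. Starting from the feature medians, the algorithm alternates: assign
each point to the bin its side of each delimiter dictates; refit the bin
Gaussians and weights; move each delimiter to the weight-weighted midpoint
between its low-bin and high-bin means; stop when the mixture
log-likelihood change falls below tolerance.

Behavior labels: LL -> rest, HL -> travel, LH -> search, HH -> search by
default (the high-speed high-turn bin can be read as extensive search or
transit; configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .base import TrajectoryAnnotator, check_trajectory, valid_mask

log = logging.getLogger(__name__)

BINS = ("LL", "LH", "HL", "HH")  # (speed, turn) low/high
_BIN_SIDES = {"LL": (0, 0), "LH": (0, 1), "HL": (1, 0), "HH": (1, 1)}

_MIN_WEIGHT = 1e-6


@dataclass
class EmbcModel:
    means: np.ndarray  # 4 x 2, rows in BINS order
    covs: np.ndarray  # 4 x 2 x 2
    weights: np.ndarray  # 4
    delimiters: np.ndarray  # per-feature split (speed, |turn|)
    loglik_path: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else np.nan


def _bin_of(X: np.ndarray, delim: np.ndarray) -> np.ndarray:
    hi = (X >= delim).astype(int)  # n x 2
    return hi[:, 0] * 2 + hi[:, 1]  # index into BINS


def _fit_bins(X: np.ndarray, labels: np.ndarray):
    n = len(X)
    means = np.zeros((4, 2))
    covs = np.zeros((4, 2, 2))
    weights = np.zeros(4)
    global_cov = np.cov(X.T) + np.eye(2) * 1e-6
    for b in range(4):
        sel = labels == b
        m = sel.sum()
        if m == 0:
            log.warning("EMbC bin %s emptied; weight floored", BINS[b])
            weights[b] = _MIN_WEIGHT
            means[b] = X.mean(axis=0)
            covs[b] = global_cov
            continue
        weights[b] = max(m / n, _MIN_WEIGHT)
        means[b] = X[sel].mean(axis=0)
        if m > 2:
            covs[b] = np.cov(X[sel].T) + np.eye(2) * 1e-9
        else:
            covs[b] = global_cov
        # regularize near-singular covariances
        if np.linalg.det(covs[b]) < 1e-12:
            covs[b] = covs[b] + np.eye(2) * max(1e-6, 1e-3 * np.trace(covs[b]))
    weights = weights / weights.sum()
    return means, covs, weights


def _delimiters_from_bins(means: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per feature, the weight-weighted midpoint between the pooled low-bin
    and high-bin means."""
    delim = np.empty(2)
    for f in range(2):
        lo = [b for b, s in enumerate(_BIN_SIDES.values()) if s[f] == 0]
        hi = [b for b, s in enumerate(_BIN_SIDES.values()) if s[f] == 1]
        w_lo, w_hi = weights[lo].sum(), weights[hi].sum()
        m_lo = (weights[lo] @ means[lo, f]) / w_lo
        m_hi = (weights[hi] @ means[hi, f]) / w_hi
        delim[f] = (w_lo * m_lo + w_hi * m_hi) / (w_lo + w_hi)
    return delim


def _mixture_loglik(X: np.ndarray, means, covs, weights) -> float:
    dens = np.zeros(len(X))
    for b in range(4):
        dens += weights[b] * multivariate_normal.pdf(
            X, means[b], covs[b], allow_singular=True
        )
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def embc_fit(X: np.ndarray, max_iter: int = 100, tol: float = 1e-6) -> EmbcModel:
    """Fit the binary-clustering mixture to an n x 2 feature matrix."""
    if not np.isfinite(X).all():
        raise ValueError("EMbC features must be finite")
    delim = np.median(X, axis=0)
    model = None
    prev_ll = -np.inf
    ll_path = []
    for _ in range(max_iter):
        labels = _bin_of(X, delim)
        means, covs, weights = _fit_bins(X, labels)
        ll = _mixture_loglik(X, means, covs, weights)
        ll_path.append(ll)
        new_delim = _delimiters_from_bins(means, weights)
        model = EmbcModel(means, covs, weights, delim, ll_path)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            break
        prev_ll = ll
        delim = new_delim
    return model


class EMbCAnnotator(TrajectoryAnnotator):
    """EMbC annotator over (speed, |turning angle|).

    Fitted attributes: ``model_`` (bin Gaussians and delimiters).
    ``hh_state`` controls the high-speed/high-turn bin's behavior label.
    """

    method = "embc"

    def __init__(self, max_iter: int = 100, tol: float = 1e-6, hh_state: str = "search"):
        self.max_iter = max_iter
        self.tol = tol
        self.hh_state = hh_state

    def _features(self, traj: pd.DataFrame):
        speed = traj["speed"].to_numpy(float)
        turn = np.abs(traj["turn"].to_numpy(float))
        ok = valid_mask(traj) & np.isfinite(speed) & np.isfinite(turn)
        return np.column_stack([speed[ok], turn[ok]]), ok

    def fit(self, traj: pd.DataFrame, y=None):
        check_trajectory(traj)
        X, _ = self._features(traj)
        if len(X) < 8:
            raise ValueError("too few defined fixes for EMbC")
        self.model_ = embc_fit(X, self.max_iter, self.tol)
        return self

    def predict(self, traj: pd.DataFrame) -> np.ndarray:
        speed = traj["speed"].to_numpy(float)
        turn = np.abs(traj["turn"].to_numpy(float))
        ok = valid_mask(traj)
        defined = ok & np.isfinite(speed) & np.isfinite(turn)
        X = np.column_stack([speed[defined], turn[defined]])
        bins = _bin_of(X, self.model_.delimiters)
        bin_state = {
            "LL": "rest",
            "LH": "search",
            "HL": "travel",
            "HH": self.hh_state,
        }
        states = self._blank_states(traj)
        states[defined] = np.array([bin_state[BINS[b]] for b in bins], dtype=object)
        states[ok & ~defined] = "travel"
        return states

    def posteriors(self, traj: pd.DataFrame) -> np.ndarray:
        """Per-point maximum posterior among the four bin Gaussians."""
        X, _ = self._features(traj)
        m = self.model_
        dens = np.column_stack(
            [
                m.weights[b]
                * multivariate_normal.pdf(X, m.means[b], m.covs[b], allow_singular=True)
                for b in range(4)
            ]
        )
        return dens.max(axis=1) / np.maximum(dens.sum(axis=1), 1e-300)
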