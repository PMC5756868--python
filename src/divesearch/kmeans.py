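"""MacQueen online k-means on (step length, |turning angle|).

MacQueen's variant updates a cluster's centroid immediately after each point
is assigned to it (running-mean update), unlike the batch Lloyd iteration.
The cluster count is chosen by the elbow rule on explained variance
EV(k) = between-cluster SS / total SS: the smallest k whose next cluster
adds less than a set fraction of the first gain EV(2) - EV(1).

Behavioral assignment: the cluster with the largest mean step and smallest
mean |turn| is travel, the smallest mean step is rest, the remaining
(intermediate step, high turn) cluster is search. If one cluster wins two
labels the fallback is step-length ordering (largest = travel, smallest =
rest, middle = search) with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .base import TrajectoryAnnotator, check_trajectory, valid_mask

log = logging.getLogger(__name__)


def macqueen_kmeans(X: np.ndarray, k: int, rng: np.random.Generator, max_passes: int = 50):
    """MacQueen online k-means.

    Centers start at k distinct random points; each pass presents the points
    in order, assigning each to its nearest center and moving that center to
    the running mean of everything assigned to it so far. Stops when a full
    pass changes no assignment.

    Returns (labels, centers).
    """
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    idx = rng.choice(n, size=k, replace=False)
    centers = X[idx].astype(float).copy()
    counts = np.ones(k)
    labels = np.full(n, -1)
    for _ in range(max_passes):
        changed = False
        for i in range(n):
            d = ((centers - X[i]) ** 2).sum(axis=1)
            j = int(np.argmin(d))
            if labels[i] != j:
                changed = True
                labels[i] = j
            counts[j] += 1
            centers[j] += (X[i] - centers[j]) / counts[j]
        if not changed:
            break
    # final hard assignment to the converged centers
    d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d.argmin(axis=1)
    return labels, centers


def explained_variance(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster sum of squares over total sum of squares."""
    mu = X.mean(axis=0)
    tot = ((X - mu) ** 2).sum()
    if tot == 0:
        return np.nan
    between = 0.0
    for j in np.unique(labels):
        sel = labels == j
        between += sel.sum() * ((X[sel].mean(axis=0) - mu) ** 2).sum()
    return between / tot


class KMeansAnnotator(TrajectoryAnnotator):
    """Elbow-selected MacQueen k-means annotator.

    Attributes set by ``fit``: ``k_``, ``ev_`` (EV per k), ``centers_``,
    ``cluster_states_`` (cluster index -> behavior).
    """

    method = "kmeans"

    def __init__(
        self, k_max: int = 8, elbow_frac: float = 0.1, n_init: int = 10, random_state: int = 0
    ):
        self.k_max = k_max
        self.elbow_frac = elbow_frac
        self.n_init = n_init
        self.random_state = random_state

    def _features(self, traj: pd.DataFrame):
        step = traj["step_len"].to_numpy(float)
        turn = np.abs(traj["turn"].to_numpy(float))
        ok = valid_mask(traj) & np.isfinite(step) & np.isfinite(turn)
        X = np.column_stack([step[ok], turn[ok]])
        return X, ok

    def fit(self, traj: pd.DataFrame, y=None):
        check_trajectory(traj)
        X, ok = self._features(traj)
        if len(X) < 2:
            raise ValueError("too few defined fixes for clustering")
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        self._mean_, self._sd_ = X.mean(axis=0), sd

        if ((X - X[0]) ** 2).sum() == 0:  # all points identical
            self.k_ = 1
            self.ev_ = {1: np.nan}
            self.centers_ = Z[:1].copy()
            self.cluster_states_ = {0: "rest"}
            self.labels_raw_ = np.zeros(len(X), dtype=int)
            return self

        rng = np.random.default_rng(self.random_state)
        k_max = min(self.k_max, len(X))
        ev = {1: 0.0}
        all_labels = {1: np.zeros(len(X), dtype=int)}
        all_centers = {1: Z.mean(axis=0)[None, :]}
        for k in range(2, k_max + 1):
            # online k-means is sensitive to its seeds: keep the best of
            # several seeded restarts by explained variance
            best = None
            for _ in range(self.n_init):
                labels, centers = macqueen_kmeans(Z, k, rng)
                e = explained_variance(Z, labels)
                if best is None or e > best[0]:
                    best = (e, labels, centers)
            ev[k] = best[0]
            all_labels[k], all_centers[k] = best[1], best[2]
        first_gain = ev[2] - ev[1]
        k_sel = k_max
        for k in range(2, k_max):
            if ev[k + 1] - ev[k] < self.elbow_frac * first_gain:
                k_sel = k
                break
        self.k_ = k_sel
        self.ev_ = ev
        self.centers_ = all_centers[k_sel]
        self.labels_raw_ = all_labels[k_sel]
        self.cluster_states_ = self._assign_behaviors(X, all_labels[k_sel], k_sel)
        return self

    def _assign_behaviors(self, X, labels, k):
        mean_step = np.array([X[labels == j, 0].mean() for j in range(k)])
        mean_turn = np.array([X[labels == j, 1].mean() for j in range(k)])
        order = np.argsort(mean_step)  # ascending step
        if k == 1:
            return {0: "rest"}
        travel_cand = int(np.argmax(mean_step))
        rest_cand = int(np.argmin(mean_step))
        mapping = {}
        if k == 3 and travel_cand == int(np.argmin(mean_turn)) and travel_cand != rest_cand:
            mapping[travel_cand] = "travel"
            mapping[rest_cand] = "rest"
            for j in range(k):
                mapping.setdefault(j, "search")
            return mapping
        if k == 3:
            log.warning("cluster label conflict; falling back to step-length ordering")
        # step-length ordering: smallest = rest, largest = travel, middle = search
        mapping[order[0]] = "rest"
        mapping[order[-1]] = "travel"
        for j in order[1:-1]:
            mapping[int(j)] = "search"
        return mapping

    def predict(self, traj: pd.DataFrame) -> np.ndarray:
        check_trajectory(traj)
        step = traj["step_len"].to_numpy(float)
        turn = np.abs(traj["turn"].to_numpy(float))
        ok = valid_mask(traj)
        defined = ok & np.isfinite(step) & np.isfinite(turn)
        Z = (np.column_stack([step[defined], turn[defined]]) - self._mean_) / self._sd_
        d = ((Z[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        states = self._blank_states(traj)
        states[defined] = np.array([self.cluster_states_[int(j)] for j in lab], dtype=object)
        # valid fixes with undefined features: conservative non-search label
        states[ok & ~defined] = "travel"
        return states
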