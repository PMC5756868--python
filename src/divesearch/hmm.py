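"""Hidden Markov model segmentation with gamma steps and von Mises turns.

The observation at each fix is (step length, turning angle); each latent
state has a gamma step-length distribution and a von Mises turning-angle
distribution. Undefined turns or steps (track ends, zero-length steps)
contribute emission probability 1 (missing at random). Parameters are
estimated by direct numerical maximization of the scaled forward
log-likelihood over unconstrained transforms (log for positive parameters,
multinomial logit for transition-matrix rows and the initial distribution),
from several random starts; the most probable state path is decoded with
the Viterbi algorithm. Independent tracks/segments multiply: the initial
distribution restarts at every segment and log-likelihoods add.

States are reported in increasing order of mean step length and mapped to
behaviors by that ordering: smallest mean step = rest, largest = travel,
middle = search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e

from .base import TrajectoryAnnotator, check_trajectory, valid_mask

_BIG = 1e10


@dataclass
class HmmModel:
    """Fitted movement HMM (K states)."""

    step_mean: np.ndarray  # m
    step_sd: np.ndarray  # m
    turn_mean: np.ndarray  # rad
    turn_kappa: np.ndarray
    Gamma: np.ndarray  # K x K transition matrix
    delta: np.ndarray  # initial distribution
    loglik: float = np.nan
    extras: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.step_mean)

    def validate(self) -> None:
        K = self.K
        if self.Gamma.shape != (K, K) or not np.allclose(self.Gamma.sum(axis=1), 1.0):
            raise ValueError("Gamma rows must sum to 1")
        if not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("delta must sum to 1")
        if (self.step_mean <= 0).any() or (self.step_sd <= 0).any():
            raise ValueError("gamma parameters must be positive")
        if (self.turn_kappa < 0).any():
            raise ValueError("von Mises concentration must be >= 0")

    def behavior_map(self) -> dict[int, str]:
        order = np.argsort(self.step_mean)
        mapping = {int(order[0]): "rest", int(order[-1]): "travel"}
        for j in order[1:-1]:
            mapping[int(j)] = "search"
        if self.K == 1:
            mapping = {0: "search"}
        return mapping


def _gamma_logpdf(x, mean, sd):
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return (shape - 1) * np.log(x) - x / scale - shape * np.log(scale) - gammaln(shape)


def _vonmises_logpdf(x, mu, kappa):
    # log I0(k) = log(i0e(k)) + k, numerically safe for large k
    return kappa * np.cos(x - mu) - np.log(2 * np.pi) - (np.log(i0e(kappa)) + kappa)


def emission_logprob(steps: np.ndarray, turns: np.ndarray, model: HmmModel) -> np.ndarray:
    """T x K matrix of per-fix emission log-densities; NaN observations
    contribute 0 (probability 1)."""
    T, K = len(steps), model.K
    logB = np.zeros((T, K))
    ok_s = np.isfinite(steps)
    ok_t = np.isfinite(turns)
    for k in range(K):
        logB[ok_s, k] += _gamma_logpdf(steps[ok_s], model.step_mean[k], model.step_sd[k])
        logB[ok_t, k] += _vonmises_logpdf(turns[ok_t], model.turn_mean[k], model.turn_kappa[k])
    return logB


@njit(cache=False)
def _forward_nb(logB, Gamma, delta, starts, ends):
    ll = 0.0
    K = Gamma.shape[1]
    alpha = np.empty(K)
    tmp = np.empty(K)
    for s in range(len(starts)):
        a, b = starts[s], ends[s]
        m = np.max(logB[a])
        for k in range(K):
            alpha[k] = delta[k] * np.exp(logB[a, k] - m)
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        ll += np.log(c) + m
        alpha /= c
        for t in range(a + 1, b):
            m = np.max(logB[t])
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[i] * Gamma[i, j]
                tmp[j] = acc * np.exp(logB[t, j] - m)
            c = tmp.sum()
            if c <= 0:
                return -np.inf
            ll += np.log(c) + m
            alpha[:] = tmp / c
    return ll


@njit(cache=False)
def _viterbi_nb(logB, logGamma, logdelta, starts, ends):
    T, K = logB.shape
    path = np.empty(T, dtype=np.int64)
    for s in range(len(starts)):
        a, b = starts[s], ends[s]
        n = b - a
        score = np.empty((n, K))
        back = np.zeros((n, K), dtype=np.int64)
        for k in range(K):
            score[0, k] = logdelta[k] + logB[a, k]
        for t in range(1, n):
            for j in range(K):
                best = -np.inf
                arg = 0
                for i in range(K):
                    v = score[t - 1, i] + logGamma[i, j]
                    if v > best:  # strict: ties stay with the lower index
                        best = v
                        arg = i
                score[t, j] = best + logB[a + t, j]
                back[t, j] = arg
        best = -np.inf
        arg = 0
        for k in range(K):
            if score[n - 1, k] > best:
                best = score[n - 1, k]
                arg = k
        path[a + n - 1] = arg
        for t in range(n - 1, 0, -1):
            path[a + t - 1] = back[t, path[a + t]]
    return path


def _sequences(traj: pd.DataFrame):
    """Steps, turns and run boundaries over maximal runs of valid fixes.

    Runs are broken by invalid fixes and by bird/segment boundaries. Zero
    step lengths are perturbed to half the smallest positive step (a gamma
    density has no mass at zero).
    """
    ok = valid_mask(traj)
    group_cols = [c for c in ("bird_id", "segment") if c in traj.columns]
    if group_cols:
        keys = traj[group_cols].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        keys = np.full(len(traj), "all")
    new_group = np.concatenate(([True], keys[1:] != keys[:-1]))

    idx, starts, ends = [], [], []
    run = []
    for i in range(len(traj)):
        if ok[i] and not (new_group[i] and run):
            run.append(i)
        else:
            if len(run) >= 1:
                starts.append(len(idx))
                idx.extend(run)
                ends.append(len(idx))
            run = [i] if ok[i] else []
    if run:
        starts.append(len(idx))
        idx.extend(run)
        ends.append(len(idx))

    idx = np.asarray(idx, dtype=int)
    steps = traj["step_len"].to_numpy(float)[idx]
    turns = traj["turn"].to_numpy(float)[idx]
    pos = steps[np.isfinite(steps) & (steps > 0)]
    if len(pos):
        steps = np.where(steps == 0, pos.min() / 2, steps)
    return steps, turns, np.asarray(starts), np.asarray(ends), idx


def hmm_forward_loglik(model: HmmModel, traj: pd.DataFrame) -> float:
    """Scaled-forward log-likelihood of the trajectory under the model."""
    model.validate()
    steps, turns, starts, ends, _ = _sequences(traj)
    logB = emission_logprob(steps, turns, model)
    return float(_forward_nb(logB, model.Gamma, model.delta, starts, ends))


def hmm_viterbi(model: HmmModel, traj: pd.DataFrame) -> np.ndarray:
    """Most probable state index per fix (-1 for invalid fixes).

    Ties in the dynamic program break toward the lower state index.
    """
    model.validate()
    steps, turns, starts, ends, idx = _sequences(traj)
    logB = emission_logprob(steps, turns, model)
    with np.errstate(divide="ignore"):
        path = _viterbi_nb(logB, np.log(model.Gamma), np.log(model.delta), starts, ends)
    out = np.full(len(traj), -1, dtype=int)
    out[idx] = path
    return out


# ---------------------------------------------------------------- fitting


def _pack(model: HmmModel) -> np.ndarray:
    K = model.K
    parts = [
        np.log(model.step_mean),
        np.log(model.step_sd),
        model.turn_mean,
        np.log(np.maximum(model.turn_kappa, 1e-6)),
    ]
    for i in range(K):
        row = model.Gamma[i]
        off = np.delete(np.arange(K), i)
        parts.append(np.log(row[off] / row[i]))
    parts.append(np.log(model.delta[1:] / model.delta[0]))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, K: int) -> HmmModel:
    p = 0

    def take(n):
        nonlocal p
        out = theta[p : p + n]
        p += n
        return out

    step_mean = np.exp(take(K))
    step_sd = np.exp(take(K))
    turn_mean = np.mod(take(K) + np.pi, 2 * np.pi) - np.pi
    turn_kappa = np.exp(take(K))
    Gamma = np.empty((K, K))
    for i in range(K):
        logits = take(K - 1)
        off = np.delete(np.arange(K), i)
        row = np.empty(K)
        row[i] = 1.0
        row[off] = np.exp(np.clip(logits, -30, 30))
        Gamma[i] = row / row.sum()
    logits = np.concatenate(([0.0], np.clip(take(K - 1), -30, 30)))
    delta = np.exp(logits) / np.exp(logits).sum()
    return HmmModel(step_mean, step_sd, turn_mean, turn_kappa, Gamma, delta)


def _init_model(steps: np.ndarray, K: int, rng: np.random.Generator) -> HmmModel:
    pos = steps[np.isfinite(steps) & (steps > 0)]
    qs = np.quantile(pos, np.linspace(0.15, 0.9, K))
    means = qs * rng.uniform(0.7, 1.3, size=K)
    sds = means * rng.uniform(0.5, 1.0, size=K)
    kappas = rng.uniform(0.5, 3.0, size=K)
    Gamma = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(Gamma, 0.9)
    delta = np.full(K, 1.0 / K)
    return HmmModel(means, sds, np.zeros(K), kappas, Gamma, delta)


def hmm_fit(
    traj: pd.DataFrame,
    K: int = 3,
    n_starts: int = 3,
    random_state: int = 0,
    maxiter: int = 300,
) -> HmmModel:
    """Fit a K-state movement HMM by direct likelihood maximization.

    Runs ``n_starts`` random initializations (gamma means seeded from step
    quantiles) of L-BFGS on the unconstrained parameterization and keeps
    the best converged solution. States come back sorted by mean step.
    """
    steps, turns, starts, ends, _ = _sequences(traj)
    if len(steps) < 10 * K:
        raise ValueError("too few valid fixes to fit an HMM")
    rng = np.random.default_rng(random_state)

    def nll(theta):
        try:
            m = _unpack(theta, K)
        except (FloatingPointError, ValueError):
            return _BIG
        if (m.step_mean > 1e8).any() or (m.turn_kappa > 1e4).any():
            return _BIG
        logB = emission_logprob(steps, turns, m)
        if not np.isfinite(logB).all():
            return _BIG
        ll = _forward_nb(logB, m.Gamma, m.delta, starts, ends)
        return -ll if np.isfinite(ll) else _BIG

    best = None
    diagnostics = []
    for _ in range(n_starts):
        theta0 = _pack(_init_model(steps, K, rng))
        res = minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": maxiter})
        diagnostics.append((res.fun, res.message))
        if np.isfinite(res.fun) and res.fun < _BIG / 2:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"no HMM start converged: {diagnostics}")

    model = _unpack(best.x, K)
    order = np.argsort(model.step_mean)
    model = HmmModel(
        step_mean=model.step_mean[order],
        step_sd=model.step_sd[order],
        turn_mean=model.turn_mean[order],
        turn_kappa=model.turn_kappa[order],
        Gamma=model.Gamma[np.ix_(order, order)],
        delta=model.delta[order],
        loglik=-best.fun,
        extras={"n_obs": len(steps), "n_starts": n_starts},
    )
    model.validate()
    return model


class HMMAnnotator(TrajectoryAnnotator):
    """HMM annotator: fit pooled over the colony's valid fixes, decode with
    Viterbi. Fitted attributes: ``model_``."""

    method = "hmm"

    def __init__(self, K: int = 3, n_starts: int = 3, random_state: int = 0):
        self.K = K
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, traj: pd.DataFrame, y=None):
        check_trajectory(traj)
        self.model_ = hmm_fit(traj, self.K, self.n_starts, self.random_state)
        return self

    def predict(self, traj: pd.DataFrame) -> np.ndarray:
        path = hmm_viterbi(self.model_, traj)
        mapping = self.model_.behavior_map()
        states = self._blank_states(traj)
        ok = valid_mask(traj) & (path >= 0)
        states[ok] = np.array([mapping[int(s)] for s in path[ok]], dtype=object)
        return states
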