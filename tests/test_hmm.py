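import itertools

import numpy as np
import pytest
from scipy import stats

from divesearch import HmmModel, hmm_fit, hmm_forward_loglik, hmm_viterbi
from divesearch.hmm import HMMAnnotator
from conftest import make_traj


def random_model(K, rng):
    mean = rng.uniform(50, 2000, K)
    sd = mean * rng.uniform(0.3, 0.9, K)
    mu = rng.uniform(-np.pi, np.pi, K)
    kappa = rng.uniform(0.1, 5, K)
    Gamma = rng.dirichlet(np.ones(K) * 2, size=K)
    delta = rng.dirichlet(np.ones(K) * 2)
    return HmmModel(mean, sd, mu, kappa, Gamma, delta)


def traj_from_obs(steps, turns):
    """One fix per (step, turn) observation pair."""
    n = len(steps)
    traj = make_traj(np.zeros(n), np.zeros(n))
    traj["step_len"] = np.asarray(steps, float)
    traj["turn"] = np.asarray(turns, float)
    for col in ("speed", "accel", "tortuosity"):
        traj[col] = 0.5
    return traj


def emission_pdf_oracle(step, turn, model, k):
    """Independent emission density via scipy.stats distributions."""
    p = 1.0
    if np.isfinite(step):
        shape = (model.step_mean[k] / model.step_sd[k]) ** 2
        scale = model.step_sd[k] ** 2 / model.step_mean[k]
        p *= stats.gamma.pdf(step, shape, scale=scale)
    if np.isfinite(turn):
        p *= stats.vonmises.pdf(turn, model.turn_kappa[k], loc=model.turn_mean[k])
    return p


def loglik_oracle(steps, turns, model):
    """Total probability by explicit sum over all K^T state paths."""
    T, K = len(steps), model.K
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.delta[path[0]] * emission_pdf_oracle(steps[0], turns[0], model, path[0])
        for t in range(1, T):
            p *= model.Gamma[path[t - 1], path[t]] * emission_pdf_oracle(
                steps[t], turns[t], model, path[t]
            )
        total += p
    return np.log(total)


def viterbi_oracle(steps, turns, model):
    """Best path by exhaustive enumeration (lexicographic tie-break)."""
    T, K = len(steps), model.K
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        p = np.log(model.delta[path[0]]) + np.log(
            emission_pdf_oracle(steps[0], turns[0], model, path[0])
        )
        for t in range(1, T):
            p += np.log(model.Gamma[path[t - 1], path[t]]) + np.log(
                emission_pdf_oracle(steps[t], turns[t], model, path[t])
            )
        if p > best + 1e-12:
            best, best_path = p, path
    return best, best_path


def path_logprob(steps, turns, model, path):
    p = np.log(model.delta[path[0]]) + np.log(
        emission_pdf_oracle(steps[0], turns[0], model, path[0])
    )
    for t in range(1, len(steps)):
        p += np.log(model.Gamma[path[t - 1], path[t]]) + np.log(
            emission_pdf_oracle(steps[t], turns[t], model, path[t])
        )
    return p


class TestForward:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        model = random_model(1, rng)
        steps = rng.gamma(2.0, 300.0, 8)
        turns = rng.vonmises(0.0, 1.0, 8)
        traj = traj_from_obs(steps, turns)
        want = sum(np.log(emission_pdf_oracle(s, t, model, 0)) for s, t in zip(steps, turns))
        assert hmm_forward_loglik(model, traj) == pytest.approx(want, abs=1e-8)

    def test_matches_enumeration_small(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            K = rng.integers(2, 4)
            T = rng.integers(2, 7)
            model = random_model(K, rng)
            steps = rng.gamma(2.0, 500.0, T)
            turns = rng.vonmises(0.0, 1.0, T)
            traj = traj_from_obs(steps, turns)
            got = hmm_forward_loglik(model, traj)
            want = loglik_oracle(steps, turns, model)
            assert got == pytest.approx(want, abs=1e-8), trial

    def test_missing_observations_contribute_one(self):
        rng = np.random.default_rng(2)
        model = random_model(2, rng)
        steps = np.array([300.0, np.nan, 500.0])
        turns = np.array([np.nan, 0.5, np.nan])
        traj = traj_from_obs(steps, turns)
        got = hmm_forward_loglik(model, traj)
        want = loglik_oracle(steps, turns, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_segment_additivity_single_state(self):
        rng = np.random.default_rng(3)
        model = random_model(1, rng)
        steps = rng.gamma(2.0, 300.0, 10)
        turns = rng.vonmises(0.0, 1.0, 10)
        t1 = traj_from_obs(steps[:6], turns[:6])
        t2 = traj_from_obs(steps[6:], turns[6:])
        t2["segment"] = 1
        both = traj_from_obs(steps, turns)
        both.loc[6:, "segment"] = 1
        assert hmm_forward_loglik(model, both) == pytest.approx(
            hmm_forward_loglik(model, t1) + hmm_forward_loglik(model, t2), abs=1e-8
        )

    def test_invalid_model_rejected(self):
        rng = np.random.default_rng(4)
        model = random_model(2, rng)
        model.Gamma = np.ones((2, 2))
        with pytest.raises(ValueError):
            hmm_forward_loglik(model, traj_from_obs([100.0], [0.1]))


class TestViterbi:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            K = rng.integers(2, 4)
            T = rng.integers(2, 7)
            model = random_model(K, rng)
            steps = rng.gamma(2.0, 500.0, T)
            turns = rng.vonmises(0.0, 1.0, T)
            traj = traj_from_obs(steps, turns)
            path = hmm_viterbi(model, traj)
            want_lp, _ = viterbi_oracle(steps, turns, model)
            got_lp = path_logprob(steps, turns, model, tuple(path))
            assert got_lp == pytest.approx(want_lp, abs=1e-8), trial

    def test_dominant_emissions_pointwise_argmax(self):
        # nearly-delta emissions: the path follows the per-point best state
        model = HmmModel(
            step_mean=np.array([100.0, 2000.0]),
            step_sd=np.array([5.0, 50.0]),
            turn_mean=np.zeros(2),
            turn_kappa=np.array([1.0, 1.0]),
            Gamma=np.array([[0.5, 0.5], [0.5, 0.5]]),
            delta=np.array([0.5, 0.5]),
        )
        steps = np.array([100.0, 2000.0, 100.0, 100.0, 2000.0])
        turns = np.full(5, np.nan)
        path = hmm_viterbi(model, traj_from_obs(steps, turns))
        assert list(path) == [0, 1, 0, 0, 1]


class TestFit:
    def test_nesting_k3_beats_k2(self, saltee):
        traj = saltee["traj"]
        m2 = hmm_fit(traj, K=2, n_starts=2, random_state=0)
        m3 = hmm_fit(traj, K=3, n_starts=2, random_state=0)
        assert m3.loglik >= m2.loglik - abs(m2.loglik) * 1e-3

    def test_states_sorted_by_step_mean(self, saltee):
        m = hmm_fit(saltee["traj"], K=3, n_starts=2, random_state=0)
        assert (np.diff(m.step_mean) > 0).all()
        assert m.behavior_map() == {0: "rest", 1: "search", 2: "travel"}

    def test_too_few_fixes_errors(self):
        traj = traj_from_obs([100.0, 200.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            hmm_fit(traj, K=3)


def test_annotator_covers_all_valid_fixes(saltee):
    traj = saltee["traj"]
    ann = HMMAnnotator(n_starts=2, random_state=0).fit(traj)
    states = ann.predict(traj)
    valid = traj["valid"].to_numpy(bool)
    assert set(states[valid]) <= {"search", "travel", "rest"}
    assert (states[~valid] == "excluded").all()
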