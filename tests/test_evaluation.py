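import itertools

import numpy as np
import pandas as pd
import pytest

from divesearch import (
    evaluate_annotation,
    extract_chains,
    kendall_tau,
    summarize,
    truth_annotation,
)
from conftest import make_traj


def _matched(fix_indices):
    return pd.DataFrame(
        {
            "bird_id": "b1",
            "t_onset": np.zeros(len(fix_indices)),
            "fix_index": fix_indices,
            "matched": True,
        }
    )


def _traj_n(n, trip=None):
    traj = make_traj(np.arange(n) * 100.0, np.zeros(n))
    traj["trip_id"] = trip if trip is not None else "t0"
    traj["valid"] = True
    return traj


def chains_oracle(labels):
    """Run-length scanner via itertools.groupby: (start, length) of S-runs."""
    out = []
    i = 0
    for key, grp in itertools.groupby(labels):
        n = len(list(grp))
        if key == "search":
            out.append((i, n))
        i += n
    return out


class TestExtractChains:
    def test_basic_runs(self):
        labels = np.array(["search", "search", "travel", "search"], dtype=object)
        chains = extract_chains(labels, _traj_n(4), _matched([]))
        assert [(c.start_idx, c.length) for c in chains] == [(0, 2), (3, 1)]

    def test_no_search_no_chains(self):
        labels = np.array(["travel"] * 5, dtype=object)
        assert extract_chains(labels, _traj_n(5), _matched([])) == []

    def test_trip_boundary_breaks_chain(self):
        labels = np.array(["search"] * 4, dtype=object)
        traj = _traj_n(4, trip=["a", "a", "b", "b"])
        chains = extract_chains(labels, traj, _matched([]))
        assert [(c.start_idx, c.length) for c in chains] == [(0, 2), (2, 2)]

    def test_dive_counts(self):
        labels = np.array(["search", "search", "travel", "search"], dtype=object)
        chains = extract_chains(labels, _traj_n(4), _matched([0, 1, 1, 3]))
        assert [c.n_dives for c in chains] == [3, 1]

    def test_random_strings_match_scanner(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 40)
            labels = rng.choice(["search", "travel", "rest"], size=n).astype(object)
            chains = extract_chains(labels, _traj_n(int(n)), _matched([]))
            assert [(c.start_idx, c.length) for c in chains] == chains_oracle(labels)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            extract_chains(np.array(["search"]), _traj_n(3), _matched([]))


def tau_oracle(x, y):
    """O(n^2) pair counting, tau-b tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (c - d) / denom if denom else np.nan


class TestKendallTau:
    def test_concordant(self):
        tau, z, p = kendall_tau([1, 2, 3], [10, 20, 30])
        assert tau == pytest.approx(1.0)

    def test_discordant(self):
        tau, _, _ = kendall_tau([1, 2, 3], [3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_tied_data_matches_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 5, 20)
            y = rng.integers(0, 4, 20)
            tau, z, p = kendall_tau(x, y)
            assert tau == pytest.approx(tau_oracle(x, y), abs=1e-12)
            assert 0 <= p <= 1
            assert np.sign(z) == np.sign(tau) or tau == 0

    def test_bad_input(self):
        with pytest.raises(ValueError):
            kendall_tau([1], [2])


class TestSummarize:
    def test_all_dives_in_search(self):
        labels = np.array(["search"] * 4 + ["travel"] * 4, dtype=object)
        s = evaluate_annotation(labels, _traj_n(8), _matched([0, 1, 2]))
        assert s.tp_rate == 100.0
        assert s.fn_rate == 0.0
        assert s.pct_searching == 50.0

    def test_tp_plus_fn_is_100(self, saltee):
        from divesearch import ThresholdAnnotator

        states = ThresholdAnnotator().fit_predict(saltee["traj"])
        s = evaluate_annotation(states, saltee["traj"], saltee["dives"])
        assert s.tp_rate + s.fn_rate == pytest.approx(100.0)

    def test_chain_lengths_sum_to_search_count(self, saltee):
        from divesearch import KMeansAnnotator

        traj = saltee["traj"]
        states = KMeansAnnotator(random_state=0).fit_predict(traj)
        chains = extract_chains(states, traj, saltee["dives"])
        assert sum(c.length for c in chains) == int((states == "search").sum())

    def test_zero_matched_dives_undefined(self):
        labels = np.array(["search", "travel"], dtype=object)
        dives = _matched([])
        s = evaluate_annotation(labels, _traj_n(2), dives)
        assert np.isnan(s.tp_rate) and np.isnan(s.fn_rate)

    def test_truth_tp_100_when_dives_only_in_search(self):
        from divesearch import SimConfig, match_dives, simulate_colony_dataset
        from divesearch.trajectory import preprocess
        from divesearch.simulate import GREAT_SALTEE

        cfg = SimConfig(n_birds=2, trip_hours=8.0, p_dive_other=0.0, seed=21)
        sim = simulate_colony_dataset(cfg)
        traj = preprocess(sim.fixes[["bird_id", "t", "lon", "lat"]].copy(), GREAT_SALTEE)
        dives = match_dives(traj, sim.dives)
        states = truth_annotation(traj, sim.truth)
        s = evaluate_annotation(states, traj, dives)
        assert s.tp_rate == pytest.approx(100.0)

    def test_relabel_monotonicity(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["search", "travel"], size=30).astype(object)
        dives = _matched(list(rng.integers(0, 30, 8)))
        base = evaluate_annotation(labels.copy(), _traj_n(30), dives)
        flip = np.flatnonzero(labels == "travel")[0]
        labels[flip] = "search"
        more = evaluate_annotation(labels, _traj_n(30), dives)
        assert more.tp_rate >= base.tp_rate
        assert more.pct_searching >= base.pct_searching
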