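"""Synthetic central-place foraging trips with known behavioral states.

The generator mirrors the generative assumptions shared by the annotation
methods: a latent 3-state Markov chain (travel / search / rest) with
state-specific gamma step lengths and von Mises turning angles, a heading
bias that steers travel away from the colony on the outbound half of the
trip and back toward it on the return half, and dive events drawn per fix
with a state-dependent Bernoulli probability (concentrated in, but not
exclusive to, search). Trips run in daylight hours so the night filter is
exercised without emptying the data.

Default scales mimic a plunge-diving seabird sampled at 2-min fixes:
travel ~15 m/s (1,800-m steps), search ~2.5 m/s (300-m steps), rest ~0.25
m/s, with turning concentration high in travel and low in rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo, io

STATES = ("travel", "search", "rest")

GREAT_SALTEE = (-6.62189, 52.11286)
BASS_ROCK = (-2.64105, 56.07736)

#: 2015-06-15 07:00:00 UTC — midsummer so 10-h trips stay in daylight
DEFAULT_T0 = 1434351600.0


@dataclass
class StateParams:
    """Emission parameters of one behavioral state."""

    step_mean: float  # m
    step_sd: float  # m
    turn_mean: float = 0.0  # rad
    turn_kappa: float = 1.0  # von Mises concentration

    def gamma_shape_scale(self) -> tuple[float, float]:
        shape = (self.step_mean / self.step_sd) ** 2
        return shape, self.step_sd**2 / self.step_mean


@dataclass
class SimConfig:
    n_birds: int = 6
    trip_hours: float = 10.0
    interval_s: float = 120.0
    colony: tuple[float, float] = GREAT_SALTEE
    utm_zone: int = 30
    t0: float = DEFAULT_T0
    states: dict = field(
        default_factory=lambda: {
            "travel": StateParams(1800.0, 500.0, 0.0, 10.0),
            "search": StateParams(300.0, 150.0, 0.0, 1.0),
            "rest": StateParams(30.0, 20.0, 0.0, 0.5),
        }
    )
    P: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.92, 0.07, 0.01],
                [0.06, 0.90, 0.04],
                [0.04, 0.10, 0.86],
            ]
        )
    )
    p0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    p_dive_search: float = 0.2
    p_dive_other: float = 0.002
    outbound_bias: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        P = np.asarray(self.P, float)
        if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0) or (P < 0).any():
            raise ValueError("P must be a 3x3 row-stochastic matrix")
        if not np.isclose(np.sum(self.p0), 1.0) or (np.asarray(self.p0) < 0).any():
            raise ValueError("p0 must be a distribution over 3 states")
        for name in STATES:
            sp = self.states[name]
            if sp.step_mean <= 0 or sp.step_sd <= 0 or sp.turn_kappa < 0:
                raise ValueError(f"invalid parameters for state {name}")
        for p in (self.p_dive_search, self.p_dive_other):
            if not 0 <= p <= 1:
                raise ValueError("dive probabilities must be in [0, 1]")


@dataclass
class SimTruth:
    """One simulated dataset: fixes, latent states, dive events."""

    fixes: pd.DataFrame  # bird_id, t, lon, lat, x, y
    truth: pd.DataFrame  # bird_id, t, true_state
    dives: pd.DataFrame  # bird_id, t_onset


def _wrap(a):
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def simulate_trip(cfg: SimConfig, bird: str, rng: np.random.Generator) -> SimTruth:
    """Simulate one bird's trip; fully reproducible from the generator state."""
    cfg.validate()
    n = int(round(cfg.trip_hours * 3600 / cfg.interval_s))
    P = np.asarray(cfg.P, float)
    p0 = np.asarray(cfg.p0, float)

    states = np.empty(n, dtype=int)
    states[0] = rng.choice(3, p=p0)
    for i in range(1, n):
        states[i] = rng.choice(3, p=P[states[i - 1]])

    cx, cy = geo.project(cfg.colony[0], cfg.colony[1], cfg.utm_zone)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = cx, cy
    heading = rng.uniform(-np.pi, np.pi)

    for i in range(1, n):
        st = STATES[states[i]]
        sp = cfg.states[st]
        shape, scale = sp.gamma_shape_scale()
        step = rng.gamma(shape, scale)
        mu = sp.turn_mean
        if st == "travel":
            # commute bias: outbound half repelled from colony, return attracted
            to_colony = np.arctan2(cy - y[i - 1], cx - x[i - 1])
            target = to_colony + np.pi if i < n / 2 else to_colony
            mu = cfg.outbound_bias * _wrap(target - heading)
        turn = rng.vonmises(mu, sp.turn_kappa)
        heading = _wrap(heading + turn)
        x[i] = x[i - 1] + step * np.cos(heading)
        y[i] = y[i - 1] + step * np.sin(heading)

    t = cfg.t0 + cfg.interval_s * np.arange(n)
    lon, lat = geo.unproject(x, y, cfg.utm_zone)
    fixes = pd.DataFrame({"bird_id": bird, "t": t, "lon": lon, "lat": lat, "x": x, "y": y})
    truth = pd.DataFrame(
        {"bird_id": bird, "t": t, "true_state": np.array(STATES, dtype=object)[states]}
    )

    p_dive = np.where(states == STATES.index("search"), cfg.p_dive_search, cfg.p_dive_other)
    hit = rng.random(n) < p_dive
    jitter = rng.uniform(0.0, cfg.interval_s / 2, size=n)
    dives = pd.DataFrame({"bird_id": bird, "t_onset": (t + jitter)[hit]})
    return SimTruth(fixes, truth, dives)


def simulate_colony_dataset(cfg: SimConfig, outdir=None) -> SimTruth:
    """Simulate ``n_birds`` independent trips from one colony.

    Each bird draws from its own RNG substream seeded by (seed, bird index),
    so bird k's trip is invariant to ``n_birds``. If ``outdir`` is given,
    track / dive / truth CSVs are written in the standard dialects.
    """
    if cfg.n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    parts = []
    for k in range(cfg.n_birds):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), k]))
        parts.append(simulate_trip(cfg, f"bird{k:02d}", rng))
    out = SimTruth(
        fixes=pd.concat([p.fixes for p in parts], ignore_index=True),
        truth=pd.concat([p.truth for p in parts], ignore_index=True),
        dives=pd.concat([p.dives for p in parts], ignore_index=True),
    )
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tracks(out.fixes, outdir / "tracks.csv")
        io.write_dives(out.dives, outdir / "dives.csv")
        truth = out.truth.copy()
        truth["timestamp"] = io._iso(truth["t"].to_numpy())
        truth[["bird_id", "timestamp", "true_state"]].to_csv(outdir / "truth.csv", index=False)
    return out


def simulate_patchy_track(
    patch_radius_m: float = 2000.0,
    n_patches: int = 4,
    leg_len_m: float = 20000.0,
    fixes_per_patch: int = 80,
    travel_step_m: float = 1800.0,
    search_step_m: float = 300.0,
    interval_s: float = 120.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Track alternating straight commutes with search confined to circular
    patches of known radius — a planted area-restricted-search scale for
    validating first-passage-time radius selection.

    Returns a planar trajectory frame (bird_id, segment, t, x, y).
    """
    rng = np.random.default_rng(seed)
    xs, ys = [0.0], [0.0]
    heading = rng.uniform(-np.pi, np.pi)
    for _ in range(n_patches):
        # straight commute leg
        n_leg = int(leg_len_m / travel_step_m)
        for _ in range(n_leg):
            heading += rng.vonmises(0.0, 50.0)
            xs.append(xs[-1] + travel_step_m * np.cos(heading))
            ys.append(ys[-1] + travel_step_m * np.sin(heading))
        cx_, cy_ = xs[-1], ys[-1]
        # tortuous search confined within the patch radius
        for _ in range(fixes_per_patch):
            heading += rng.vonmises(0.0, 0.8)
            nx = xs[-1] + search_step_m * np.cos(heading)
            ny = ys[-1] + search_step_m * np.sin(heading)
            if np.hypot(nx - cx_, ny - cy_) > patch_radius_m:
                heading = np.arctan2(cy_ - ys[-1], cx_ - xs[-1]) + rng.normal(0, 0.3)
                nx = xs[-1] + search_step_m * np.cos(heading)
                ny = ys[-1] + search_step_m * np.sin(heading)
            xs.append(nx)
            ys.append(ny)
        heading = rng.uniform(-np.pi, np.pi)
    n = len(xs)
    return pd.DataFrame(
        {
            "bird_id": "patchy",
            "segment": 0,
            "t": interval_s * np.arange(n, dtype=float),
            "x": np.asarray(xs),
            "y": np.asarray(ys),
        }
    )
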