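import numpy as np
import pandas as pd
import pytest

from divesearch import SimConfig, simulate_colony_dataset
from divesearch.reference import make_reference_dataset


def make_traj(x, y, t=None, bird="b1", valid=None, interval=120.0):
    """Hand-built planar trajectory frame for unit tests."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.arange(len(x)) * interval if t is None else np.asarray(t, float)
    df = pd.DataFrame({"bird_id": bird, "segment": 0, "t": t, "x": x, "y": y})
    if valid is not None:
        df["valid"] = valid
    df.attrs["interval_s"] = float(t[1] - t[0]) if len(t) > 1 else interval
    return df


@pytest.fixture(scope="session")
def ref_dataset():
    """Small processed two-colony reference dataset (shared, read-only)."""
    return make_reference_dataset(seed=1, n_birds=4, trip_hours=10.0)


@pytest.fixture(scope="session")
def saltee(ref_dataset):
    return ref_dataset["saltee"]


@pytest.fixture(scope="session")
def big_sim():
    """One long unbiased simulation for distributional checks."""
    cfg = SimConfig(n_birds=1, trip_hours=20000 * 120 / 3600, outbound_bias=0.0, seed=7)
    return simulate_colony_dataset(cfg), cfg
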