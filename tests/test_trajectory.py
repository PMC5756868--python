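import numpy as np
import pandas as pd
import pytest

from divesearch import geo, trajectory
from conftest import make_traj

COLONY = (-6.62189, 52.11286)


def _raw(lonlat_t):
    return pd.DataFrame(
        [{"bird_id": "b", "t": t, "lon": lon, "lat": lat} for lon, lat, t in lonlat_t]
    )


class TestInterpolateTime:
    def test_midpoint(self):
        traj = make_traj([0, 480], [0, 0], t=[0, 240])
        out = trajectory.interpolate_time(traj, interval_s=120)
        row = out[out["t"] == 120].iloc[0]
        assert row["x"] == pytest.approx(240.0)
        assert row["y"] == pytest.approx(0.0)

    def test_regular_track_unchanged(self):
        traj = make_traj(np.arange(5) * 100.0, np.zeros(5))
        out = trajectory.interpolate_time(traj, interval_s=120)
        assert np.allclose(out["t"], traj["t"])
        assert np.allclose(out["x"], traj["x"])
        assert np.allclose(out["y"], traj["y"])

    def test_long_gap_splits_segments(self):
        t = [0, 120, 240, 240 + 7200, 240 + 7320]
        traj = make_traj(np.arange(5) * 100.0, np.zeros(5), t=t)
        out = trajectory.interpolate_time(traj, interval_s=120, max_gap_s=1800)
        assert out["segment"].nunique() == 2
        in_gap = (out["t"] > 240) & (out["t"] < 240 + 7200)
        assert not in_gap.any()

    def test_single_fix_errors(self):
        traj = make_traj([0.0], [0.0])
        with pytest.raises(ValueError):
            trajectory.interpolate_time(traj)

    def test_constant_dt_after(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 3600, 30))
        traj = make_traj(rng.normal(0, 500, 30), rng.normal(0, 500, 30), t=t)
        out = trajectory.interpolate_time(traj, interval_s=120, max_gap_s=1e9)
        assert np.allclose(np.diff(out["t"]), 120.0)


class TestRediscretizeSpace:
    def test_straight_path(self):
        traj = make_traj(np.arange(0, 1001, 300, dtype=float)[:4].tolist() + [1000.0], np.zeros(5))
        out = trajectory.rediscretize_space(traj, step_m=500)
        assert np.allclose(out["x"], [0, 500, 1000])
        assert np.allclose(out["y"], 0)

    def test_constant_spacing_on_random_walks(self):
        rng = np.random.default_rng(1)
        for seed in range(3):
            traj = make_traj(
                np.cumsum(rng.normal(0, 400, 80)), np.cumsum(rng.normal(0, 400, 80))
            )
            out = trajectory.rediscretize_space(traj, step_m=500)
            d = np.hypot(np.diff(out["x"]), np.diff(out["y"]))
            # spacing is along-path; on convex (monotone) pieces it equals the
            # planar distance; generally planar distance <= 500
            assert (d <= 500 + 1e-6).all()
        straight = make_traj(np.linspace(0, 5000, 40), np.zeros(40))
        d = np.hypot(
            np.diff(trajectory.rediscretize_space(straight, 500)["x"]),
            np.diff(trajectory.rediscretize_space(straight, 500)["y"]),
        )
        assert np.allclose(d, 500, atol=1e-6)

    def test_l_shaped_path(self):
        # east 1,000 m then north 500 m; steps of 500 land at the corner walk
        traj = make_traj([0, 1000, 1000], [0, 0, 500], t=[0, 100, 150])
        out = trajectory.rediscretize_space(traj, step_m=500)
        assert len(out) == 4
        assert np.allclose(out[["x", "y"]].to_numpy(), [[0, 0], [500, 0], [1000, 0], [1000, 500]])

    def test_short_path_single_point(self, caplog):
        traj = make_traj([0, 100], [0, 0])
        with caplog.at_level("WARNING"):
            out = trajectory.rediscretize_space(traj, step_m=500)
        assert len(out) == 1


class TestComputeMetrics:
    def test_collinear_turn_zero(self):
        traj = make_traj([0, 100, 200], [0, 0, 0])
        out = trajectory.compute_metrics(traj)
        assert out["turn"].iloc[1] == pytest.approx(0.0)

    def test_speed_arithmetic(self):
        traj = make_traj([0, 1200, 2400], [0, 0, 0], interval=120)
        out = trajectory.compute_metrics(traj)
        assert out["speed"].iloc[1] == pytest.approx(10.0)
        assert np.isnan(out["speed"].iloc[0])

    def test_tortuosity_straight_is_one(self):
        traj = make_traj(np.arange(9) * 100.0, np.zeros(9))
        out = trajectory.compute_metrics(traj, tort_window=4)
        assert out["tortuosity"].iloc[4] == pytest.approx(1.0)
        assert out["tortuosity"].iloc[[0, 3, 5, 8]].isna().all()

    def test_right_angle_turn_ccw_positive(self):
        traj = make_traj([0, 1, 1], [0, 0, 1])
        out = trajectory.compute_metrics(traj)
        assert out["turn"].iloc[1] == pytest.approx(np.pi / 2)

    def test_zero_step_turn_undefined(self):
        traj = make_traj([0, 100, 100, 200], [0, 0, 0, 0])
        out = trajectory.compute_metrics(traj)
        assert np.isnan(out["turn"].iloc[1])
        assert np.isnan(out["turn"].iloc[2])

    def test_tortuosity_le_one_random(self):
        rng = np.random.default_rng(5)
        traj = make_traj(np.cumsum(rng.normal(0, 300, 60)), np.cumsum(rng.normal(0, 300, 60)))
        out = trajectory.compute_metrics(traj)
        tort = out["tortuosity"].dropna()
        assert len(tort) == 60 - 8
        assert (tort <= 1 + 1e-12).all()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.normal(0, 300, 40))
        y = np.cumsum(rng.normal(0, 300, 40))
        a = trajectory.compute_metrics(make_traj(x, y))
        th = 0.7
        xr = 1e5 + x * np.cos(th) - y * np.sin(th)
        yr = -3e4 + x * np.sin(th) + y * np.cos(th)
        b = trajectory.compute_metrics(make_traj(xr, yr))
        for col in ("step_len", "speed", "accel", "turn", "tortuosity"):
            assert np.allclose(a[col], b[col], equal_nan=True, atol=1e-8), col
        # reflection flips the turn sign only
        c = trajectory.compute_metrics(make_traj(x, -y))
        assert np.allclose(a["turn"], -c["turn"], equal_nan=True, atol=1e-8)
        assert np.allclose(a["step_len"], c["step_len"], equal_nan=True)


class TestFiltersAndTrips:
    def _daylight_traj(self, dists):
        # place fixes east of the colony at given distances, local noon
        cx, cy = geo.project(*COLONY, 30)
        x = cx + np.asarray(dists, float)
        y = np.full(len(dists), cy)
        t = 1434368400.0 + 120 * np.arange(len(dists))
        lon, lat = geo.unproject(x, y, 30)
        df = pd.DataFrame(
            {"bird_id": "b", "segment": 0, "t": t, "x": x, "y": y, "lon": lon, "lat": lat}
        )
        df.attrs["interval_s"] = 120.0
        return df

    def test_colony_radius_cut(self):
        traj = self._daylight_traj([4999.0, 5001.0])
        out = trajectory.apply_filters(traj, COLONY)
        assert not out["valid"].iloc[0]
        assert out["valid"].iloc[1]

    def test_night_cut(self):
        traj = self._daylight_traj([8000.0, 8000.0])
        traj.loc[1, "t"] += 12 * 3600  # local midnight
        out = trajectory.apply_filters(traj, COLONY)
        assert out["valid"].iloc[0]
        assert not out["valid"].iloc[1]

    def test_all_daylight_far_colony_all_valid(self):
        traj = self._daylight_traj(np.linspace(2e4, 3e4, 10))
        out = trajectory.apply_filters(traj, COLONY)
        assert out["valid"].all()

    def test_missing_colony_errors(self):
        traj = self._daylight_traj([8000.0])
        with pytest.raises(ValueError):
            trajectory.apply_filters(traj, None)

    def test_trip_split_at_colony_visit(self):
        d = [20000] * 5 + [1000] * 3 + [20000] * 5
        traj = self._daylight_traj(d)
        out = trajectory.apply_filters(traj, COLONY)
        out = trajectory.assign_trips(out)
        trips = out.loc[out["dist_colony"] > 5000, "trip_id"]
        assert trips.nunique() == 2

    def test_short_colony_touch_does_not_split(self):
        d = [20000] * 5 + [1000] * 2 + [20000] * 5
        traj = self._daylight_traj(d)
        out = trajectory.apply_filters(traj, COLONY)
        out = trajectory.assign_trips(out)
        assert out["trip_id"].nunique() == 1
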