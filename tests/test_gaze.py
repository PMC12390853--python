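"""Gaze engine tests: filter oracles, cone geometry, stabilization, entropy."""

import math

import numpy as np
import pytest

from trimanus.config import SessionConfig
from trimanus.gaze import (CONE_HALF_ANGLE_DEG, FixationMap, KalmanFilter,
                           TargetLock, angular_offset_deg, cone_candidates,
                           filter_gaze, gaze_entropy, gaze_kalman, lock_target,
                           stabilize)
from trimanus.synthetic import gen_gaze


class FakeActivation:
    def __init__(self, accepted=True, time=1.0):
        self.accepted = accepted
        self.time = time


def scalar_filter(q, r, p0=1.0):
    return KalmanFilter(A=[[1.0]], H=[[1.0]], Q=[[q]], R=[[r]],
                        x0=[0.0], P0=[[p0]])


class TestKalman:
    def test_small_r_posterior_tracks_observation(self):
        kf = scalar_filter(q=0.01, r=1e-12)
        st = kf.step(np.array([5.0]))
        assert st.x[0] == pytest.approx(5.0, abs=1e-6)

    def test_riccati_fixed_point(self):
        # scalar random walk: steady-state variance (-q + sqrt(q^2+4qr))/2
        q, r = 0.01, 0.25
        kf = scalar_filter(q, r)
        for _ in range(200):
            kf.step(np.array([0.0]))
        p_expected = (-q + math.sqrt(q**2 + 4 * q * r)) / 2
        assert p_expected == pytest.approx(0.04525, abs=5e-6)
        assert kf.state.P[0, 0] == pytest.approx(p_expected, abs=1e-6)
        m = kf.state.P[0, 0] + q
        gain = m / (m + r)
        assert gain == pytest.approx(0.18103, abs=5e-5)

    def test_constant_observations_zero_velocity(self):
        kf = gaze_kalman(dt=1 / 120)
        for _ in range(1000):
            kf.step(np.array([3.0, -2.0]))
        assert abs(kf.state.x[2]) < 1e-3 and abs(kf.state.x[3]) < 1e-3
        assert kf.state.x[0] == pytest.approx(3.0, abs=1e-3)

    def test_missing_observation_predict_only(self):
        kf = gaze_kalman(dt=1 / 120)
        kf.step(np.array([1.0, 1.0]))
        p_before = kf.state.P.copy()
        st = kf.step(np.array([np.nan, np.nan]))
        assert st.innovation is None
        assert np.all(np.diag(st.P) >= np.diag(p_before) - 1e-15)

    def test_batch_information_filter_oracle(self, rng):
        """Sequential filter equals the batch MAP solution on 10 steps."""
        dt = 0.1
        A = np.array([[1.0, dt], [0.0, 1.0]])
        H = np.array([[1.0, 0.0]])
        Q = np.diag([1e-4, 1e-2])
        R = np.array([[0.25]])
        x0 = np.array([0.0, 0.0])
        P0 = np.eye(2)
        n = 10
        zs = rng.normal(0, 1, (n, 1))

        kf = KalmanFilter(A, H, Q, R, x0, P0)
        for z in zs:
            kf.step(z)

        # batch weighted least squares over all states
        dim = 2 * (n + 1)
        rows, rhs = [], []

        def add(block_rows, block_rhs):
            rows.extend(block_rows)
            rhs.extend(block_rhs)

        sqrtP0 = np.linalg.inv(np.linalg.cholesky(P0))
        blk = np.zeros((2, dim))
        blk[:, :2] = sqrtP0
        add(blk, sqrtP0 @ x0)
        sqrtQ = np.linalg.inv(np.linalg.cholesky(Q))
        sqrtR = np.linalg.inv(np.linalg.cholesky(R))
        for k in range(n):
            blk = np.zeros((2, dim))
            blk[:, 2 * k:2 * k + 2] = -sqrtQ @ A
            blk[:, 2 * k + 2:2 * k + 4] = sqrtQ
            add(blk, np.zeros(2))
            blk = np.zeros((1, dim))
            blk[:, 2 * k + 2:2 * k + 4] = sqrtR @ H
            add(blk, sqrtR @ zs[k])
        solution, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        x_batch = solution[-2:]
        assert np.allclose(kf.state.x, x_batch, atol=1e-8)

    def test_innovation_consistency_on_generative_data(self, rng):
        """Normalized innovation squared near its chi^2 expectation."""
        dt = 1 / 120
        kf = gaze_kalman(dt)
        truth = np.zeros(4)
        truth[:2] = [1.0, -1.0]
        kf.state.x = truth.copy()
        kf.state.P = np.eye(4) * 1e-6
        A, Q, H = kf.A, kf.Q, kf.R  # noqa: F841  (A/Q reused below)
        nis = []
        for _ in range(2000):
            w = rng.multivariate_normal(np.zeros(4), kf.Q)
            truth = kf.A @ truth + w
            z = truth[:2] + rng.normal(0, 0.5, 2)
            st = kf.step(z)
            v = st.innovation
            s = st.innovation_cov
            nis.append(float(v @ np.linalg.solve(s, v)))
        mean_nis = np.mean(nis) / 2  # per observation dimension
        assert 0.5 < mean_nis < 1.5

    def test_filter_gaze_reduces_noise_on_steady_fixation(self):
        from trimanus.config import SceneSpec

        # single-target scene -> constant true gaze; the filter should beat
        # the raw observation noise once converged
        scene = SceneSpec(sphere_start={"s3": (0.0, 1.0, 0.8)},
                          sphere_target={"s3": (0.0, 1.2, 0.8)},
                          manual_spheres=("s3", "s3"))
        cfg = SessionConfig(seed=5, trial_duration=30.0, gaze_dropout=0.0,
                            scene=scene)
        stream, _ = gen_gaze(cfg)
        out = filter_gaze(stream)
        late = stream.times > 10.0
        filt = np.stack([out["x"], out["y"]], axis=1)
        resid_filt = filt[late] - stream.true_values[late]
        resid_raw = stream.values[late] - stream.true_values[late]
        assert np.abs(resid_filt).std() < np.abs(resid_raw).std()

    def test_filter_gaze_handles_dropout(self):
        cfg = SessionConfig(seed=6, trial_duration=10.0, gaze_dropout=0.1)
        stream, _ = gen_gaze(cfg)
        out = filter_gaze(stream)
        assert np.isfinite(out["x"]).all() and np.isfinite(out["y"]).all()
        assert np.isnan(out["innovation"][~stream.valid]).all()


class TestCone:
    targets = {"a": (0.0, 0.0), "b": (10.0, 0.0), "c": (0.0, 20.0),
               "far": (50.0, 0.0)}

    def test_on_axis_target_rank_one(self):
        ranked = cone_candidates((0.0, 0.0), self.targets)
        assert ranked[0] == ("a", pytest.approx(0.0))

    def test_beyond_half_angle_excluded(self):
        ranked = cone_candidates((0.0, 0.0), self.targets)
        assert all(tid != "far" for tid, _ in ranked)

    def test_ranking_by_offset(self):
        ranked = cone_candidates((0.0, 0.0), {"near": (10.0, 0.0),
                                              "mid": (20.0, 0.0)})
        assert [tid for tid, _ in ranked] == ["near", "mid"]

    def test_full_angle_mode_halves_limit(self):
        ranked = cone_candidates((0.0, 0.0), {"t": (30.0, 0.0)},
                                 half_angle=45.0, full_angle=True)
        assert ranked == []

    def test_empty_scene(self):
        assert cone_candidates((0.0, 0.0), {}) == []

    def test_angular_offset_symmetry(self):
        assert angular_offset_deg((5.0, 3.0), (8.0, -2.0)) == pytest.approx(
            angular_offset_deg((8.0, -2.0), (5.0, 3.0)))


class TestLockTarget:
    def test_lock_rank_one(self):
        lock = lock_target([("a", 2.0), ("b", 8.0)], FakeActivation(time=4.5))
        assert lock is not None
        assert lock.target_id == "a" and lock.time == 4.5
        assert lock.offset_deg == 2.0

    def test_rejected_activation_no_lock(self):
        assert lock_target([("a", 2.0)], FakeActivation(accepted=False)) is None

    def test_empty_cone_no_lock(self):
        assert lock_target([], FakeActivation()) is None

    def test_offset_exceeding_half_angle_invalid(self):
        with pytest.raises(ValueError):
            TargetLock("x", 0.0, CONE_HALF_ANGLE_DEG, 46.0)


class TestStabilize:
    dt = 1 / 120

    def test_constant_input_fixed_point(self):
        out = stabilize(np.full(200, 3.5), c=0.75, dt=self.dt)
        assert np.allclose(out, 3.5)

    def test_step_response_no_overshoot(self):
        x = np.concatenate([np.zeros(50), np.ones(400)])
        out = stabilize(x, c=0.75, dt=self.dt)
        assert out.max() <= 1.0 + 1e-6
        assert np.all(np.diff(out[50:]) >= -1e-9)
        assert out[-1] == pytest.approx(1.0, abs=0.01)

    def test_higher_damping_lower_velocity_variance(self, rng):
        x = rng.normal(0, 1, 2000)
        v_low = np.diff(stabilize(x, c=0.65, dt=self.dt))
        v_high = np.diff(stabilize(x, c=0.85, dt=self.dt))
        assert v_high.var() < v_low.var()

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = stabilize(np.ones(10), c=0.95, dt=self.dt)
        assert np.allclose(out, 1.0)


class TestEntropy:
    def test_point_mass_zero(self):
        probs = np.zeros((8, 8))
        probs[3, 3] = 1.0
        assert gaze_entropy(FixationMap(probs)) == 0.0

    def test_uniform_16_bins(self):
        probs = np.full((4, 4), 1 / 16)
        assert gaze_entropy(FixationMap(probs)) == pytest.approx(math.log(16))

    def test_two_equal_bins(self):
        assert gaze_entropy(np.array([0.5, 0.5])) == pytest.approx(math.log(2))

    def test_unnormalized_raises(self):
        with pytest.raises(ValueError):
            gaze_entropy(np.array([0.5, 0.2]))

    def test_bounds(self, rng):
        for _ in range(20):
            p = rng.random(64)
            p /= p.sum()
            h = gaze_entropy(p)
            assert 0.0 <= h <= math.log(64) + 1e-12

    def test_from_points_normalized(self, rng):
        pts = rng.normal(0, 10, (500, 2))
        fm = FixationMap.from_points(pts)
        assert fm.probs.sum() == pytest.approx(1.0)
        assert gaze_entropy(fm) > 0
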