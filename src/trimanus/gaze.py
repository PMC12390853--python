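"""Gaze filtering, cone targeting, stabilization, and gaze entropy.

The filter is a linear-Gaussian state-space model with a constant-velocity
transition and a position-only observation: state [x, y, vx, vy] in
degrees, process noise 0.1^2 driving the velocity components, observation
noise 0.5^2 per axis.  Targets are selected inside a 45-degree cone about
the filtered gaze ray and ranked by angular offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .streams import SampleStream

PROCESS_SD_DEG = 0.1
OBS_SD_DEG = 0.5
CONE_HALF_ANGLE_DEG = 45.0
DAMPING_RANGE = (0.65, 0.85)


class FilterError(RuntimeError):
    pass


@dataclass
class GazeState:
    x: np.ndarray           # state mean
    P: np.ndarray           # state covariance
    innovation: np.ndarray | None = None
    innovation_cov: np.ndarray | None = None


class KalmanFilter:
    """Generic linear Kalman filter (predict/update per step)."""

    def __init__(self, A: np.ndarray, H: np.ndarray, Q: np.ndarray,
                 R: np.ndarray, x0: np.ndarray, P0: np.ndarray):
        self.A = np.asarray(A, float)
        self.H = np.asarray(H, float)
        self.Q = np.asarray(Q, float)
        self.R = np.asarray(R, float)
        self.state = GazeState(np.asarray(x0, float).copy(),
                               np.asarray(P0, float).copy())

    def step(self, z: np.ndarray | None) -> GazeState:
        """One predict(+update) step; ``z`` of None/NaN -> predict only."""
        x, P = self.state.x, self.state.P
        x = self.A @ x
        P = self.A @ P @ self.A.T + self.Q
        innovation = innovation_cov = None
        if z is not None:
            z = np.asarray(z, float)
            if not np.isnan(z).any():
                innovation = z - self.H @ x
                S = self.H @ P @ self.H.T + self.R
                try:
                    K = P @ self.H.T @ np.linalg.inv(S)
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise FilterError("singular innovation covariance") from exc
                x = x + K @ innovation
                P = (np.eye(len(x)) - K @ self.H) @ P
                P = 0.5 * (P + P.T)
                innovation_cov = S
        if not np.all(np.linalg.eigvalsh(P) > -1e-9):
            raise FilterError("state covariance lost positive semidefiniteness")
        self.state = GazeState(x, P, innovation, innovation_cov)
        return self.state

    def run(self, observations) -> list[GazeState]:
        return [self.step(z) for z in observations]


def gaze_kalman(dt: float, process_sd: float = PROCESS_SD_DEG,
                obs_sd: float = OBS_SD_DEG,
                x0: np.ndarray | None = None) -> KalmanFilter:
    """Constant-velocity filter for 2-D gaze in degrees."""
    A = np.eye(4)
    A[0, 2] = A[1, 3] = dt
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    q = process_sd**2
    # white-noise acceleration discretization per axis
    g = np.array([dt**2 / 2, dt])
    Qb = q * np.outer(g, g)
    Q = np.zeros((4, 4))
    for axis in range(2):
        idx = np.array([axis, axis + 2])
        Q[np.ix_(idx, idx)] = Qb
    R = np.eye(2) * obs_sd**2
    if x0 is None:
        x0 = np.zeros(4)
    P0 = np.diag([25.0, 25.0, 100.0, 100.0])
    return KalmanFilter(A, H, Q, R, x0, P0)


def filter_gaze(stream: SampleStream, process_sd: float = PROCESS_SD_DEG,
                obs_sd: float = OBS_SD_DEG) -> dict[str, np.ndarray]:
    """Filter an observed gaze stream; NaN samples take predict-only steps.

    Returns arrays: t, x, y, vx, vy, innovation (norm, NaN when missing).
    """
    kf = gaze_kalman(1.0 / stream.rate, process_sd, obs_sd)
    first = next((v for v in stream.values if not np.isnan(v).any()), None)
    if first is not None:
        kf.state.x[:2] = first
    out = {k: np.empty(stream.n) for k in ("x", "y", "vx", "vy", "innovation")}
    for i, z in enumerate(stream.values):
        st = kf.step(z)
        out["x"][i], out["y"][i], out["vx"][i], out["vy"][i] = st.x
        out["innovation"][i] = (np.nan if st.innovation is None
                                else float(np.linalg.norm(st.innovation)))
    out["t"] = stream.times
    return out


def direction_vector(x_deg: float, y_deg: float) -> np.ndarray:
    """Unit 3-D vector for a (horizontal, vertical) view angle pair."""
    v = np.array([math.tan(math.radians(x_deg)), math.tan(math.radians(y_deg)), 1.0])
    return v / np.linalg.norm(v)


def angular_offset_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    dot = float(np.clip(direction_vector(*a) @ direction_vector(*b), -1.0, 1.0))
    return math.degrees(math.acos(dot))


def cone_candidates(gaze_deg: tuple[float, float],
                    targets: dict[str, tuple[float, float]],
                    half_angle: float = CONE_HALF_ANGLE_DEG,
                    full_angle: bool = False) -> list[tuple[str, float]]:
    """Targets inside the visual cone, ranked by angular offset.

    ``full_angle=True`` reinterprets ``half_angle`` as the cone's full
    opening angle.
    """
    if not targets:
        return []
    limit = half_angle / 2 if full_angle else half_angle
    hits = [(tid, angular_offset_deg(gaze_deg, tdir)) for tid, tdir in targets.items()]
    hits = [(tid, off) for tid, off in hits if off <= limit]
    return sorted(hits, key=lambda item: item[1])


@dataclass
class TargetLock:
    target_id: str
    time: float
    half_angle: float
    offset_deg: float

    def __post_init__(self) -> None:
        if self.offset_deg > self.half_angle + 1e-9:
            raise ValueError("lock offset exceeds cone half-angle")


def lock_target(candidates: list[tuple[str, float]], activation,
                half_angle: float = CONE_HALF_ANGLE_DEG) -> TargetLock | None:
    """Lock the rank-1 in-cone target at an accepted activation."""
    if not getattr(activation, "accepted", False) or not candidates:
        return None
    tid, offset = candidates[0]
    return TargetLock(tid, getattr(activation, "time", 0.0), half_angle, offset)


def stabilize(values: np.ndarray, c: float, dt: float,
              omega0: float = 12.0) -> np.ndarray:
    """Critically damped second-order tracker of the raw gaze signal.

    ``c`` is the (unitless) damping setting in the calibrated 0.65-0.85
    range; larger values lower the tracker bandwidth and hence the output
    velocity variance.  Out-of-range values are clamped with a warning.
    """
    lo, hi = DAMPING_RANGE
    if not lo <= c <= hi:
        warnings.warn(f"damping {c} outside calibrated range {DAMPING_RANGE}; clamping")
        c = min(max(c, lo), hi)
    omega = omega0 * (1.5 - c)
    values = np.atleast_2d(np.asarray(values, float).T).T
    y = values[0].astype(float).copy()
    v = np.zeros_like(y)
    out = np.empty_like(values)
    for i, target in enumerate(values):
        a = omega**2 * (target - y) - 2.0 * omega * v
        v = v + a * dt
        y = y + v * dt
        out[i] = y
    return out.squeeze()


@dataclass
class FixationMap:
    """Normalized spatial occupancy histogram of fixation positions."""

    probs: np.ndarray
    edges_x: np.ndarray = field(default_factory=lambda: np.array([]))
    edges_y: np.ndarray = field(default_factory=lambda: np.array([]))

    @classmethod
    def from_points(cls, points: np.ndarray,
                    bounds: tuple[float, float, float, float] = (-45, 45, -45, 45),
                    bins: int = 8) -> "FixationMap":
        points = np.asarray(points, float)
        points = points[~np.isnan(points).any(axis=1)]
        hist, ex, ey = np.histogram2d(
            points[:, 0], points[:, 1], bins=bins,
            range=[[bounds[0], bounds[1]], [bounds[2], bounds[3]]])
        total = hist.sum()
        probs = hist / total if total > 0 else hist
        return cls(probs, ex, ey)


def gaze_entropy(fixation_map: FixationMap | np.ndarray) -> float:
    """Shannon entropy (nats) of the fixation distribution; 0*log0 = 0."""
    p = fixation_map.probs if isinstance(fixation_map, FixationMap) else np.asarray(fixation_map, float)
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fixation map not normalized (sum={total})")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
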