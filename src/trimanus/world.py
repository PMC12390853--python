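"""Three-sphere scene simulation and objective trial metrics.

Kinematic point-hand physics: the two manual spheres track their
controller poses 1:1; the virtual hand approaches its locked sphere at a
capped speed (optionally with proportional stabilizing control when the
workload adaptation is active), captures it on contact and carries it to
the wireframe target.  Success requires all three spheres within 5 mm of
their targets simultaneously for a continuous second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arbitration import ArbitrationConfig, AuthorityState, authority_weights, resolve
from .config import SceneSpec, SessionConfig
from .eeg import feature_stream, frames_to_table, scale_attention
from .gate import GateConfig, detect_activations
from .gaze import cone_candidates, filter_gaze, lock_target
from .load import AdaptationState

from .synthetic import generate_session

SPHERE_RADIUS = 0.05
SUCCESS_TOL_M = 0.005
SUCCESS_HOLD_S = 1.0
ARRIVE_TOL = 0.002  # m, direct-mode stopping deadband


@dataclass
class Scene:
    positions: dict[str, np.ndarray]
    targets: dict[str, np.ndarray]
    distractors: int = 0
    radius: float = SPHERE_RADIUS

    @classmethod
    def from_spec(cls, spec: SceneSpec) -> "Scene":
        return cls(positions={k: np.asarray(v, float).copy()
                              for k, v in spec.sphere_start.items()},
                   targets={k: np.asarray(v, float).copy()
                            for k, v in spec.sphere_target.items()},
                   distractors=spec.distractors)

    def errors(self) -> dict[str, float]:
        return {k: float(np.linalg.norm(self.positions[k] - self.targets[k]))
                for k in self.positions}


@dataclass
class VirtualHandState:
    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    engaged: str | None = None
    vmax: float = 0.5
    stiffness: float = 0.0


def step_virtual_hand(hand: VirtualHandState, target_point: np.ndarray,
                      dt: float, disturbance: np.ndarray | None = None) -> None:
    """Advance the virtual hand toward a point, enforcing the speed cap.

    With stabilizing stiffness the hand runs damped proportional control
    (acceleration = k * error - damping * velocity); otherwise it moves at
    the capped speed directly along the error vector.
    """
    error = target_point - hand.position
    dist = float(np.linalg.norm(error))
    if hand.stiffness > 0:
        # critically damped proportional control; the N/mm stiffness maps to
        # an acceleration gain since no mass model exists
        k_acc = hand.stiffness * 400.0
        damping = 2.0 * math.sqrt(k_acc)
        accel = k_acc * error - damping * hand.velocity
        hand.velocity = hand.velocity + accel * dt
    else:
        # direct mode: drive at the capped speed, hold inside a 2 mm deadband
        if dist > ARRIVE_TOL:
            hand.velocity = error / dist * min(hand.vmax, dist / dt)
        else:
            hand.velocity = np.zeros(3)
    if disturbance is not None:
        hand.velocity = hand.velocity + disturbance
    speed = float(np.linalg.norm(hand.velocity))
    if speed > hand.vmax:
        hand.velocity = hand.velocity * (hand.vmax / speed)
    step = hand.velocity * dt
    if dist > 1e-12 and hand.stiffness == 0 and float(np.linalg.norm(step)) > dist:
        step = error  # do not overshoot in direct mode
    hand.position = hand.position + step


def step_world(scene: Scene, manual_positions: dict[str, np.ndarray],
               manual_sphere_map: dict[str, str],
               hand: VirtualHandState, authority: AuthorityState,
               adaptation: AdaptationState, lock_id: str | None,
               dt: float, disturbance: np.ndarray | None = None) -> None:
    """One tick of scene kinematics."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    for hand_name, sphere_id in manual_sphere_map.items():
        if hand_name in manual_positions and sphere_id in scene.positions:
            scene.positions[sphere_id] = np.asarray(manual_positions[hand_name], float).copy()
    hand.vmax = adaptation.vmax
    hand.stiffness = adaptation.stiffness
    if authority.controller == "virtual" and lock_id is not None:
        if hand.engaged is None:
            target_point = scene.positions[lock_id]
            step_virtual_hand(hand, target_point, dt, disturbance)
            if float(np.linalg.norm(hand.position - scene.positions[lock_id])) <= scene.radius:
                hand.engaged = lock_id
        else:
            step_virtual_hand(hand, scene.targets[hand.engaged], dt, disturbance)
            scene.positions[hand.engaged] = hand.position.copy()


def check_success(times: np.ndarray, errors: np.ndarray,
                  tol: float = SUCCESS_TOL_M, hold: float = SUCCESS_HOLD_S,
                  ) -> tuple[bool, float | None]:
    """First time all sphere errors stay <= tol for a continuous hold.

    ``errors`` is (n_ticks, n_spheres); returns (success, time at which the
    hold completes).
    """
    times = np.asarray(times, float)
    ok = (np.asarray(errors, float) <= tol).all(axis=1)
    start = None
    for i, good in enumerate(ok):
        if good:
            if start is None:
                start = times[i]
            if times[i] - start >= hold - 1e-9:
                return True, float(times[i])
        else:
            start = None
    return False, None


def path_efficiency(positions: np.ndarray) -> float | None:
    """100 * straight-line displacement / arc length; None for no motion."""
    positions = np.asarray(positions, float)
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    arc = float(steps.sum())
    if arc <= 1e-12:
        return None
    chord = float(np.linalg.norm(positions[-1] - positions[0]))
    return 100.0 * chord / arc


def log_dimensionless_jerk(positions: np.ndarray, dt: float) -> float | None:
    """Negated log dimensionless jerk; higher = smoother."""
    positions = np.asarray(positions, float)
    if len(positions) < 5:
        return None
    vel = np.gradient(positions, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    v_peak = float(speed.max())
    if v_peak <= 1e-12:
        return None
    acc = np.gradient(vel, dt, axis=0)
    jerk = np.gradient(acc, dt, axis=0)
    duration = dt * (len(positions) - 1)
    dj = float((np.linalg.norm(jerk, axis=1) ** 2).sum() * dt) * duration**3 / v_peak**2
    return -math.log(max(dj, 1e-300))


def speed_cross_correlation(speed_a: np.ndarray, speed_b: np.ndarray) -> float | None:
    """Max of the normalized cross-correlation between two speed profiles."""
    a = np.asarray(speed_a, float) - np.mean(speed_a)
    b = np.asarray(speed_b, float) - np.mean(speed_b)
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na <= 1e-12 or nb <= 1e-12:
        return None
    corr = np.correlate(a / na, b / nb, mode="full")
    return float(corr.max())


@dataclass
class TrialResult:
    success: bool
    success_time: float | None
    completion_time: float
    spatial_error_mm: dict[str, float]
    mean_error_mm: float
    efficiency: float | None
    jerk_score: float | None
    coordination: float | None
    tasks_completed: int
    precision: float

    def metric_row(self) -> dict[str, float]:
        return {
            "tasks_completed": self.tasks_completed,
            "spatial_error_mm": self.mean_error_mm,
            "movement_efficiency": np.nan if self.efficiency is None else self.efficiency,
            "task_success": float(self.success),
            "completion_time": self.completion_time,
            "jerk_score": np.nan if self.jerk_score is None else self.jerk_score,
            "coordination": np.nan if self.coordination is None else self.coordination,
            "control_precision": self.precision,
        }


def trial_metrics(times: np.ndarray, scene: Scene,
                  sphere_trace: dict[str, np.ndarray],
                  hand_trace: np.ndarray,
                  manual_speed: np.ndarray, virtual_speed: np.ndarray,
                  success: bool, success_time: float | None) -> TrialResult:
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    errors_mm = {k: float(np.linalg.norm(trace[-1] - scene.targets[k])) * 1000.0
                 for k, trace in sphere_trace.items()}
    mean_error = float(np.mean(list(errors_mm.values())))
    efficiencies = [path_efficiency(trace) for trace in sphere_trace.values()]
    efficiencies = [e for e in efficiencies if e is not None]
    efficiency = float(np.mean(efficiencies)) if efficiencies else None
    jerk = log_dimensionless_jerk(hand_trace, dt)
    coordination = speed_cross_correlation(manual_speed, virtual_speed)
    tasks = sum(1 for v in errors_mm.values() if v <= SUCCESS_TOL_M * 1000.0)
    precision = float(np.clip(10.0 - mean_error, 1.0, 10.0))
    completion = success_time if success_time is not None else float(times[-1])
    return TrialResult(success, success_time, completion, errors_mm, mean_error,
                       efficiency, jerk, coordination, tasks, precision)


def run_trial(config: SessionConfig, run: int = 0, tri_manual: bool = True,
              gate_cfg: GateConfig | None = None,
              arb_cfg: ArbitrationConfig | None = None,
              adaptation: AdaptationState | None = None,
              actuation_noise: float = 0.0,
              ) -> tuple[TrialResult, dict]:
    """Simulate one trial end to end and compute its metrics.

    With ``tri_manual=False`` the virtual channel is disabled (two-hand
    baseline): the third sphere never moves.
    """
    streams, gt = generate_session(config, run)
    scene = Scene.from_spec(config.scene)
    spec = config.scene
    dt = 1.0 / config.pose_rate
    n_ticks = streams["pose"].n
    rng = np.random.default_rng([config.seed, run, 44])

    frames = feature_stream(streams["eeg"])
    att = scale_attention(np.array([f.attention for f in frames]))
    events = (detect_activations(frames, gate_cfg, attention_scaled=att)
              if tri_manual else [])
    accepted = [e for e in events if e.accepted]

    filtered = filter_gaze(streams["gaze"])
    gaze_targets = spec.gaze_targets()
    arb_cfg = arb_cfg or ArbitrationConfig()
    adaptation = adaptation or AdaptationState()

    hand = VirtualHandState(position=np.array([0.0, 1.1, 0.3]),
                            vmax=adaptation.vmax, stiffness=adaptation.stiffness)
    manual_map = dict(zip(("left", "right"), spec.manual_spheres))

    times = streams["pose"].times
    sphere_trace = {k: np.empty((n_ticks, 3)) for k in scene.positions}
    hand_trace = np.empty((n_ticks, 3))
    authority_trace = []
    lock_id: str | None = None
    lock_time = -math.inf
    event_idx = 0
    last_manual_move = -math.inf
    prev_left = streams["pose"].values[0, :3].copy()

    for i, t in enumerate(times):
        pose = streams["pose"].values[i]
        manual_positions = {"left": pose[:3], "right": pose[3:]}

        if float(np.linalg.norm(pose[:3] - prev_left)) > 1e-6:
            last_manual_move = t
        prev_left = pose[:3].copy()

        gi = min(int(round(t * config.gaze_rate)), len(filtered["x"]) - 1)
        gaze_dir = (filtered["x"][gi], filtered["y"][gi])
        candidates = cone_candidates(gaze_dir, gaze_targets)

        while event_idx < len(accepted) and accepted[event_idx].time <= t:
            lock = lock_target(candidates, accepted[event_idx])
            if lock is not None:
                lock_id, lock_time = lock.target_id, t
            event_idx += 1

        eps_bci = float(att[min(int(t * 8), len(att) - 1)]) / 100.0
        t_gaze = min(t - lock_time, arb_cfg.t_cap) if lock_id else 0.0
        t_manual = min(max(t - last_manual_move, 0.0), arb_cfg.t_cap)
        weights = authority_weights(eps_bci, t_gaze, t_manual=t_manual, cfg=arb_cfg)
        auth = resolve(weights, [manual_positions["left"], manual_positions["right"]],
                       hand.position, arb_cfg, t=t)
        if not tri_manual:
            auth.controller = "manual"

        disturbance = (rng.normal(0.0, actuation_noise, 3)
                       if actuation_noise > 0 else None)
        step_world(scene, manual_positions, manual_map, hand, auth, adaptation,
                   lock_id, dt, disturbance)

        for k in scene.positions:
            sphere_trace[k][i] = scene.positions[k]
        hand_trace[i] = hand.position
        authority_trace.append(auth)

    err = np.stack([np.linalg.norm(sphere_trace[k] - scene.targets[k], axis=1)
                    for k in sorted(scene.positions)], axis=1)
    success, success_time = check_success(times, err)

    left = streams["pose"].values[:, :3]
    manual_speed = np.linalg.norm(np.gradient(left, dt, axis=0), axis=1)
    virtual_speed = np.linalg.norm(np.gradient(hand_trace, dt, axis=0), axis=1)
    result = trial_metrics(times, scene, sphere_trace, hand_trace,
                           manual_speed, virtual_speed, success, success_time)
    trace = {
        "times": times, "spheres": sphere_trace, "hand": hand_trace,
        "authority": authority_trace, "events": events,
        "frames": frames, "attention_scaled": att, "ground_truth": gt,
        "features_table": frames_to_table(frames),
    }
    return result, trace
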