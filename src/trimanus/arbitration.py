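"""Softmax arbitration of control authority between manual and virtual channels.

Per tick, each modality gets a score ``a * confidence + b * stability_time``;
authority weights are the softmax over the two scores.  Spatial overlap of a
manual hand with the virtual hand's engagement point forces manual override
regardless of the weights, and an exact 0.5 tie resolves to manual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ArbitrationConfig:
    a: float = 4.0              # confidence gain
    b: float = 1.0              # per-second stabilization gain
    overlap_radius: float = 0.10  # m
    eps_manual: float = 1.0
    t_cap: float = 2.0          # s, cap on stabilization times

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("gains a, b must be positive")
        if self.overlap_radius <= 0:
            raise ValueError("overlap_radius must be positive")


@dataclass
class AuthorityState:
    t: float
    scores: dict[str, float]
    weights: dict[str, float]
    controller: str             # 'manual-override' | 'virtual' | 'manual'
    overlap: bool
    handover: bool = False


def _clamp(value: float, lo: float, hi: float, name: str) -> float:
    if value < lo or value > hi:
        warnings.warn(f"{name}={value} outside [{lo}, {hi}]; clamping")
        return min(max(value, lo), hi)
    return value


def authority_weights(eps_bci: float, t_gaze: float,
                      eps_manual: float | None = None, t_manual: float = 0.0,
                      cfg: ArbitrationConfig | None = None) -> dict[str, float]:
    """Softmax weights over the {manual, virtual} modality pair."""
    cfg = cfg or ArbitrationConfig()
    if eps_manual is None:
        eps_manual = cfg.eps_manual
    eps_bci = _clamp(eps_bci, 0.0, 1.0, "eps_bci")
    eps_manual = _clamp(eps_manual, 0.0, 1.0, "eps_manual")
    t_gaze = _clamp(t_gaze, 0.0, cfg.t_cap, "t_gaze")
    t_manual = _clamp(t_manual, 0.0, cfg.t_cap, "t_manual")
    scores = np.array([cfg.a * eps_manual + cfg.b * t_manual,
                       cfg.a * eps_bci + cfg.b * t_gaze])
    scores -= scores.max()
    expd = np.exp(scores)
    w = expd / expd.sum()
    return {"manual": float(w[0]), "virtual": float(w[1])}


def resolve(weights: dict[str, float], hand_positions, virtual_point,
            cfg: ArbitrationConfig | None = None, t: float = 0.0) -> AuthorityState:
    """Pick the controller of the virtual hand for this tick.

    Manual override wins whenever any manual hand lies within the overlap
    radius of the virtual hand's engagement point; otherwise the virtual
    channel is active iff its weight strictly exceeds 0.5.
    """
    cfg = cfg or ArbitrationConfig()
    virtual_point = np.asarray(virtual_point, float)
    overlap = any(
        float(np.linalg.norm(np.asarray(p, float) - virtual_point)) <= cfg.overlap_radius
        for p in hand_positions)
    if overlap:
        controller = "manual-override"
    elif weights["virtual"] > 0.5:
        controller = "virtual"
    else:
        controller = "manual"
    scores = {k: float(np.log(max(v, 1e-300))) for k, v in weights.items()}
    return AuthorityState(t=t, scores=scores, weights=dict(weights),
                          controller=controller, overlap=overlap)


def handover_latency(times: np.ndarray, controllers,
                     preconditions: np.ndarray) -> list[float]:
    """Latency of each authority flip relative to its precondition onset.

    For every tick at which the controller changes while the flip's
    preconditions hold, the latency is the time since the start of the
    contiguous run of satisfied preconditions containing that tick.
    """
    times = np.asarray(times, float)
    preconditions = np.asarray(preconditions, bool)
    latencies: list[float] = []
    run_start: float | None = None
    prev_controller = None
    for i, t in enumerate(times):
        if preconditions[i]:
            if run_start is None:
                run_start = t
        else:
            run_start = None
        if prev_controller is not None and controllers[i] != prev_controller \
                and run_start is not None:
            latencies.append(float(t - run_start))
        prev_controller = controllers[i]
    return latencies


def authority_table(states: list[AuthorityState]):
    import pandas as pd

    return pd.DataFrame([{
        "t": s.t,
        "w_manual": s.weights["manual"],
        "w_virtual": s.weights["virtual"],
        "overlap": int(s.overlap),
        "controller": s.controller,
    } for s in states], columns=["t", "w_manual", "w_virtual", "overlap", "controller"])
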