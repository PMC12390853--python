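"""Three-tier false-trigger mitigation cascade.

Tier 1 (temporal consistency): attention must exceed the effective
threshold continuously for 300 ms; any frame with quality below 150 or
attention at/below threshold resets the timer.  Tier 2 (quality gating):
the threshold rises 20% below quality 100 and triggering is disabled below
quality 50.  Tier 3 (contextual validation): candidates deviating more
than 2.5 SD from the last 60 s of attention values are rejected.  Frames
inside artifact blanking intervals can never fire.  Accepted events start
a 1 s refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eeg import FeatureFrame

#: sentinel effective threshold when triggering is disabled outright
DISABLED = math.inf


@dataclass
class GateConfig:
    base_threshold: float = 80.0   # attention units on the 0-100 scale
    hold_time: float = 0.3         # s
    quality_reset: float = 150.0
    quality_degrade: float = 100.0
    quality_disable: float = 50.0
    degrade_factor: float = 1.2
    context_sigma: float = 2.5
    context_window: float = 60.0   # s
    context_min_history: float = 10.0  # s; shorter buffers pass with a note
    blanking: float = 0.5          # s (informational; blanking flags come in)
    refractory: float = 1.0        # s after an accepted event
    frame_rate: float = 8.0

    def __post_init__(self) -> None:
        if not (self.quality_disable < self.quality_degrade < self.quality_reset <= 200):
            raise ValueError("quality tiers must satisfy disable < degrade < reset <= 200")
        if self.hold_time <= 0:
            raise ValueError("hold_time must be positive")


@dataclass
class ActivationEvent:
    time: float
    attention: float
    threshold: float          # effective threshold at the candidate frame
    run_start: float          # when the tier-1 timer started
    quality: float
    z_context: float | None
    accepted: bool
    reject_tier: str | None = None   # 'temporal' | 'quality' | 'context' | 'blanking'
    notes: list[str] = field(default_factory=list)


def effective_threshold(base: float, quality: float, cfg: GateConfig | None = None) -> float:
    """Quality-scaled activation threshold; ``DISABLED`` below the floor."""
    cfg = cfg or GateConfig(base_threshold=base)
    if not 0.0 <= quality <= 200.0:
        raise ValueError(f"quality {quality} outside [0, 200]")
    if quality < cfg.quality_disable:
        return DISABLED
    if quality < cfg.quality_degrade:
        return base * cfg.degrade_factor
    return base


def temporal_consistency(times: np.ndarray, attention: np.ndarray,
                         quality: np.ndarray, cfg: GateConfig,
                         use_quality_gate: bool = True,
                         ) -> list[tuple[float, float]]:
    """Tier-1 candidate times as (candidate_t, run_start_t) pairs.

    A timer starts at the first frame whose attention exceeds the
    effective threshold; the candidate fires at the first frame at/after
    ``run_start + hold_time`` with the run unbroken.  Quality below 150,
    attention at/below threshold, or a disabled state reset the timer.
    """
    candidates: list[tuple[float, float]] = []
    run_start: float | None = None
    for t, att, q in zip(times, attention, quality):
        thr = (effective_threshold(cfg.base_threshold, q, cfg)
               if use_quality_gate else cfg.base_threshold)
        if math.isinf(thr) or att <= thr or q < cfg.quality_reset:
            run_start = None
            continue
        if run_start is None:
            run_start = t
            continue
        if t - run_start >= cfg.hold_time - 1e-9:
            candidates.append((t, run_start))
            run_start = None
    return candidates


def contextual_validate(candidate_attention: float, buffer: list[tuple[float, float]],
                        cfg: GateConfig) -> tuple[bool, float | None, str | None]:
    """(accept, z score, note). Short or degenerate buffers pass with a note."""
    if not buffer or buffer[-1][0] - buffer[0][0] < cfg.context_min_history:
        return True, None, "context-unchecked"
    vals = np.array([v for _, v in buffer])
    mean, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        return True, None, "context-degenerate"
    z = (candidate_attention - mean) / sd
    return abs(candidate_attention - mean) <= cfg.context_sigma * sd, z, None


def blanking_gate(t: float, blanking_intervals: list[tuple[float, float]]) -> bool:
    """True if the candidate time is blocked by a blanking interval."""
    return any(lo <= t < hi for lo, hi in blanking_intervals)


def detect_activations(frames: list[FeatureFrame], cfg: GateConfig | None = None,
                       attention_scaled: np.ndarray | None = None,
                       use_quality_gate: bool = True,
                       use_context: bool = True,
                       use_blanking: bool = True,
                       ) -> list[ActivationEvent]:
    """Run the full cascade over a feature stream.

    ``attention_scaled`` overrides the frames' attention values (use this
    to feed 0-100-scaled attention).  Tier subsets can be switched off for
    ablation studies; tier 1 is always active.
    """
    cfg = cfg or GateConfig()
    events: list[ActivationEvent] = []
    buffer: list[tuple[float, float]] = []  # (t, attention), non-blanked frames
    run_start: float | None = None
    refractory_until = -math.inf

    for i, frame in enumerate(frames):
        att = float(attention_scaled[i]) if attention_scaled is not None else frame.attention
        t = frame.t

        if not frame.blanked:
            buffer.append((t, att))
            while buffer and buffer[0][0] < t - cfg.context_window:
                buffer.pop(0)

        if t < refractory_until:
            run_start = None
            continue

        thr = (effective_threshold(cfg.base_threshold, frame.quality, cfg)
               if use_quality_gate else cfg.base_threshold)
        if math.isinf(thr) or att <= thr or frame.quality < cfg.quality_reset:
            run_start = None
            continue
        if run_start is None:
            run_start = t
            continue
        if t - run_start < cfg.hold_time - 1e-9:
            continue

        # tier-1 candidate fires at this frame
        event = ActivationEvent(time=t, attention=att, threshold=thr,
                                run_start=run_start, quality=frame.quality,
                                z_context=None, accepted=False)
        run_start = None

        if use_context:
            # exclude the candidate frame itself from its own context
            history = buffer[:-1] if buffer and buffer[-1][0] == t else buffer
            ok, z, note = contextual_validate(att, history, cfg)
            event.z_context = z
            if note:
                event.notes.append(note)
            if not ok:
                event.reject_tier = "context"
                events.append(event)
                continue

        if use_blanking and frame.blanked:
            event.reject_tier = "blanking"
            events.append(event)
            continue

        event.accepted = True
        refractory_until = t + cfg.refractory
        events.append(event)

    return events


def accepted_times(events: list[ActivationEvent]) -> list[float]:
    return [e.time for e in events if e.accepted]


def episode_tpr(events: list[ActivationEvent], episodes,
                tolerance: float = 0.5) -> float:
    """Fraction of ground-truth episodes containing >= 1 accepted event."""
    if not episodes:
        return float("nan")
    hits = 0
    times = accepted_times(events)
    for ep in episodes:
        if any(ep.onset - tolerance <= t <= ep.offset + tolerance for t in times):
            hits += 1
    return hits / len(episodes)


def false_activations_per_min(events: list[ActivationEvent], episodes,
                              duration: float, tolerance: float = 0.5) -> float:
    """Accepted events outside every ground-truth episode, per minute."""
    times = accepted_times(events)
    false = [t for t in times
             if not any(ep.onset - tolerance <= t <= ep.offset + tolerance
                        for ep in episodes)]
    return len(false) / (duration / 60.0)


def events_to_table(events: list[ActivationEvent]):
    import pandas as pd

    return pd.DataFrame([{
        "onset": e.time,
        "attention": e.attention,
        "eff_threshold": e.threshold,
        "z_context": np.nan if e.z_context is None else e.z_context,
        "accepted": int(e.accepted),
        "reject_tier": e.reject_tier or "",
        "notes": ";".join(e.notes),
    } for e in events], columns=["onset", "attention", "eff_threshold",
                                 "z_context", "accepted", "reject_tier", "notes"])
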