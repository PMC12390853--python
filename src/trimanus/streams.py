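"""Sample stream and ground-truth containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SampleStream:
    """Uniformly sampled, timestamped channel data.

    ``values`` is ``(n,)`` for single-channel data or ``(n, k)`` for
    multi-column data (gaze x/y, controller poses).  ``valid`` flags
    per-sample validity (dropout); ``None`` means all samples valid.
    """

    name: str
    rate: float
    t0: float
    values: np.ndarray
    units: str
    columns: tuple[str, ...] | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != len(self.values):
                raise ValueError("valid flags must match sample count")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        return int(round((t - self.t0) * self.rate))

    def segment(self, t_start: float, t_stop: float) -> np.ndarray:
        i0 = max(0, self.index_at(t_start))
        i1 = min(self.n, self.index_at(t_stop))
        return self.values[i0:i1]


@dataclass
class Episode:
    """A ground-truth interval (attention episode, artifact, fixation, reach)."""

    kind: str
    onset: float
    duration: float
    value: float | str = ""
    detail: dict = field(default_factory=dict)

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset


@dataclass
class GroundTruth:
    """Oracle annotations recorded while generating a session."""

    attention: list[Episode] = field(default_factory=list)
    artifacts: list[Episode] = field(default_factory=list)
    fixations: list[Episode] = field(default_factory=list)
    reaches: list[Episode] = field(default_factory=list)

    def all_events(self) -> list[Episode]:
        events = self.attention + self.artifacts + self.fixations + self.reaches
        return sorted(events, key=lambda e: (e.onset, e.kind))

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            attention=self.attention + other.attention,
            artifacts=self.artifacts + other.artifacts,
            fixations=self.fixations + other.fixations,
            reaches=self.reaches + other.reaches,
        )
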