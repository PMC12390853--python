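"""Session configuration and scene geometry.

A :class:`SessionConfig` fully determines every synthetic stream the
simulator emits: the seed, sampling rates, the attention schedule, artifact
rates, the spectral structure of the EEG background, and the scene layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a session configuration violates its invariants."""


@dataclass(frozen=True)
class BandSpec:
    """Centre frequency and baseline amplitude of one EEG oscillator."""

    centre_hz: float
    amplitude_uv: float


def default_band_params() -> dict[str, BandSpec]:
    return {
        "theta": BandSpec(6.0, 8.0),
        "alpha": BandSpec(10.0, 10.0),
        "beta": BandSpec(20.0, 6.0),
    }


# Cyclopean eye position used to convert workspace points to view directions.
EYE_POSITION = np.array([0.0, 1.6, 0.0])


def direction_deg(point: np.ndarray, eye: np.ndarray = EYE_POSITION) -> tuple[float, float]:
    """Horizontal/vertical view angles (deg) of a workspace point.

    ``x`` increases rightward, ``y`` upward, ``z`` away from the viewer.
    """
    d = np.asarray(point, float) - eye
    az = math.degrees(math.atan2(d[0], d[2]))
    el = math.degrees(math.atan2(d[1], math.hypot(d[0], d[2])))
    return az, el


@dataclass
class SceneSpec:
    """Sphere start/target layout plus the derived gaze directions."""

    sphere_start: dict[str, tuple[float, float, float]]
    sphere_target: dict[str, tuple[float, float, float]]
    distractors: int = 0
    #: id of the sphere driven by the virtual (gaze+EEG) channel
    bci_sphere: str = "s3"
    #: ids of spheres driven by the left/right manual controllers
    manual_spheres: tuple[str, str] = ("s1", "s2")

    def gaze_targets(self) -> dict[str, tuple[float, float]]:
        return {k: direction_deg(np.asarray(v)) for k, v in self.sphere_start.items()}

    @classmethod
    def default(cls, side: float = 0.40, displacement: float = 0.25,
                seed: int | None = None) -> "SceneSpec":
        """Three spheres at the vertices of an equilateral triangle.

        Targets are the start positions shifted by ``displacement`` along
        per-sphere directions (deterministic unless a seed is given).
        """
        h = side * math.sqrt(3) / 2
        start = {
            "s1": (-side / 2, 1.0, 0.60),
            "s2": (side / 2, 1.0, 0.60),
            "s3": (0.0, 1.0, 0.60 + h),
        }
        if seed is None:
            offsets = {
                "s1": (-0.10, 0.15, 0.10),
                "s2": (0.10, 0.15, 0.10),
                "s3": (0.0, 0.20, 0.10),
            }
        else:
            rng = np.random.default_rng(seed)
            offsets = {
                k: tuple(rng.uniform(-displacement, displacement, 3)) for k in start
            }
        target = {
            k: tuple(np.asarray(start[k]) + np.asarray(offsets[k])) for k in start
        }
        return cls(sphere_start=start, sphere_target=target)


@dataclass
class SessionConfig:
    """Everything needed to synthesize one multimodal session."""

    seed: int = 0
    trial_duration: float = 60.0
    n_trials: int = 20
    eeg_rate: float = 512.0
    gaze_rate: float = 120.0
    pose_rate: float = 90.0
    #: (onset s, duration s, level in [0, 1]) attention episodes
    attention_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    blink_rate_per_min: float = 2.0
    muscle_rate_per_min: float = 1.0
    band_params: dict[str, BandSpec] = field(default_factory=default_band_params)
    noise_rms_uv: float = 5.0
    gaze_noise_sd_deg: float = 0.5
    gaze_dropout: float = 0.02
    scene: SceneSpec = field(default_factory=SceneSpec.default)

    def validate(self) -> None:
        for name in ("trial_duration", "eeg_rate", "gaze_rate", "pose_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for onset, duration, level in self.attention_schedule:
            if duration < 0 or onset < 0 or onset + duration > self.trial_duration + 1e-9:
                raise ConfigError(
                    f"attention episode ({onset}, {duration}) outside [0, {self.trial_duration}]"
                )
            if not 0.0 <= level <= 1.0:
                raise ConfigError(f"attention level {level} outside [0, 1]")
        if self.blink_rate_per_min < 0 or self.muscle_rate_per_min < 0:
            raise ConfigError("artifact rates must be non-negative")
        if not 0.0 <= self.gaze_dropout < 1.0:
            raise ConfigError("gaze_dropout must be in [0, 1)")
        if not self.scene.sphere_start:
            raise ConfigError("scene_spec must contain at least one sphere")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        d = asdict(self)
        d["band_params"] = {k: [v.centre_hz, v.amplitude_uv] for k, v in self.band_params.items()}
        return plain(d)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SessionConfig":
        d = dict(d)
        if "band_params" in d:
            d["band_params"] = {
                k: BandSpec(*v) if not isinstance(v, BandSpec) else v
                for k, v in d["band_params"].items()
            }
        if "attention_schedule" in d:
            d["attention_schedule"] = [tuple(e) for e in d["attention_schedule"]]
        if "scene" in d and not isinstance(d["scene"], SceneSpec):
            s = dict(d["scene"])
            s["sphere_start"] = {k: tuple(v) for k, v in s["sphere_start"].items()}
            s["sphere_target"] = {k: tuple(v) for k, v in s["sphere_target"].items()}
            if "manual_spheres" in s:
                s["manual_spheres"] = tuple(s["manual_spheres"])
            d["scene"] = SceneSpec(**s)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def periodic_schedule(n_episodes: int = 10, duration: float = 60.0,
                      episode_len: float = 4.0, level: float = 1.0,
                      start: float = 2.0) -> list[tuple[float, float, float]]:
    """Evenly spaced attention episodes covering ``[start, duration)``."""
    if n_episodes < 1:
        return []
    gap = (duration - start) / n_episodes
    if gap < episode_len:
        raise ConfigError("episodes do not fit in the trial")
    return [(start + i * gap, episode_len, level) for i in range(n_episodes)]
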