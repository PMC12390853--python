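"""Seeded synthetic multimodal session streams with ground-truth annotations.

Signal model
------------
EEG is a pink-noise floor plus three narrow-band oscillators (theta/alpha/
beta) whose instantaneous phase carries a small random jitter.  During
attention episodes the beta amplitude scales up and the alpha amplitude
down, proportionally to the episode level, so the beta/(alpha+theta) band
ratio is a monotone readout of the scheduled attention level.  Blink
artifacts are 300 ms raised-cosine deflections peaking at 150 uV; muscle
artifacts are 150 ms white bursts with 40 uV SD, both comfortably past the
downstream detection thresholds.

Gaze is a fixation-saccade process over the scene's sphere directions with
independent Gaussian observation noise (0.5 deg SD per axis) and flagged
dropout samples.  Controller poses follow minimum-jerk reach profiles
between scene points.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ConfigError, SessionConfig
from .streams import Episode, GroundTruth, SampleStream

BLINK_DURATION = 0.3
BLINK_PEAK_UV = 150.0
MUSCLE_DURATION = 0.15
MUSCLE_SD_UV = 80.0
EPISODE_RAMP = 0.25  # s, raised-cosine edge on attention envelopes
PHASE_JITTER = 0.02  # rad/sample random-walk SD of each oscillator


def pink_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spectrum *= 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def _envelope(n: int, rate: float, schedule, gain_fn) -> np.ndarray:
    """Per-sample amplitude envelope with raised-cosine episode edges."""
    env = np.ones(n)
    ramp_n = max(1, int(round(EPISODE_RAMP * rate)))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, ramp_n)))
    for onset, duration, level in schedule:
        gain = gain_fn(level)
        i0 = int(round(onset * rate))
        i1 = min(n, int(round((onset + duration) * rate)))
        if i1 <= i0:
            continue
        shape = np.ones(i1 - i0)
        k = min(ramp_n, len(shape) // 2)
        if k > 0:
            shape[:k] = ramp[:k]
            shape[-k:] = ramp[:k][::-1]
        env[i0:i1] += (gain - 1.0) * shape
    return env


def _poisson_times(rate_per_min: float, duration: float, width: float,
                   rng: np.random.Generator) -> list[float]:
    lam = rate_per_min * duration / 60.0
    count = rng.poisson(lam)
    if count == 0 or duration <= 2 * width:
        return []
    times = np.sort(rng.uniform(width, duration - width, count))
    # enforce non-overlap so ground-truth intervals stay distinct
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= 2 * width:
            kept.append(float(t))
    return kept


def gen_eeg(config: SessionConfig, run: int = 0) -> tuple[SampleStream, GroundTruth]:
    """Synthesize a single-channel EEG trial stream (uV) plus ground truth."""
    config.validate()
    rate = config.eeg_rate
    n = int(round(rate * config.trial_duration))
    rng = np.random.default_rng([config.seed, run, 11])
    t = np.arange(n) / rate

    x = pink_noise(n, rate, rng) * config.noise_rms_uv

    beta_env = _envelope(n, rate, config.attention_schedule, lambda lv: 1.0 + 2.0 * lv)
    alpha_env = _envelope(n, rate, config.attention_schedule, lambda lv: 1.0 - 0.7 * lv)
    envs = {"beta": beta_env, "alpha": alpha_env}

    for band, spec in config.band_params.items():
        jitter = np.cumsum(rng.normal(0.0, PHASE_JITTER, n))
        phase = 2 * math.pi * spec.centre_hz * t + jitter + rng.uniform(0, 2 * math.pi)
        env = envs.get(band, 1.0)
        x += spec.amplitude_uv * env * np.sin(phase)

    gt = GroundTruth()
    for onset, duration, level in config.attention_schedule:
        gt.attention.append(Episode("attention", onset, duration, level))

    # blink artifacts: smooth deflections guaranteed to exceed +-100 uV
    for onset in _poisson_times(config.blink_rate_per_min, config.trial_duration,
                                BLINK_DURATION, rng):
        i0 = int(round(onset * rate))
        m = int(round(BLINK_DURATION * rate))
        i1 = min(n, i0 + m)
        tau = np.linspace(0, 1, i1 - i0)
        template = BLINK_PEAK_UV * 0.5 * (1 - np.cos(2 * math.pi * tau))
        x[i0:i1] += template
        while np.abs(x[i0:i1]).max() <= 100.0:
            x[i0:i1] += 0.25 * template
        gt.artifacts.append(Episode("blink", onset, BLINK_DURATION))

    # muscle bursts: white noise guaranteed to exceed 50 uV/sample gradients
    for onset in _poisson_times(config.muscle_rate_per_min, config.trial_duration,
                                MUSCLE_DURATION, rng):
        i0 = int(round(onset * rate))
        m = int(round(MUSCLE_DURATION * rate))
        i1 = min(n, i0 + m)
        burst = rng.normal(0.0, MUSCLE_SD_UV, i1 - i0)
        x[i0:i1] += burst
        while np.abs(np.diff(x[max(i0 - 1, 0):i1])).max() <= 50.0:
            x[i0:i1] += 0.5 * burst
        gt.artifacts.append(Episode("muscle", onset, MUSCLE_DURATION))

    stream = SampleStream("eeg", rate, 0.0, x, "uV", columns=("uv",))
    return stream, gt


def _episode_level_at(schedule, t: float) -> float:
    for onset, duration, level in schedule:
        if onset <= t < onset + duration:
            return level
    return 0.0


def gen_gaze(config: SessionConfig, run: int = 0) -> tuple[SampleStream, GroundTruth]:
    """Fixation-saccade gaze over the scene targets, with observation noise.

    During scheduled attention episodes the fixated target is the scene's
    BCI sphere, mimicking the gaze-then-trigger strategy the pipeline
    assumes; outside episodes targets are drawn uniformly.
    """
    config.validate()
    targets = config.scene.gaze_targets()
    if not targets:
        raise ConfigError("scene_spec has no gaze targets")
    rate = config.gaze_rate
    n = int(round(rate * config.trial_duration))
    rng = np.random.default_rng([config.seed, run, 22])

    ids = sorted(targets)
    true = np.empty((n, 2))
    gt = GroundTruth()
    t_cursor = 0.0
    while t_cursor < config.trial_duration:
        dwell = float(rng.uniform(0.4, 1.2))
        if _episode_level_at(config.attention_schedule, t_cursor) > 0 and \
                config.scene.bci_sphere in targets:
            tid = config.scene.bci_sphere
        else:
            tid = ids[rng.integers(len(ids))]
        i0 = int(round(t_cursor * rate))
        i1 = min(n, int(round((t_cursor + dwell) * rate)))
        true[i0:i1] = targets[tid]
        gt.fixations.append(
            Episode("fixation", t_cursor, min(dwell, config.trial_duration - t_cursor),
                    tid, {"x_deg": targets[tid][0], "y_deg": targets[tid][1]})
        )
        t_cursor += dwell

    observed = true.copy()
    if config.gaze_noise_sd_deg > 0:
        observed = observed + rng.normal(0.0, config.gaze_noise_sd_deg, (n, 2))
    valid = rng.random(n) >= config.gaze_dropout
    observed[~valid] = np.nan

    stream = SampleStream("gaze", rate, 0.0, observed, "deg",
                          columns=("x_deg", "y_deg"), valid=valid)
    # stash the noiseless trace for oracle tests
    stream.true_values = true  # type: ignore[attr-defined]
    return stream, gt


def min_jerk(tau: np.ndarray | float) -> np.ndarray | float:
    """Minimum-jerk position profile on normalized time tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_peak_speed(displacement: float, duration: float) -> float:
    """Closed-form peak speed of a minimum-jerk reach: 15/8 * d / T."""
    return 1.875 * displacement / duration


def default_reaches(config: SessionConfig, rng: np.random.Generator,
                    endpoint_sd: float = 0.0015) -> list[Episode]:
    """One reach per manual hand from its sphere start to its target."""
    scene = config.scene
    reaches = []
    for hand, sphere in zip(("left", "right"), scene.manual_spheres):
        if sphere not in scene.sphere_start:
            continue
        start = np.asarray(scene.sphere_start[sphere])
        end = np.asarray(scene.sphere_target[sphere])
        if endpoint_sd > 0:
            end = end + rng.normal(0.0, endpoint_sd, 3)
        onset = float(rng.uniform(1.0, max(1.0, config.trial_duration / 4)))
        duration = float(rng.uniform(0.8, 1.5))
        reaches.append(Episode("reach", onset, duration, hand,
                               {"start": start.tolist(), "end": end.tolist()}))
    return reaches


def gen_controllers(config: SessionConfig, run: int = 0,
                    reaches: list[Episode] | None = None,
                    endpoint_sd: float = 0.0015,
                    ) -> tuple[SampleStream, GroundTruth]:
    """Two controller pose channels following minimum-jerk reaches.

    Returns a single stream with six columns (left xyz, right xyz) and the
    reach segments as ground truth.  Stationary segments hold the previous
    pose exactly (zero velocity).
    """
    config.validate()
    rate = config.pose_rate
    n = int(round(rate * config.trial_duration))
    rng = np.random.default_rng([config.seed, run, 33])
    if reaches is None:
        reaches = default_reaches(config, rng, endpoint_sd)

    scene = config.scene
    poses = {}
    for hand, sphere in zip(("left", "right"), scene.manual_spheres):
        start = np.asarray(scene.sphere_start.get(sphere, (0.0, 1.0, 0.4)))
        poses[hand] = np.tile(start, (n, 1))

    t = np.arange(n) / rate
    first_onset = {hand: None for hand in poses}
    for reach in sorted(reaches, key=lambda r: r.onset):
        hand = str(reach.value)
        if hand not in poses:
            continue
        start = np.asarray(reach.detail["start"], float)
        end = np.asarray(reach.detail["end"], float)
        tau = (t - reach.onset) / reach.duration
        profile = np.asarray(min_jerk(tau))[:, None]
        moving = (t >= reach.onset)
        poses[hand][moving] = start + profile[moving] * (end - start)
        if first_onset[hand] is None:
            # hold the reach's start pose before its onset (zero velocity)
            poses[hand][~moving] = start
            first_onset[hand] = reach.onset

    values = np.hstack([poses["left"], poses["right"]])
    stream = SampleStream("pose", rate, 0.0, values, "m",
                          columns=("lx", "ly", "lz", "rx", "ry", "rz"))
    return stream, GroundTruth(reaches=list(reaches))


def generate_session(config: SessionConfig, run: int = 0,
                     ) -> tuple[dict[str, SampleStream], GroundTruth]:
    """All three streams for one run, with merged ground truth."""
    eeg, gt_e = gen_eeg(config, run)
    gaze, gt_g = gen_gaze(config, run)
    pose, gt_p = gen_controllers(config, run)
    return {"eeg": eeg, "gaze": gaze, "pose": pose}, gt_e.merge(gt_g).merge(gt_p)
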