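"""Single-channel EEG feature pipeline.

Raw microvolt samples at 512 Hz are screened for artifacts (amplitude,
gradient and variance thresholds with 500 ms blanking), band-pass filtered
(4th-order Butterworth, 4-40 Hz, zero-phase) and detrended with a 500 ms
centred moving average.  Welch spectra (256-point segments, Hamming taper,
50% overlap) on 2-s sliding windows yield theta/alpha/beta band powers,
the beta/(alpha+theta) attention ratio normalized by a 30-s rolling
baseline, a 0-200 quality index, and zero-crossing rates -- a
10-dimensional feature vector emitted at 8 Hz.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .streams import SampleStream

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}
TOTAL_BAND = (4.0, 40.0)

AMP_THRESHOLD_UV = 100.0
GRAD_THRESHOLD_UV = 50.0
SD_THRESHOLD_UV = 35.0
BLANKING_S = 0.5
ARTIFACT_WINDOW_S = 2.0
ARTIFACT_HOP_S = 1.0
QUALITY_SPAN_S = 10.0
BASELINE_SPAN_S = 30.0
FRAME_RATE_HZ = 8.0
FEATURE_WINDOW_S = 2.0

FEATURE_NAMES = ("theta", "alpha", "beta", "d_theta", "d_alpha", "d_beta",
                 "ratio_raw", "attention", "quality", "zcr")


class PipelineError(ValueError):
    pass


class UndefinedRatioError(PipelineError):
    """alpha + theta power is zero: the attention ratio is undefined."""


@dataclass
class ArtifactFlags:
    t_start: float
    t_stop: float
    blink: bool
    muscle: bool
    poor_contact: bool

    @property
    def any(self) -> bool:
        return self.blink or self.muscle or self.poor_contact


@dataclass
class BandPowers:
    theta: float
    alpha: float
    beta: float
    total: float


@dataclass
class FeatureFrame:
    t: float
    theta: float
    alpha: float
    beta: float
    d_theta: float
    d_alpha: float
    d_beta: float
    ratio_raw: float
    attention: float
    quality: float
    zcr: float
    blanked: bool = False

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def in_intervals(t: float, intervals: list[tuple[float, float]]) -> bool:
    return any(lo <= t < hi for lo, hi in intervals)


def detect_artifacts(raw: SampleStream,
                     window: float = ARTIFACT_WINDOW_S,
                     hop: float = ARTIFACT_HOP_S,
                     amp: float = AMP_THRESHOLD_UV,
                     grad: float = GRAD_THRESHOLD_UV,
                     sd: float = SD_THRESHOLD_UV,
                     blanking: float = BLANKING_S,
                     ) -> tuple[list[ArtifactFlags], list[tuple[float, float]]]:
    """Per-window artifact flags plus merged 500 ms blanking intervals.

    Each flagged criterion opens a blanking interval at its first offending
    sample (window start for the variance criterion, which has no single
    offending sample).
    """
    x = raw.values
    if x.size == 0:
        return [], []
    rate = raw.rate
    win_n = int(round(window * rate))
    hop_n = max(1, int(round(hop * rate)))
    flags: list[ArtifactFlags] = []
    blank: list[tuple[float, float]] = []
    for i0 in range(0, max(1, len(x) - win_n + 1), hop_n):
        seg = x[i0:i0 + win_n]
        t0 = raw.t0 + i0 / rate
        over_amp = np.abs(seg) > amp
        grads = np.abs(np.diff(seg))
        over_grad = grads > grad
        poor = seg.std() > sd
        fl = ArtifactFlags(t0, t0 + len(seg) / rate,
                           bool(over_amp.any()), bool(over_grad.any()), poor)
        flags.append(fl)
        if fl.blink:
            ts = t0 + int(np.argmax(over_amp)) / rate
            blank.append((ts, ts + blanking))
        if fl.muscle:
            ts = t0 + int(np.argmax(over_grad)) / rate
            blank.append((ts, ts + blanking))
        if fl.poor_contact:
            blank.append((t0, t0 + blanking))
    return flags, merge_intervals(blank)


def bandpass_detrend(raw: SampleStream, low: float = 4.0, high: float = 40.0,
                     order: int = 4, detrend_window: float = 0.5,
                     causal: bool = False) -> SampleStream:
    """Zero-phase Butterworth band-pass then moving-average detrend."""
    if raw.rate < 2 * high + 8:
        raise PipelineError(f"sampling rate {raw.rate} too low for {high} Hz band edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=raw.rate,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if raw.n <= padlen:
        raise PipelineError(
            f"stream of {raw.n} samples shorter than filter warm-up ({padlen})")
    y = signal.sosfilt(sos, raw.values) if causal else signal.sosfiltfilt(sos, raw.values)
    ma_n = max(1, int(round(detrend_window * raw.rate)))
    y = y - uniform_filter1d(y, size=ma_n, mode="nearest")
    return SampleStream(raw.name + "_filt", raw.rate, raw.t0, y, raw.units,
                        columns=raw.columns)


def welch_psd(values: np.ndarray, rate: float, nperseg: int = 256,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (uV^2/Hz), Hamming taper, segment-averaged."""
    values = np.asarray(values, float)
    if len(values) < nperseg:
        raise PipelineError(f"window of {len(values)} samples < nperseg={nperseg}")
    freqs, psd = signal.welch(values, fs=rate, window="hamming", nperseg=nperseg,
                              noverlap=int(nperseg * overlap), detrend=False)
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                bands: dict[str, tuple[float, float]] = BANDS) -> BandPowers:
    """Rectangular integration over half-open band intervals [lo, hi)."""
    df = freqs[1] - freqs[0]

    def integrate(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(psd[mask].sum() * df)

    return BandPowers(theta=integrate(*bands["theta"]),
                      alpha=integrate(*bands["alpha"]),
                      beta=integrate(*bands["beta"]),
                      total=integrate(*TOTAL_BAND))


@dataclass
class BaselineState:
    """Rolling history of the raw attention ratio (artifact frames excluded)."""

    span: float = BASELINE_SPAN_S
    _entries: deque = field(default_factory=deque)

    def update(self, t: float, ratio: float) -> None:
        self._entries.append((t, ratio))
        while self._entries and self._entries[0][0] < t - self.span:
            self._entries.popleft()

    @property
    def n(self) -> int:
        return len(self._entries)

    @property
    def mean(self) -> float:
        if not self._entries:
            raise PipelineError("baseline history is empty")
        return float(np.mean([r for _, r in self._entries]))

    @property
    def sd(self) -> float:
        if not self._entries:
            raise PipelineError("baseline history is empty")
        return float(np.std([r for _, r in self._entries]))


def attention_metric(bp: BandPowers, baseline: BaselineState, t: float = 0.0,
                     update: bool = True) -> tuple[float, float]:
    """(ratio_raw, attention). Baseline is read before it is updated."""
    denom = bp.alpha + bp.theta
    if denom <= 0:
        raise UndefinedRatioError("alpha + theta power is zero")
    ratio = bp.beta / denom
    attention = ratio / baseline.mean if baseline.n > 0 else 1.0
    if update:
        baseline.update(t, ratio)
    return ratio, attention


def quality_index(flagged: np.ndarray | list[bool]) -> float:
    """0-200 quality from the flagged fraction of recent windows (200 = clean)."""
    flagged = np.asarray(flagged, bool)
    if flagged.size == 0:
        return 200.0
    return float(np.clip(200.0 * (1.0 - flagged.mean()), 0.0, 200.0))


def zero_crossing_rate(values: np.ndarray, rate: float) -> float:
    signs = np.sign(values)
    signs[signs == 0] = 1
    crossings = int((np.diff(signs) != 0).sum())
    return crossings * rate / max(len(values), 1)


def feature_stream(raw: SampleStream, frame_rate: float = FRAME_RATE_HZ,
                   window: float = FEATURE_WINDOW_S,
                   baseline_span: float = BASELINE_SPAN_S,
                   ) -> list[FeatureFrame]:
    """Full pipeline: 10-dimensional feature frames at ``frame_rate`` Hz.

    Each frame is computed on the trailing ``window`` seconds of filtered
    signal; band-power derivatives are first differences between
    consecutive frames divided by the frame spacing.  Frames whose
    timestamp lies inside a blanking interval are marked ``blanked`` and
    excluded from the rolling baseline.
    """
    if raw.duration < window:
        raise PipelineError(f"session of {raw.duration:.2f}s shorter than {window}s window")
    flags, blanking = detect_artifacts(raw)
    filt = bandpass_detrend(raw)
    baseline = BaselineState(span=baseline_span)
    hop = 1.0 / frame_rate
    win_n = int(round(window * raw.rate))
    frames: list[FeatureFrame] = []
    prev: FeatureFrame | None = None

    n_frames = int(np.floor((raw.duration - window) / hop + 1e-9)) + 1
    for k in range(n_frames):
        t = raw.t0 + window + k * hop
        i1 = filt.index_at(t)
        seg = filt.values[i1 - win_n:i1]
        freqs, psd = welch_psd(seg, raw.rate)
        bp = band_powers(freqs, psd)
        blanked = in_intervals(t, blanking)
        try:
            ratio, attention = attention_metric(bp, baseline, t, update=not blanked)
        except UndefinedRatioError:
            continue  # frame dropped
        recent = [f.any for f in flags if t - QUALITY_SPAN_S <= f.t_start and f.t_stop <= t]
        quality = quality_index(recent)
        zcr = zero_crossing_rate(seg, raw.rate)
        if prev is None:
            d_theta = d_alpha = d_beta = 0.0
        else:
            dt = t - prev.t
            d_theta = (bp.theta - prev.theta) / dt
            d_alpha = (bp.alpha - prev.alpha) / dt
            d_beta = (bp.beta - prev.beta) / dt
        frame = FeatureFrame(t, bp.theta, bp.alpha, bp.beta, d_theta, d_alpha,
                             d_beta, ratio, attention, quality, zcr, blanked)
        frames.append(frame)
        prev = frame
    return frames


#: piecewise-linear anchors mapping the baseline-normalized ratio to the
#: vendor-style 0-100 attention scale.  The rolling baseline already
#: personalizes the metric, so the map itself is fixed: a ratio at baseline
#: (1.0) reads 60, sustained focus (+20% over baseline) reads 80, and a
#: near-doubling saturates the scale.
ATTENTION_ANCHORS = ((0.0, 0.0), (1.0, 60.0), (1.2, 80.0), (1.9, 100.0))


def scale_attention(values: np.ndarray,
                    anchors=ATTENTION_ANCHORS) -> np.ndarray:
    """Map the baseline-normalized ratio onto the 0-100 attention scale."""
    values = np.asarray(values, float)
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    return np.clip(np.interp(values, xs, ys), 0.0, 100.0)


def frames_to_table(frames: list[FeatureFrame]):
    import pandas as pd

    return pd.DataFrame([{
        "t": f.t, **{name: getattr(f, name) for name in FEATURE_NAMES},
        "blanked": int(f.blanked),
    } for f in frames])


def frames_from_table(df) -> list[FeatureFrame]:
    return [FeatureFrame(t=row["t"],
                         **{name: row[name] for name in FEATURE_NAMES},
                         blanked=bool(row.get("blanked", 0)))
            for _, row in df.iterrows()]


def segment_epochs(values: np.ndarray, rate: float, epoch_len: float = 3.75,
                   overlap: float = 0.5, taper: bool = True) -> np.ndarray:
    """Sliding epochs starting every ``epoch_len * (1 - overlap)`` seconds.

    One epoch per step start strictly inside the trial; the trailing
    partial epoch is zero-padded.  A Hamming taper is applied unless
    ``taper`` is False.  Returns an ``(n_epochs, epoch_samples)`` array.
    """
    values = np.asarray(values, float)
    duration = len(values) / rate
    if duration < epoch_len:
        raise PipelineError("trial shorter than one epoch")
    step = epoch_len * (1.0 - overlap)
    n_epochs = int(np.ceil(duration / step - 1e-9))
    ep_n = int(round(epoch_len * rate))
    window = np.hamming(ep_n) if taper else np.ones(ep_n)
    epochs = np.zeros((n_epochs, ep_n))
    for k in range(n_epochs):
        i0 = int(round(k * step * rate))
        seg = values[i0:i0 + ep_n]
        epochs[k, :len(seg)] = seg
    return epochs * window


def erd_percent(power: np.ndarray | float, reference: float) -> np.ndarray | float:
    """Percent change of band power relative to a reference level."""
    if reference <= 0:
        raise PipelineError("reference band power must be positive")
    return 100.0 * (np.asarray(power, float) - reference) / reference


def band_power_series(values: np.ndarray, rate: float,
                      band: tuple[float, float] = BANDS["beta"],
                      window: float = 1.0, hop: float = 0.25,
                      nperseg: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Short-time band power P(t) from sliding Welch spectra."""
    win_n = int(round(window * rate))
    hop_n = max(1, int(round(hop * rate)))
    if win_n < nperseg:
        raise PipelineError("window shorter than one Welch segment")
    times, powers = [], []
    for i0 in range(0, len(values) - win_n + 1, hop_n):
        seg = values[i0:i0 + win_n]
        freqs, psd = welch_psd(seg, rate, nperseg=nperseg)
        df = freqs[1] - freqs[0]
        mask = (freqs >= band[0]) & (freqs < band[1])
        powers.append(float(psd[mask].sum() * df))
        times.append((i0 + win_n / 2) / rate)
    return np.asarray(times), np.asarray(powers)


def spectrogram_erd(raw: SampleStream, band: tuple[float, float],
                    baseline_interval: tuple[float, float],
                    window: float = 1.0, hop: float = 0.25,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Time course of event-related band-power change in percent.

    Negative values indicate desynchronization relative to the mean band
    power over ``baseline_interval``.
    """
    times, powers = band_power_series(raw.values, raw.rate, band, window, hop)
    times = times + raw.t0
    mask = (times >= baseline_interval[0]) & (times < baseline_interval[1])
    if not mask.any():
        raise PipelineError("baseline interval contains no spectrogram frames")
    p_ref = float(powers[mask].mean())
    return times, erd_percent(powers, p_ref)
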