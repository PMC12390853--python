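"""EEG pipeline tests, including the independent spectral oracles."""

import numpy as np
import pytest

from trimanus.config import SessionConfig
from trimanus.eeg import (BandPowers, BaselineState,
                          PipelineError, UndefinedRatioError, attention_metric,
                          band_powers, bandpass_detrend, detect_artifacts,
                          erd_percent, feature_stream, quality_index,
                          scale_attention, segment_epochs, spectrogram_erd,
                          welch_psd, FEATURE_NAMES)
from trimanus.streams import SampleStream
from trimanus.synthetic import gen_eeg

FS = 512.0


def make_stream(values, rate=FS):
    return SampleStream("eeg", rate, 0.0, np.asarray(values, float), "uV")


def welch_oracle(x, fs, nperseg=256, noverlap=128):
    """Independently coded Welch estimate (Hamming, one-sided, density)."""
    x = np.asarray(x, float)
    # periodic (DFT-even) Hamming window
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    step = nperseg - noverlap
    segs = [x[i:i + nperseg] * w for i in range(0, len(x) - nperseg + 1, step)]
    scale = 1.0 / (fs * (w**2).sum())
    psds = []
    for seg in segs:
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:-1] *= 2  # one-sided
        psds.append(spec)
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    return freqs, np.mean(psds, axis=0)


class TestArtifacts:
    def test_blink_flag_and_blanking(self):
        x = np.zeros(int(4 * FS))
        x[1000] = 120.0
        flags, blanking = detect_artifacts(make_stream(x))
        assert any(f.blink for f in flags)
        t_off = 1000 / FS
        # a merged blanking interval must cover [t_off, t_off + 0.5)
        assert any(lo <= t_off and hi >= t_off + 0.5 - 1e-9 for lo, hi in blanking)
        assert all(hi - lo <= 0.51 for lo, hi in blanking)

    def test_gradient_flag(self):
        x = np.zeros(int(4 * FS))
        x[2000] = 30.0
        x[2001] = -30.0  # 60 uV jump
        flags, _ = detect_artifacts(make_stream(x))
        assert any(f.muscle for f in flags)
        assert not any(f.blink for f in flags)

    def test_zero_signal_no_flags(self):
        flags, blanking = detect_artifacts(make_stream(np.zeros(int(6 * FS))))
        assert not any(f.any for f in flags)
        assert blanking == []

    def test_poor_contact_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 45, int(4 * FS))
        x = np.clip(x, -99, 99)  # keep below blink threshold
        flags, _ = detect_artifacts(make_stream(x), grad=1e9)
        assert any(f.poor_contact for f in flags)

    def test_empty_stream(self):
        flags, blanking = detect_artifacts(make_stream([]))
        assert flags == [] and blanking == []


class TestFilter:
    def test_low_frequency_attenuated_40db(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        y = bandpass_detrend(make_stream(x)).values
        core = slice(int(5 * FS), int(15 * FS))
        atten = 20 * np.log10(np.abs(y[core]).max() / 1.0)
        assert atten < -40.0

    def test_passband_10hz_preserved(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_detrend(make_stream(x)).values
        core = slice(int(5 * FS), int(15 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_constant_input_zeroed(self):
        y = bandpass_detrend(make_stream(np.full(int(5 * FS), 42.0))).values
        assert np.abs(y).max() < 1e-6

    def test_short_stream_raises(self):
        with pytest.raises(PipelineError):
            bandpass_detrend(make_stream(np.zeros(10)))


class TestWelch:
    def test_sinusoid_power_parseval(self):
        t = np.arange(int(8 * FS)) / FS
        amp = 3.0
        x = amp * np.sin(2 * np.pi * 10.0 * t)
        freqs, psd = welch_psd(x, FS)
        peak = freqs[np.argmax(psd)]
        assert peak == pytest.approx(10.0, abs=freqs[1] - freqs[0])
        power = psd.sum() * (freqs[1] - freqs[0])
        assert power == pytest.approx(amp**2 / 2, rel=0.05)

    def test_white_noise_variance(self, rng):
        sigma = 2.5
        x = rng.normal(0, sigma, int(60 * FS))
        freqs, psd = welch_psd(x, FS)
        assert psd.sum() * (freqs[1] - freqs[0]) == pytest.approx(sigma**2, rel=0.10)

    def test_zero_input_zero_spectrum(self):
        _, psd = welch_psd(np.zeros(1024), FS)
        assert np.all(psd == 0)

    def test_short_window_raises(self):
        with pytest.raises(PipelineError):
            welch_psd(np.zeros(100), FS)

    def test_oracle_equivalence(self, rng):
        # agreement with an independently coded segment-averaged periodogram
        x = rng.normal(0, 1, 1024)
        f1, p1 = welch_psd(x, FS)
        f2, p2 = welch_oracle(x, FS)
        assert np.allclose(f1, f2)
        assert np.max(np.abs(p1 - p2)) / np.max(p2) < 1e-6


class TestBandPowers:
    @staticmethod
    def line_spectrum(f0, value=1.0):
        freqs = np.arange(0, 257) * 2.0  # 2 Hz resolution up to 512 Hz
        psd = np.zeros_like(freqs)
        psd[np.argmin(np.abs(freqs - f0))] = value
        return freqs, psd

    def test_pure_alpha(self):
        bp = band_powers(*self.line_spectrum(10.0))
        assert bp.alpha > 0
        assert bp.theta == 0.0 and bp.beta == 0.0

    def test_pure_beta(self):
        bp = band_powers(*self.line_spectrum(20.0))
        assert bp.beta > 0 and bp.alpha == 0.0 and bp.theta == 0.0

    def test_half_open_band_edges(self):
        # 8 Hz belongs to alpha only; 12 Hz to beta only
        bp = band_powers(*self.line_spectrum(8.0))
        assert bp.alpha > 0 and bp.theta == 0.0
        bp = band_powers(*self.line_spectrum(12.0))
        assert bp.beta > 0 and bp.alpha == 0.0

    def test_quadratic_scaling(self, rng):
        x = rng.normal(0, 1, 2048)
        f, p1 = welch_psd(x, FS)
        _, p2 = welch_psd(2 * x, FS)
        b1, b2 = band_powers(f, p1), band_powers(f, p2)
        for name in ("theta", "alpha", "beta", "total"):
            assert getattr(b2, name) == pytest.approx(4 * getattr(b1, name), rel=1e-9)

    def test_bands_bounded_by_total(self, rng):
        x = rng.normal(0, 1, 4096)
        f, p = welch_psd(x, FS)
        bp = band_powers(f, p)
        assert bp.theta + bp.alpha + bp.beta <= bp.total + 1e-12


class TestAttentionMetric:
    def test_arithmetic(self):
        bp = BandPowers(theta=4.0, alpha=6.0, beta=10.0, total=25.0)
        ratio, _ = attention_metric(bp, BaselineState())
        assert ratio == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        x = rng.normal(0, 1, 1024)
        for c in (0.5, 3.0, 100.0):
            f, p1 = welch_psd(x, FS)
            _, p2 = welch_psd(c * x, FS)
            r1, _ = attention_metric(band_powers(f, p1), BaselineState(), update=False)
            r2, _ = attention_metric(band_powers(f, p2), BaselineState(), update=False)
            assert abs(r1 - r2) < 1e-9

    def test_self_normalization_near_one(self):
        baseline = BaselineState()
        bp = BandPowers(theta=3.0, alpha=5.0, beta=6.0, total=20.0)
        for t in np.arange(0, 30, 0.125):
            _, att = attention_metric(bp, baseline, t=t)
        assert att == pytest.approx(1.0, abs=1e-9)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            attention_metric(BandPowers(0.0, 0.0, 5.0, 5.0), BaselineState())

    def test_baseline_read_before_update(self):
        baseline = BaselineState()
        bp1 = BandPowers(theta=5.0, alpha=5.0, beta=10.0, total=25.0)
        _, att1 = attention_metric(bp1, baseline, t=0.0)
        assert att1 == 1.0  # empty baseline -> self-normalized
        bp2 = BandPowers(theta=5.0, alpha=5.0, beta=20.0, total=35.0)
        _, att2 = attention_metric(bp2, baseline, t=1.0)
        assert att2 == pytest.approx(2.0)  # normalized by bp1's ratio only


class TestQuality:
    def test_clean_is_200(self):
        assert quality_index([False] * 10) == 200.0

    def test_all_flagged_is_0(self):
        assert quality_index([True] * 10) == 0.0

    def test_half_flagged_is_100(self):
        assert quality_index([True, False] * 5) == 100.0

    def test_empty_history(self):
        assert quality_index([]) == 200.0


class TestFeatureStream:
    def test_frame_timing_and_dimension(self, short_config):
        stream, _ = gen_eeg(short_config)
        frames = feature_stream(stream)
        dts = np.diff([f.t for f in frames])
        assert np.allclose(dts, 0.125)
        assert len(frames[0].vector()) == 10
        assert len(FEATURE_NAMES) == 10

    def test_stationary_attention_sd_small(self):
        cfg = SessionConfig(seed=13, trial_duration=60.0,
                            blink_rate_per_min=0, muscle_rate_per_min=0)
        stream, _ = gen_eeg(cfg)
        frames = feature_stream(stream)
        att = np.array([f.attention for f in frames if f.t > 32.0])
        assert att.std() < 0.2

    def test_episode_raises_attention(self):
        cfg = SessionConfig(seed=13, trial_duration=60.0,
                            attention_schedule=[(40.0, 5.0, 1.0)],
                            blink_rate_per_min=0, muscle_rate_per_min=0)
        stream, _ = gen_eeg(cfg)
        frames = feature_stream(stream)
        inside = [f.attention for f in frames if 42.0 <= f.t <= 45.0]
        assert max(inside) > 1.3

    def test_blanked_frames_marked(self):
        cfg = SessionConfig(seed=21, trial_duration=30.0,
                            blink_rate_per_min=8, muscle_rate_per_min=0)
        stream, gt = gen_eeg(cfg)
        frames = feature_stream(stream)
        assert gt.artifacts
        # the blink crosses 100 uV about 0.1 s after onset; the 500 ms
        # blanking interval starts there
        for e in gt.artifacts:
            hit = [f for f in frames if e.onset + 0.15 <= f.t < e.onset + 0.55]
            assert hit and all(f.blanked for f in hit)

    def test_too_short_session_raises(self):
        with pytest.raises(PipelineError):
            feature_stream(make_stream(np.zeros(256)))


class TestScaleAttention:
    def test_baseline_maps_to_60(self):
        assert scale_attention(np.array([1.0]))[0] == pytest.approx(60.0)

    def test_monotone_and_clipped(self):
        vals = scale_attention(np.array([0.0, 0.5, 1.0, 1.2, 1.9, 5.0]))
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] == 0.0 and vals[-1] == 100.0
        assert vals[3] == pytest.approx(80.0)


class TestEpochs:
    def test_60s_trial_gives_32_epochs(self):
        epochs = segment_epochs(np.zeros(int(60 * FS)), FS)
        assert epochs.shape[0] == 32

    def test_20_trials_give_640(self):
        per_trial = segment_epochs(np.zeros(int(60 * FS)), FS).shape[0]
        assert per_trial * 20 == 640

    def test_short_trial_padding_convention(self):
        epochs = segment_epochs(np.ones(int(3.75 * FS)), FS)
        assert epochs.shape == (2, int(3.75 * FS))
        # second epoch covers only the trailing half; rest zero-padded
        half = int(1.875 * FS)
        assert np.all(epochs[1, FS and half:] == 0)

    def test_hamming_taper_applied(self):
        epochs = segment_epochs(np.ones(int(7.5 * FS)), FS)
        expected = np.hamming(epochs.shape[1])
        assert np.allclose(epochs[0], expected)

    def test_epoch_shorter_than_trial_raises(self):
        with pytest.raises(PipelineError):
            segment_epochs(np.zeros(100), FS)


class TestERD:
    def test_no_change_zero_percent(self):
        assert erd_percent(5.0, 5.0) == 0.0

    def test_printed_desync_magnitude(self):
        assert erd_percent(0.577, 1.0) == pytest.approx(-42.3)

    def test_doubling_is_plus_100(self):
        assert erd_percent(2.0, 1.0) == pytest.approx(100.0)

    def test_zero_reference_raises(self):
        with pytest.raises(PipelineError):
            erd_percent(1.0, 0.0)

    def test_spectrogram_erd_detects_suppression(self):
        t = np.arange(int(20 * FS)) / FS
        amp = np.where(t < 10, 1.0, 0.5)  # beta power drops by 75%
        x = amp * np.sin(2 * np.pi * 20 * t)
        stream = make_stream(x)
        times, erd = spectrogram_erd(stream, (12.0, 30.0), (0.0, 9.0))
        late = erd[times > 12.0]
        assert np.median(late) == pytest.approx(-75.0, abs=5.0)
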