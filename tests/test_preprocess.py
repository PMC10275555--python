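import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import periodogram

from sleeparousal import (
    ArousalAnnotation,
    EEGRecord,
    ValidationError,
    dwt_subbands,
    window_signal,
)
from sleeparousal.preprocess import BAND_ORDER


def band_energy_fraction(component, fs, lo, hi):
    freqs, pxx = periodogram(component, fs=fs)
    mask = (freqs >= lo) & (freqs <= hi)
    return pxx[mask].sum() / max(pxx.sum(), 1e-30)


class TestDwtSubbands:
    def test_zero_signal_gives_zero_bands(self):
        record = EEGRecord(np.zeros(1024), fs=200)
        sb = dwt_subbands(record)
        for band in BAND_ORDER:
            assert np.all(sb.bands[band] == 0)

    @pytest.mark.parametrize("level", [3, 5])
    def test_reconstruction_white_noise(self, rng, level):
        """The band reconstructions must sum back to the input signal."""
        x = rng.standard_normal(1024)
        sb = dwt_subbands(EEGRecord(x, fs=200), level=level)
        err = np.max(np.abs(sb.sum() - x)) / np.max(np.abs(x))
        assert err < 1e-8

    def test_two_hz_tone_routes_to_delta(self):
        t = np.arange(2048) / 200.0
        record = EEGRecord(np.sin(2 * np.pi * 2.0 * t), fs=200)
        sb = dwt_subbands(record, level=5)
        energies = {
            band: float(np.sum(sb.bands[band] ** 2)) for band in BAND_ORDER
        }
        assert energies["delta"] / sum(energies.values()) >= 0.80

    def test_40_hz_tone_routes_to_gamma(self):
        t = np.arange(2048) / 200.0
        record = EEGRecord(np.sin(2 * np.pi * 40.0 * t), fs=200)
        sb = dwt_subbands(record, level=5)
        energies = {b: float(np.sum(sb.bands[b] ** 2)) for b in BAND_ORDER}
        assert energies["gamma"] / sum(energies.values()) >= 0.80

    def test_level3_band_mapping(self):
        """Level 3 at 200 Hz: approximation (<12.5 Hz) lands in theta by
        centre frequency; D1/D2 in gamma, D3 in beta."""
        record = EEGRecord(np.random.default_rng(1).standard_normal(512), fs=200)
        sb = dwt_subbands(record, level=3)
        assert np.all(sb.bands["delta"] == 0)
        assert np.all(sb.bands["alpha"] == 0)
        assert np.any(sb.bands["theta"] != 0)
        assert np.any(sb.bands["gamma"] != 0)
        err = np.max(np.abs(sb.sum() - record.samples)) / np.max(np.abs(record.samples))
        assert err < 1e-8

    def test_too_short_signal_raises(self):
        with pytest.raises(ValidationError):
            dwt_subbands(EEGRecord(np.ones(16), fs=200), level=5)

    def test_unknown_wavelet_raises(self):
        with pytest.raises(ValidationError):
            dwt_subbands(EEGRecord(np.ones(1024), fs=200), wavelet="nosuch")


def _flat_annotation(duration):
    return ArousalAnnotation(((0.0, duration, 0),))


class TestWindowing:
    @pytest.mark.parametrize(
        "duration,win_s,overlap,expected",
        [(10.0, 1.0, 0.5, 19), (10.0, 1.0, 0.0, 10), (4.0, 2.0, 0.75, 5)],
    )
    def test_window_count(self, duration, win_s, overlap, expected):
        record = EEGRecord(np.ones(int(duration * 200)), fs=200)
        windows = window_signal(record, _flat_annotation(duration),
                                win_s=win_s, overlap=overlap)
        assert len(windows) == expected

    @given(st.integers(300, 4000), st.integers(100, 300), st.integers(10, 150))
    def test_window_count_formula(self, n, w_samples, hop_samples):
        """floor((L - W)/H) + 1 windows for any L >= W."""
        if n < w_samples:
            n = w_samples
        record = EEGRecord(np.ones(n), fs=200)
        win_s = w_samples / 200.0
        overlap = 1.0 - hop_samples / w_samples
        if not 0 <= overlap < 1:
            return
        windows = window_signal(record, _flat_annotation(n / 200.0),
                                win_s=win_s, overlap=overlap)
        assert len(windows) == (n - w_samples) // hop_samples + 1

    def test_window_inside_arousal_is_positive(self):
        record = EEGRecord(np.ones(2000), fs=200)
        ann = ArousalAnnotation(((0.0, 3.0, 0), (3.0, 7.0, 1), (7.0, 10.0, 0)))
        windows = window_signal(record, ann, win_s=1.0, overlap=0.0)
        assert [w.label for w in windows] == [0, 0, 0, 1, 1, 1, 1, 0, 0, 0]

    def test_half_coverage_is_positive(self):
        record = EEGRecord(np.ones(2000), fs=200)
        ann = ArousalAnnotation(((0.0, 0.5, 0), (0.5, 1.0, 1), (1.0, 10.0, 0)))
        windows = window_signal(record, ann, win_s=1.0, overlap=0.0)
        assert windows[0].label == 1

    def test_undefined_region_taints_windows(self):
        record = EEGRecord(np.ones(2000), fs=200)
        ann = ArousalAnnotation(((0.0, 4.0, 0), (4.0, 5.0, -1), (5.0, 10.0, 0)))
        labels = [w.label for w in window_signal(record, ann, win_s=1.0, overlap=0.0)]
        assert labels[4] == -1
        assert labels.count(-1) == 1

    @pytest.mark.parametrize("grow", [0.2, 0.7, 1.5])
    def test_label_rule_monotone_in_interval_growth(self, grow):
        """Enlarging a label-1 interval never flips a window from 1 to 0."""
        record = EEGRecord(np.ones(2000), fs=200)
        base = (4.0, 5.2)
        ann_small = ArousalAnnotation(((base[0], base[1], 1),)).normalized(10.0)
        ann_big = ArousalAnnotation(((base[0] - grow, base[1] + grow, 1),)).normalized(10.0)
        small = [w.label for w in window_signal(record, ann_small)]
        big = [w.label for w in window_signal(record, ann_big)]
        for lab_s, lab_b in zip(small, big):
            if lab_s == 1:
                assert lab_b == 1

    def test_record_shorter_than_window_raises(self):
        with pytest.raises(ValidationError):
            window_signal(EEGRecord(np.ones(100), fs=200),
                          _flat_annotation(0.5), win_s=1.0)

    def test_bad_overlap_raises(self):
        with pytest.raises(ValidationError):
            window_signal(EEGRecord(np.ones(400), fs=200),
                          _flat_annotation(2.0), overlap=1.0)
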