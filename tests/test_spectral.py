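"""Tests for Welch PSD, Energy Ratio, mel filterbank, MFCCs and spectral shape."""

import numpy as np
import pytest

from phonalysis.errors import DegenerateSpectrum, InsufficientBandwidth, InvalidInput
from phonalysis.segment import PhonationSegment
from phonalysis.spectral import (
    LOG_FLOOR,
    PowerSpectralDensity,
    build_mel_filterbank,
    energy_ratio_db,
    filterbank_for_segment,
    hz_to_mel,
    mel_power_to_mfcc,
    mel_to_hz,
    mfcc2_weighting_curve,
    mfcc_frames,
    mfcc_summary,
    rms_intensity_db,
    spectral_contrast_octave,
    spectral_flatness,
    welch_psd,
)

FS = 32000


def direct_cosine_sum_mfcc(log_mel: np.ndarray, n_coeff: int) -> np.ndarray:
    """Independent oracle: cosine-weighted sums over the filter index.

    Coefficient k (1-based) multiplies the log mel spectrum by a cosine
    with (k - 1) half-cycles across the filter axis and sums, with
    orthonormal scaling.
    """
    n = len(log_mel)
    out = np.empty(n_coeff)
    for k in range(1, n_coeff + 1):
        j = k - 1
        cos = np.cos(np.pi * j * (2 * np.arange(n) + 1) / (2 * n))
        scale = np.sqrt(1.0 / n) if j == 0 else np.sqrt(2.0 / n)
        out[k - 1] = scale * np.sum(log_mel * cos)
    return out


class TestWelch:
    def test_sine_peak_location(self):
        t = np.arange(FS) / FS
        seg = PhonationSegment.from_samples(np.sin(2 * np.pi * 1000 * t), FS)
        psd = welch_psd(seg)
        df = psd.freqs_hz[1] - psd.freqs_hz[0]
        assert abs(psd.freqs_hz[np.argmax(psd.pxx)] - 1000) <= df

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(FS * 2)
        psd = welch_psd(PhonationSegment.from_samples(x, FS))
        integral = np.trapezoid(psd.pxx, psd.freqs_hz)
        assert abs(integral - np.mean(x**2)) < 0.05 * np.mean(x**2)

    def test_zero_signal(self):
        psd = welch_psd(PhonationSegment.from_samples(np.zeros(FS), FS))
        assert np.all(psd.pxx == 0)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInput):
            welch_psd(PhonationSegment.from_samples(np.ones(100), FS))


class TestEnergyRatio:
    def test_flat_spectrum_analytic_value(self):
        freqs = np.linspace(0, 16000, 1601)
        psd = PowerSpectralDensity(freqs, np.ones_like(freqs), 0.02, 0.5)
        er = energy_ratio_db(psd)
        assert er.er_db == pytest.approx(10 * np.log10(4000 / 8000), abs=0.01)

    def test_low_band_only_is_degenerate(self):
        freqs = np.linspace(0, 16000, 1601)
        pxx = np.where(freqs < 4000, 1.0, 0.0)
        with pytest.raises(DegenerateSpectrum):
            energy_ratio_db(PowerSpectralDensity(freqs, pxx, 0.02, 0.5))

    def test_insufficient_bandwidth(self):
        freqs = np.linspace(0, 8000, 801)
        with pytest.raises(InsufficientBandwidth):
            energy_ratio_db(PowerSpectralDensity(freqs, np.ones_like(freqs), 0.02, 0.5))

    def test_scale_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(FS * 2)
        a = energy_ratio_db(welch_psd(PhonationSegment.from_samples(x, FS))).er_db
        b = energy_ratio_db(welch_psd(PhonationSegment.from_samples(7.3 * x, FS))).er_db
        assert abs(a - b) < 1e-6


class TestMelFilterbank:
    def test_mel_scale_endpoints_against_hand_formula(self):
        # Slaney scale: linear below 1 kHz (f / (200/3)), log above
        assert hz_to_mel(133.0) == pytest.approx(133.0 / (200.0 / 3.0), rel=1e-9)
        expected_12k = 15.0 + np.log(12000.0 / 1000.0) / (np.log(6.4) / 27.0)
        assert hz_to_mel(12000.0) == pytest.approx(expected_12k, rel=1e-9)
        # HTK variant
        assert hz_to_mel(1000.0, "htk") == pytest.approx(2595 * np.log10(1 + 1000 / 700), rel=1e-9)

    def test_mel_round_trip(self):
        f = np.array([133.0, 500.0, 1000.0, 4000.0, 12000.0])
        for variant in ("slaney", "htk"):
            assert np.allclose(mel_to_hz(hz_to_mel(f, variant), variant), f)

    def test_filters_peak_at_center(self):
        fb = build_mel_filterbank(FS, 1024, n_filters=40, fmax_hz=12000.0)
        fft_freqs = np.fft.rfftfreq(1024, 1 / FS)
        for m in range(fb.n_filters):
            assert fb.weights[m].sum() > 0
            peak_freq = fft_freqs[np.argmax(fb.weights[m])]
            df = fft_freqs[1]
            assert abs(peak_freq - fb.center_freqs_hz[m]) <= df

    def test_every_bin_in_range_covered(self):
        fb = build_mel_filterbank(FS, 1024, fmax_hz=12000.0)
        fft_freqs = np.fft.rfftfreq(1024, 1 / FS)
        inside = (fft_freqs > fb.fmin_hz) & (fft_freqs < fb.fmax_hz)
        assert np.all(fb.weights.sum(axis=0)[inside] > 0)

    def test_higher_fmax_raises_top_center(self):
        fb8 = build_mel_filterbank(FS, 1024, fmax_hz=8000.0)
        fb12 = build_mel_filterbank(FS, 1024, fmax_hz=12000.0)
        assert fb12.center_freqs_hz[-1] > fb8.center_freqs_hz[-1]
        assert fb12.center_freqs_hz[-1] > 8000.0

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(InsufficientBandwidth):
            build_mel_filterbank(16000, 1024, fmax_hz=12000.0)


class TestMfcc:
    def test_constant_mel_spectrum_kills_higher_coefficients(self):
        const = np.full(40, 3.7)
        coeffs = mel_power_to_mfcc(const, 13)
        assert np.all(np.abs(coeffs[1:]) < 1e-9)
        assert coeffs[0] != 0

    def test_fast_transform_equals_cosine_sum_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            log_mel = rng.uniform(-50, 50, size=40)
            fast = mel_power_to_mfcc(log_mel, 13)
            direct = direct_cosine_sum_mfcc(log_mel, 13)
            assert np.max(np.abs(fast - direct)) < 1e-9

    def test_mfcc2_sign_tracks_energy_placement(self):
        low = np.full(40, -60.0)
        low[:2] = 40.0  # energy in lowest two filters
        high = np.full(40, -60.0)
        high[-2:] = 40.0
        assert mel_power_to_mfcc(low, 2)[1] > 0
        assert mel_power_to_mfcc(high, 2)[1] < 0

    def test_frame_matrix_indexing_is_one_based(self, clean_male_segment):
        fb = filterbank_for_segment(clean_male_segment, 12000.0)
        frames = mfcc_frames(clean_male_segment, fb)
        assert np.array_equal(frames.coefficient(1), frames.values[:, 0])
        with pytest.raises(IndexError):
            frames.coefficient(0)

    def test_summary_mean_sd(self):
        from phonalysis.spectral import MfccFrameMatrix

        m = MfccFrameMatrix(np.array([[1.0, 3.0], [1.0, 7.0]]), 133.0, 8000.0)
        s = mfcc_summary(m)
        assert s.mean(2) == pytest.approx(5.0)
        assert s.sd(2) == pytest.approx(2.0)  # |a - b| / 2
        assert s.sd(1) == 0.0

    def test_identical_frames_zero_sd(self):
        from phonalysis.spectral import MfccFrameMatrix

        m = MfccFrameMatrix(np.tile([[2.0, -1.0, 0.5]], (10, 1)), 133.0, 8000.0)
        assert np.all(mfcc_summary(m).mfcc_sd == 0)

    def test_single_frame_warns(self):
        from phonalysis.spectral import MfccFrameMatrix

        m = MfccFrameMatrix(np.array([[1.0, 2.0]]), 133.0, 8000.0)
        with pytest.warns(UserWarning):
            s = mfcc_summary(m)
        assert np.all(s.mfcc_sd == 0)

    def test_amplitude_wobble_raises_mfcc1_sd(self, clean_male_segment):
        t = np.arange(len(clean_male_segment.samples)) / FS
        wobble = clean_male_segment.samples * 10 ** (1.5 * np.sin(2 * np.pi * 0.8 * t) / 20)
        seg_w = PhonationSegment.from_samples(wobble, FS)
        fb = filterbank_for_segment(clean_male_segment, 12000.0)
        sd_flat = mfcc_summary(mfcc_frames(clean_male_segment, fb)).sd(1)
        sd_wobble = mfcc_summary(mfcc_frames(seg_w, fb)).sd(1)
        assert sd_wobble > sd_flat

    def test_gain_shifts_only_first_coefficient(self, clean_male_segment):
        fb = filterbank_for_segment(clean_male_segment, 12000.0)
        base = mfcc_summary(mfcc_frames(clean_male_segment, fb))
        scaled_seg = PhonationSegment.from_samples(10.0 * clean_male_segment.samples, FS)
        scaled = mfcc_summary(mfcc_frames(scaled_seg, fb))
        assert scaled.mean(1) != pytest.approx(base.mean(1), abs=1.0)
        assert np.max(np.abs(scaled.mfcc_mn[1:] - base.mfcc_mn[1:])) < 1e-6


class TestMfcc2WeightingCurve:
    def test_sign_structure(self):
        fb = build_mel_filterbank(FS, 1024, fmax_hz=12000.0)
        freqs, w = mfcc2_weighting_curve(fb)
        assert w[0] > 0 and w[-1] < 0
        assert np.sum(np.diff(np.sign(w)) != 0) == 1  # single zero crossing
        assert np.all(np.diff(freqs) > 0)

    def test_zero_crossing_moves_up_with_fmax(self):
        def crossing_hz(fmax):
            fb = build_mel_filterbank(FS, 1024, fmax_hz=fmax)
            freqs, w = mfcc2_weighting_curve(fb)
            i = np.where(np.diff(np.sign(w)) != 0)[0][0]
            return np.interp(0.0, [w[i + 1], w[i]], [freqs[i + 1], freqs[i]])

        assert crossing_hz(12000.0) > crossing_hz(8000.0)


class TestSpectralShape:
    def test_white_noise_contrast_is_small(self, white_noise_segment):
        mn, _, _ = spectral_contrast_octave(white_noise_segment)
        assert np.all(mn < 15.0)

    def test_tone_contrast_largest_in_its_band(self):
        t = np.arange(FS * 2) / FS
        seg = PhonationSegment.from_samples(np.sin(2 * np.pi * 150 * t), FS)
        mn, sd, bands = spectral_contrast_octave(seg)
        assert bands[0] == (100.0, 200.0)
        assert mn[0] > mn[-1] + 5.0
        assert np.all(sd < 1.0)  # stationary input

    def test_flatness_extremes(self, white_noise_segment):
        flat_noise, _ = spectral_flatness(white_noise_segment)
        assert flat_noise > 0.3
        t = np.arange(FS * 2) / FS
        flat_sine, _ = spectral_flatness(
            PhonationSegment.from_samples(np.sin(2 * np.pi * 1000 * t), FS)
        )
        assert flat_sine < 0.01
        assert 0.0 <= flat_sine <= 1.0 and 0.0 <= flat_noise <= 1.0

    def test_rms_intensity_gain_shift(self, white_noise_segment):
        mn, sd = rms_intensity_db(white_noise_segment)
        seg10 = PhonationSegment.from_samples(10 * white_noise_segment.samples, FS)
        mn10, sd10 = rms_intensity_db(seg10)
        assert mn10 - mn == pytest.approx(20.0, abs=1e-6)
        assert sd10 == pytest.approx(sd, abs=1e-6)
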