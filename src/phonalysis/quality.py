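"""Interpretable voice-quality features: pitch, jitter, shimmer, HNR, CPP.

These are the classical dysphonia comparators against which MFCC-based
markers are interpreted. Jitter and shimmer quantify cycle-to-cycle
instability of the glottal period and amplitude; harmonics-to-noise
ratio (HNR) and cepstral peak prominence (CPP) quantify how strongly
periodic (clear, non-breathy) the voice is. All are scale-invariant:
multiplying the waveform by a constant changes none of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from ._framing import autocorr_peak, frame_rms, frame_signal, frame_times
from .errors import InvalidCycles, TooFewCycles, UnvoicedInput
from .segment import DEFAULT_VOICING_THRESHOLD, PhonationSegment

__all__ = [
    "PitchContour",
    "CycleSeries",
    "VoiceQualitySet",
    "pitch_contour",
    "pitch_statistics",
    "cycle_series",
    "jitter_local_abs",
    "shimmer_local_db",
    "harmonicity_hnr",
    "cepstral_peak_prominence",
    "voice_quality_set",
]

#: clamp on autocorrelation r before 10 log10(r / (1 - r)): caps HNR at +/- 60 dB
_R_CLAMP = 1e-6


@dataclass
class PitchContour:
    """Per-voiced-frame fundamental frequency estimates."""

    frame_times_s: np.ndarray
    f0_hz: np.ndarray
    periodicity: np.ndarray

    @property
    def median_f0_hz(self) -> float:
        return float(np.median(self.f0_hz))


@dataclass
class CycleSeries:
    """Detected glottal cycles: period, peak amplitude and start mark per cycle."""

    period_s: np.ndarray
    peak_amplitude: np.ndarray
    mark_s: np.ndarray  # segment-time of the mark opening each cycle


@dataclass
class VoiceQualitySet:
    """The full comparator feature set for one recording."""

    pitch_mn_hz: float
    pitch_sd_hz: float
    pitch_semitone_range: float
    jitter_localabs_s: float
    shimmer_local_db: float
    hnr_mn_db: float
    hnr_sd_db: float
    cpp_mn_db: float
    cpp_sd_db: float


def _voiced_autocorr(
    segment: PhonationSegment,
    f0_range_hz: tuple[float, float],
    frame_s: float,
    hop_s: float,
    threshold: float,
):
    """Shared frame loop: (times, lags, peaks, voiced mask)."""
    fs = segment.sample_rate_hz
    flen = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    frames = frame_signal(segment.samples, flen, hop)
    if len(frames) < 2:
        raise UnvoicedInput("segment shorter than two pitch frames")
    lag_min = max(2, int(np.floor(fs / f0_range_hz[1])))
    lag_max = int(np.ceil(fs / f0_range_hz[0]))
    lags, peaks = autocorr_peak(frames, lag_min, lag_max)
    rms = frame_rms(frames)
    floor = np.max(rms) * 1e-2
    voiced = (peaks >= threshold) & (rms >= floor)
    return frame_times(len(frames), hop_s), lags, peaks, voiced


def pitch_contour(
    segment: PhonationSegment,
    f0_range_hz: tuple[float, float] = (60.0, 500.0),
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> PitchContour:
    """Frame-wise f0 from the normalized autocorrelation peak.

    Two passes guard against octave errors: a first pass over the full
    search range fixes the median f0, then the lag range is narrowed to
    ~0.7 octaves around that median and the frames are re-analyzed.
    Only voiced frames are returned.
    """
    fs = segment.sample_rate_hz
    times, lags, peaks, voiced = _voiced_autocorr(
        segment, f0_range_hz, frame_s, hop_s, voicing_threshold
    )
    if not np.any(voiced):
        raise UnvoicedInput("no voiced frame in the pitch search range")
    median_f0 = float(np.median(fs / lags[voiced]))

    # second pass: narrowed range centered on the first-pass median
    lo = max(f0_range_hz[0], median_f0 / 2**0.7)
    hi = min(f0_range_hz[1], median_f0 * 2**0.7)
    times, lags, peaks, voiced = _voiced_autocorr(
        segment, (lo, hi), frame_s, hop_s, voicing_threshold
    )
    if not np.any(voiced):
        raise UnvoicedInput("no voiced frame after octave-guard pass")
    return PitchContour(
        frame_times_s=times[voiced],
        f0_hz=fs / lags[voiced],
        periodicity=peaks[voiced],
    )


def pitch_statistics(contour: PitchContour, trim_fraction: float = 0.01):
    """Mean, SD and semitone range of f0; range after trimming 1% tails."""
    f0 = contour.f0_hz
    lo, hi = np.quantile(f0, [trim_fraction, 1.0 - trim_fraction])
    trimmed = f0[(f0 >= lo) & (f0 <= hi)]
    if len(trimmed) == 0:
        trimmed = f0
    semitone_range = 12.0 * np.log2(trimmed.max() / trimmed.min())
    return float(f0.mean()), float(f0.std(ddof=0)), float(semitone_range)


def cycle_series(segment: PhonationSegment, contour: PitchContour) -> CycleSeries:
    """Glottal cycle marks by peak picking on the fundamental-band waveform.

    Coarse cycle candidates come from peak picking on the brick-wall
    fundamental band (0.5-1.5x the median f0, minimum spacing 0.6
    periods); each mark is then refined to the nearest excitation burst
    — the parabolic-interpolated maximum of |x| within +/- 0.35 periods
    in the *original* waveform — whose timing is far sharper than the
    narrowband fundamental's. Periods are successive mark-to-mark
    intervals; each cycle's amplitude is the interpolated burst height
    at its mark.
    """
    fs = segment.sample_rate_hz
    f0_med = contour.median_f0_hz
    x = segment.samples
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    spec[freqs > 1.5 * f0_med] = 0.0
    spec[freqs < 0.5 * f0_med] = 0.0  # remove DC / sub-harmonic drift
    fund = np.fft.irfft(spec, n=len(x))

    min_dist = int(0.6 * fs / f0_med)
    peaks, _ = scipy.signal.find_peaks(fund, distance=min_dist)
    peaks = peaks[(peaks > 0) & (peaks < len(x) - 1)]
    if len(peaks) < 4:
        raise TooFewCycles(f"only {len(peaks)} cycle marks found")

    half = max(2, int(0.35 * fs / f0_med))
    marks = np.empty(len(peaks))
    heights = np.empty(len(peaks))
    for j, p in enumerate(peaks):
        a, b = max(p - half, 1), min(p + half, len(x) - 1)
        i = a + int(np.argmax(np.abs(x[a:b])))
        y0, y1, y2 = abs(x[i - 1]), abs(x[i]), abs(x[i + 1])
        denom = y0 - 2 * y1 + y2
        delta = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0)) if abs(denom) > 1e-15 else 0.0
        marks[j] = i + delta
        heights[j] = y1 - 0.25 * (y0 - y2) * delta
    order = np.argsort(marks)
    marks, heights = marks[order] / fs, heights[order]
    # two coarse candidates can refine to the same burst; drop duplicates
    keep = np.concatenate([[True], np.diff(marks) > 0.3 / f0_med])
    marks, heights = marks[keep], heights[keep]
    if len(marks) < 4:
        raise TooFewCycles("fewer than 4 distinct cycle marks after refinement")

    periods = np.diff(marks)
    amps = heights[:-1]
    if len(periods) < 3:
        raise TooFewCycles("fewer than 3 glottal cycles detected")
    return CycleSeries(period_s=periods, peak_amplitude=amps, mark_s=marks[:-1])


def jitter_local_abs(cycles: CycleSeries) -> float:
    """Local absolute jitter: mean |T_i - T_{i-1}| over consecutive periods, in seconds."""
    if len(cycles.period_s) < 3:
        raise TooFewCycles("jitter needs at least 3 cycles")
    return float(np.mean(np.abs(np.diff(cycles.period_s))))


def shimmer_local_db(cycles: CycleSeries) -> float:
    """Local shimmer in dB: mean |20 log10(A_{i+1} / A_i)| over consecutive cycles."""
    a = cycles.peak_amplitude
    if len(a) < 3:
        raise TooFewCycles("shimmer needs at least 3 cycles")
    if np.any(a <= 0):
        raise InvalidCycles("non-positive cycle amplitude")
    return float(np.mean(np.abs(20.0 * np.log10(a[1:] / a[:-1]))))


def hnr_from_r(r) -> np.ndarray:
    """HNR in dB from autocorrelation r at the pitch lag: 10 log10(r / (1 - r))."""
    r = np.clip(np.asarray(r, dtype=float), _R_CLAMP, 1.0 - _R_CLAMP)
    return 10.0 * np.log10(r / (1.0 - r))


def harmonicity_hnr(
    segment: PhonationSegment,
    f0_range_hz: tuple[float, float] = (60.0, 500.0),
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
    force: bool = False,
) -> tuple[float, float]:
    """Harmonics-to-noise ratio: mean and SD over voiced frames, in dB.

    Per frame the interpolated autocorrelation peak r at the pitch lag
    gives HNR = 10 log10(r / (1 - r)); r is clamped so values cap at
    +/- 60 dB. With ``force=True`` all frames are evaluated even if
    none passes the voicing threshold (useful to characterize noise).
    """
    _, _, peaks, voiced = _voiced_autocorr(
        segment, f0_range_hz, frame_s, hop_s, voicing_threshold
    )
    if not np.any(voiced):
        if not force:
            raise UnvoicedInput("no voiced frame; HNR undefined")
        voiced = np.ones_like(voiced, dtype=bool)
    hnr = hnr_from_r(peaks[voiced])
    return float(hnr.mean()), float(hnr.std(ddof=0))


def cepstral_peak_prominence(
    segment: PhonationSegment,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    quefrency_range_s: tuple[float, float] = (1.0 / 500.0, 1.0 / 60.0),
) -> tuple[float, float]:
    """Cepstral peak prominence (CPP): mean and SD over frames, in dB.

    Per frame: the real cepstrum of the dB power spectrum is searched
    for its peak in the pitch quefrency range; a least-squares line is
    fitted to the cepstrum over that same range, and CPP is the peak
    height above the line at the peak quefrency. Clear, periodic voices
    have a tall rahmonic peak and high CPP; breathy or noisy voices a
    flat cepstrum and low CPP.
    """
    fs = segment.sample_rate_hz
    flen = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    frames = frame_signal(segment.samples, flen, hop)
    if len(frames) < 1:
        raise UnvoicedInput("segment shorter than one CPP frame")
    n_fft = 1 << (2 * flen - 1).bit_length()
    window = scipy.signal.windows.hann(flen, sym=False)
    power = np.abs(np.fft.rfft(frames * window, n=n_fft, axis=1)) ** 2
    # relative floor (120 dB below frame peak) keeps CPP gain-invariant
    frame_max = power.max(axis=1, keepdims=True)
    floor = np.where(frame_max > 0, frame_max * 1e-12, 1e-10)
    spectrum_db = 10.0 * np.log10(np.maximum(power, floor))
    cepstrum = np.fft.irfft(spectrum_db, n=n_fft, axis=1)

    quef = np.arange(n_fft) / fs
    lo, hi = quefrency_range_s
    sel = (quef >= lo) & (quef <= hi)
    q = quef[sel]
    c = cepstrum[:, sel]

    peak_idx = np.argmax(c, axis=1)
    peak_val = np.take_along_axis(c, peak_idx[:, None], axis=1)[:, 0]
    peak_q = q[peak_idx]

    # least-squares trend line over the search window, per frame
    design = np.column_stack([np.ones_like(q), q])
    coef, *_ = np.linalg.lstsq(design, c.T, rcond=None)
    trend_at_peak = coef[0] + coef[1] * peak_q
    cpp = peak_val - trend_at_peak
    if np.allclose(c.std(axis=1), 0.0):
        warnings.warn("constant cepstrum; CPP reported as 0", stacklevel=2)
        cpp = np.zeros_like(cpp)
    return float(cpp.mean()), float(cpp.std(ddof=0))


def voice_quality_set(segment: PhonationSegment) -> VoiceQualitySet:
    """Compute the full comparator set for one segment."""
    contour = pitch_contour(segment)
    mn, sd, semi = pitch_statistics(contour)
    cycles = cycle_series(segment, contour)
    hnr_mn, hnr_sd = harmonicity_hnr(segment)
    cpp_mn, cpp_sd = cepstral_peak_prominence(segment)
    return VoiceQualitySet(
        pitch_mn_hz=mn,
        pitch_sd_hz=sd,
        pitch_semitone_range=semi,
        jitter_localabs_s=jitter_local_abs(cycles),
        shimmer_local_db=shimmer_local_db(cycles),
        hnr_mn_db=hnr_mn,
        hnr_sd_db=hnr_sd,
        cpp_mn_db=cpp_mn,
        cpp_sd_db=cpp_sd,
    )
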