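"""Spectral features: Welch PSD, the low-to-high Energy Ratio, and MFCCs.

The central object here is the second mel-frequency cepstral coefficient
(MFCC2). Because the cepstral transform multiplies the *log* mel
spectrum by a half-cycle cosine — positive weights at low frequency,
negative at high — and log(a) - log(b) = log(a/b), MFCC2 is a weighted
log-ratio of low- to high-frequency energy. The Energy Ratio

    ER(dB) = 10 log10( int_0^4000 Pxx df / int_4000^fmax Pxx df )

is the unweighted analogue computed from a Welch power spectral
density. Both drop when aspiration noise raises the high-frequency part
of the spectrum, which is why they act as breathiness markers.

The MFCC upper frequency bound (``fmax``) is an explicit, reportable
parameter throughout: the filterbank, the coefficients, and the MFCC2
weighting curve all carry it, so the effect of analyzing up to 8 kHz
versus 12 kHz can be measured directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal

from ._framing import frame_rms, frame_signal
from .errors import DegenerateSpectrum, InsufficientBandwidth, InvalidInput
from .segment import PhonationSegment

__all__ = [
    "PowerSpectralDensity",
    "EnergyRatioValue",
    "MelFilterbank",
    "MfccFrameMatrix",
    "MfccSummary",
    "SpectralShapeSet",
    "welch_psd",
    "energy_ratio_db",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "filterbank_for_segment",
    "mfcc_frames",
    "mfcc_summary",
    "mfcc2_weighting_curve",
    "spectral_contrast_octave",
    "spectral_flatness",
    "rms_intensity_db",
    "spectral_shape_set",
    "OCTAVE_BANDS",
]

#: power floor applied before any log, to keep silent frames finite
LOG_FLOOR = 1e-10

#: octave analysis bands for spectral contrast (Hz)
OCTAVE_BANDS = (
    (100.0, 200.0),
    (200.0, 400.0),
    (400.0, 800.0),
    (800.0, 1600.0),
    (1600.0, 3200.0),
    (3200.0, 6400.0),
)


# ---------------------------------------------------------------------------
# Welch PSD and the Energy Ratio
# ---------------------------------------------------------------------------


@dataclass
class PowerSpectralDensity:
    """One-sided Welch PSD on a uniform frequency grid (amplitude^2 / Hz)."""

    freqs_hz: np.ndarray
    pxx: np.ndarray
    window_s: float
    overlap_fraction: float


@dataclass
class EnergyRatioValue:
    """Low-to-high band energy ratio in dB, with the band edges used."""

    er_db: float
    split_hz: float
    fmax_hz: float


def welch_psd(
    segment: PhonationSegment,
    window_s: float = 0.020,
    overlap_fraction: float = 0.5,
) -> PowerSpectralDensity:
    """Welch power spectral density with Hann windows (density scaling).

    Default 20 ms windows with 50% overlap. The density normalization
    satisfies Parseval: the integral of ``pxx`` over frequency matches
    the mean square of a stationary input.
    """
    fs = segment.sample_rate_hz
    nperseg = int(round(window_s * fs))
    if len(segment.samples) < 2 * nperseg:
        raise InvalidInput("segment shorter than two Welch windows")
    freqs, pxx = scipy.signal.welch(
        segment.samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)),
        detrend=False,
        scaling="density",
    )
    return PowerSpectralDensity(
        freqs_hz=freqs, pxx=pxx, window_s=window_s, overlap_fraction=overlap_fraction
    )


def _band_integral(freqs: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], with exact edge interpolation."""
    grid = freqs[(freqs > lo) & (freqs < hi)]
    f = np.concatenate([[lo], grid, [hi]])
    p = np.interp(f, freqs, pxx)
    return float(np.trapezoid(p, f))


def energy_ratio_db(
    psd: PowerSpectralDensity, split_hz: float = 4000.0, fmax_hz: float = 12000.0
) -> EnergyRatioValue:
    """Energy Ratio: 10 log10 of band power below ``split_hz`` over [split, fmax].

    Low-to-high orientation, so the value moves in the same direction as
    MFCC2 (drops as high-frequency noise grows).
    """
    if split_hz >= fmax_hz:
        raise InvalidInput("split_hz must be below fmax_hz")
    if psd.freqs_hz[-1] < fmax_hz:
        raise InsufficientBandwidth(
            f"PSD extends to {psd.freqs_hz[-1]:.0f} Hz < fmax {fmax_hz:.0f} Hz"
        )
    low = _band_integral(psd.freqs_hz, psd.pxx, 0.0, split_hz)
    high = _band_integral(psd.freqs_hz, psd.pxx, split_hz, fmax_hz)
    if high <= 0.0:
        raise DegenerateSpectrum("no power in the high band; Energy Ratio undefined")
    return EnergyRatioValue(
        er_db=float(10.0 * np.log10(low / high)), split_hz=split_hz, fmax_hz=fmax_hz
    )


# ---------------------------------------------------------------------------
# Mel filterbank
# ---------------------------------------------------------------------------


def hz_to_mel(f_hz, variant: str = "slaney"):
    """Mel scale: linear below 1 kHz, logarithmic above ('slaney'), or 'htk'."""
    f = np.asarray(f_hz, dtype=float)
    if variant == "htk":
        return 2595.0 * np.log10(1.0 + f / 700.0)
    if variant != "slaney":
        raise ValueError(f"unknown mel variant {variant!r}")
    f_sp = 200.0 / 3.0
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    mel = f / f_sp
    above = f >= min_log_hz
    mel = np.where(above, min_log_mel + np.log(np.maximum(f, min_log_hz) / min_log_hz) / logstep, mel)
    return mel if mel.ndim else float(mel)


def mel_to_hz(mel, variant: str = "slaney"):
    m = np.asarray(mel, dtype=float)
    if variant == "htk":
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    if variant != "slaney":
        raise ValueError(f"unknown mel variant {variant!r}")
    f_sp = 200.0 / 3.0
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    f = m * f_sp
    above = m >= min_log_mel
    f = np.where(above, min_log_hz * np.exp(logstep * (np.maximum(m, min_log_mel) - min_log_mel)), f)
    return f if f.ndim else float(f)


@dataclass
class MelFilterbank:
    """Triangular mel filters evaluated on an FFT bin grid."""

    n_filters: int
    fmin_hz: float
    fmax_hz: float
    sample_rate_hz: int
    n_fft: int
    weights: np.ndarray  # (n_filters, n_fft // 2 + 1)
    center_freqs_hz: np.ndarray
    mel_variant: str


def build_mel_filterbank(
    sample_rate_hz: int,
    n_fft: int,
    n_filters: int = 40,
    fmin_hz: float = 133.0,
    fmax_hz: float = 12000.0,
    mel_variant: str = "slaney",
) -> MelFilterbank:
    """Triangular filters with centers equally spaced on the mel scale.

    Filters are area-normalized (each triangle integrates to ~2/bandwidth
    in Hz), matching the common Slaney-style filterbank, so a filter's
    output approximates the mean power density inside its band.
    """
    nyquist = sample_rate_hz / 2.0
    if fmax_hz > nyquist:
        raise InsufficientBandwidth(
            f"fmax {fmax_hz:.0f} Hz exceeds Nyquist {nyquist:.0f} Hz"
        )
    mel_edges = np.linspace(
        hz_to_mel(fmin_hz, mel_variant), hz_to_mel(fmax_hz, mel_variant), n_filters + 2
    )
    hz_edges = mel_to_hz(mel_edges, mel_variant)
    fft_freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate_hz)

    weights = np.zeros((n_filters, len(fft_freqs)))
    for m in range(n_filters):
        lo, center, hi = hz_edges[m], hz_edges[m + 1], hz_edges[m + 2]
        rising = (fft_freqs - lo) / (center - lo)
        falling = (hi - fft_freqs) / (hi - center)
        tri = np.maximum(0.0, np.minimum(rising, falling))
        weights[m] = tri * (2.0 / (hi - lo))  # area normalization
    return MelFilterbank(
        n_filters=n_filters,
        fmin_hz=fmin_hz,
        fmax_hz=fmax_hz,
        sample_rate_hz=sample_rate_hz,
        n_fft=n_fft,
        weights=weights,
        center_freqs_hz=hz_edges[1:-1],
        mel_variant=mel_variant,
    )


# ---------------------------------------------------------------------------
# MFCC frames and summaries
# ---------------------------------------------------------------------------


@dataclass
class MfccFrameMatrix:
    """Per-frame MFCCs; column ``j`` holds coefficient ``j + 1`` (MFCC1 = energy term)."""

    values: np.ndarray  # (n_frames, n_coeff)
    fmin_hz: float
    fmax_hz: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def coefficient(self, k: int) -> np.ndarray:
        """Per-frame values of MFCC ``k`` (1-based)."""
        if k < 1 or k > self.values.shape[1]:
            raise IndexError(f"MFCC index {k} out of range (1-based)")
        return self.values[:, k - 1]


@dataclass
class MfccSummary:
    """Per-recording MFCC features: mean and SD of each coefficient across frames."""

    mfcc_mn: np.ndarray  # index 0 is MFCC1
    mfcc_sd: np.ndarray
    fmax_hz: float

    def mean(self, k: int) -> float:
        return float(self.mfcc_mn[k - 1])

    def sd(self, k: int) -> float:
        return float(self.mfcc_sd[k - 1])


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def _power_frames(
    segment: PhonationSegment, frame_s: float, hop_s: float
) -> tuple[np.ndarray, int]:
    """Hann-windowed one-sided power spectra per frame; returns (power, n_fft)."""
    fs = segment.sample_rate_hz
    flen = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    frames = frame_signal(segment.samples, flen, hop)
    if len(frames) < 1:
        raise InvalidInput("segment shorter than one analysis frame")
    n_fft = _next_pow2(flen)
    window = scipy.signal.windows.hann(flen, sym=False)
    spec = np.fft.rfft(frames * window, n=n_fft, axis=1)
    return np.abs(spec) ** 2, n_fft


def mel_power_to_mfcc(log_mel_db: np.ndarray, n_coeff: int) -> np.ndarray:
    """Orthonormal DCT-II across the filter axis, truncated to ``n_coeff`` terms.

    Coefficient k (1-based) weights the log mel spectrum by (k - 1)
    half-cycles of cosine across the filter index; k = 1 is the
    constant (overall energy) term.
    """
    return scipy.fft.dct(log_mel_db, type=2, norm="ortho", axis=-1)[..., :n_coeff]


def mfcc_frames(
    segment: PhonationSegment,
    filterbank: MelFilterbank,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    n_coeff: int = 13,
) -> MfccFrameMatrix:
    """Per-frame MFCCs: power spectrum -> mel energies -> 10 log10 -> DCT-II.

    The log uses a per-frame relative floor and no top clipping, so
    all-zero frames stay finite, coefficient magnitudes are not
    compressed, and coefficients k >= 2 are exactly gain-invariant.
    """
    power, n_fft = _power_frames(segment, frame_s, hop_s)
    if n_fft != filterbank.n_fft:
        raise InvalidInput(
            f"filterbank built for n_fft={filterbank.n_fft}, frames give {n_fft}"
        )
    mel_power = power @ filterbank.weights.T
    # floor 120 dB below each frame's peak: keeps silence finite while
    # preserving exact invariance of coefficients k >= 2 under gain changes
    frame_max = mel_power.max(axis=1, keepdims=True)
    floor = np.where(frame_max > 0, frame_max * 1e-12, LOG_FLOOR)
    log_mel_db = 10.0 * np.log10(np.maximum(mel_power, floor))
    values = mel_power_to_mfcc(log_mel_db, n_coeff)
    return MfccFrameMatrix(
        values=values, fmin_hz=filterbank.fmin_hz, fmax_hz=filterbank.fmax_hz
    )


def filterbank_for_segment(
    segment: PhonationSegment,
    fmax_hz: float,
    fmin_hz: float = 133.0,
    n_filters: int = 40,
    frame_s: float = 0.025,
    mel_variant: str = "slaney",
) -> MelFilterbank:
    """Build the filterbank matching :func:`mfcc_frames` framing for this segment."""
    n_fft = _next_pow2(int(round(frame_s * segment.sample_rate_hz)))
    return build_mel_filterbank(
        segment.sample_rate_hz, n_fft, n_filters, fmin_hz, fmax_hz, mel_variant
    )


def mfcc_summary(frames: MfccFrameMatrix) -> MfccSummary:
    """Mean and population SD of each coefficient across frames."""
    if frames.n_frames < 1:
        raise InvalidInput("no frames to summarize")
    if frames.n_frames == 1:
        warnings.warn("single frame: MFCC SDs reported as 0", stacklevel=2)
        sd = np.zeros(frames.values.shape[1])
    else:
        sd = frames.values.std(axis=0, ddof=0)
    return MfccSummary(
        mfcc_mn=frames.values.mean(axis=0), mfcc_sd=sd, fmax_hz=frames.fmax_hz
    )


def mfcc2_weighting_curve(filterbank: MelFilterbank) -> tuple[np.ndarray, np.ndarray]:
    """The MFCC2 cosine term remapped from filter index to frequency in Hz.

    Returns ``(center_freqs_hz, weights)``: a half-cycle of cosine over
    the filter index, positive at low frequencies and negative at high,
    with a single zero crossing. Its location moves up in Hz as the
    filterbank's fmax increases — the tunable boundary between the
    "low" and "high" sides of the energy ratio that MFCC2 encodes.
    """
    n = filterbank.n_filters
    m = np.arange(n)
    weights = np.sqrt(2.0 / n) * np.cos(np.pi * (2 * m + 1) / (2 * n))
    return filterbank.center_freqs_hz.copy(), weights


# ---------------------------------------------------------------------------
# Spectral contrast, flatness, intensity
# ---------------------------------------------------------------------------


@dataclass
class SpectralShapeSet:
    """Octave-band spectral contrast, flatness and RMS intensity summaries."""

    bands_hz: tuple[tuple[float, float], ...]
    contrast_mn_db: np.ndarray
    contrast_sd_db: np.ndarray
    flatness_mn: float
    flatness_sd: float
    rms_mn_db: float
    rms_sd_db: float


def spectral_contrast_octave(
    segment: PhonationSegment,
    bands: tuple[tuple[float, float], ...] = OCTAVE_BANDS,
    frame_s: float = 0.064,
    hop_s: float = 0.016,
    quantile: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, tuple[tuple[float, float], ...]]:
    """Per-band peak-to-trough spectral contrast, mean and SD across frames.

    Within each band and frame, contrast is the dB difference between
    the mean of the top and bottom ``quantile`` fraction of spectral
    magnitudes (at least one bin each). Longer frames than the MFCC
    default are used so the narrow 100-200 Hz band spans several FFT
    bins. Bands with fewer than two bins are merged into their lower
    neighbor with a warning.
    """
    power, n_fft = _power_frames(segment, frame_s, hop_s)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / segment.sample_rate_hz)

    merged: list[list[float]] = []
    for lo, hi in bands:
        n_bins = int(np.sum((freqs >= lo) & (freqs < hi)))
        if n_bins < 2 and merged:
            warnings.warn(f"band {lo:.0f}-{hi:.0f} Hz has < 2 bins; merged", stacklevel=2)
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    out_bands = tuple((lo, hi) for lo, hi in merged)

    magnitude = np.sqrt(power)
    mn, sd = [], []
    for lo, hi in out_bands:
        band = magnitude[:, (freqs >= lo) & (freqs < hi)]
        k = max(1, int(round(quantile * band.shape[1])))
        s = np.sort(band, axis=1)
        valley = np.maximum(s[:, :k].mean(axis=1), LOG_FLOOR)
        peak = np.maximum(s[:, -k:].mean(axis=1), LOG_FLOOR)
        contrast = 10.0 * np.log10(peak / valley)
        mn.append(contrast.mean())
        sd.append(contrast.std(ddof=0))
    return np.array(mn), np.array(sd), out_bands


def spectral_flatness(
    segment: PhonationSegment, frame_s: float = 0.025, hop_s: float = 0.010
) -> tuple[float, float]:
    """Geometric over arithmetic mean of the power spectrum, per frame; mean and SD.

    1 for a flat (noise-like) spectrum, toward 0 for tonal spectra.
    """
    power, _ = _power_frames(segment, frame_s, hop_s)
    p = np.maximum(power[:, 1:], LOG_FLOOR)  # exclude DC bin
    flat = np.exp(np.mean(np.log(p), axis=1)) / np.mean(p, axis=1)
    flat = np.clip(flat, 0.0, 1.0)
    return float(flat.mean()), float(flat.std(ddof=0))


def rms_intensity_db(
    segment: PhonationSegment, frame_s: float = 0.025, hop_s: float = 0.010
) -> tuple[float, float]:
    """Frame RMS level in dB (re full scale); mean and SD across frames."""
    fs = segment.sample_rate_hz
    frames = frame_signal(
        segment.samples, int(round(frame_s * fs)), int(round(hop_s * fs))
    )
    if len(frames) < 1:
        raise InvalidInput("segment shorter than one analysis frame")
    level = 20.0 * np.log10(np.maximum(frame_rms(frames), LOG_FLOOR))
    return float(level.mean()), float(level.std(ddof=0))


def spectral_shape_set(segment: PhonationSegment) -> SpectralShapeSet:
    """Convenience bundle: octave contrast + flatness + RMS intensity."""
    c_mn, c_sd, bands = spectral_contrast_octave(segment)
    f_mn, f_sd = spectral_flatness(segment)
    r_mn, r_sd = rms_intensity_db(segment)
    return SpectralShapeSet(
        bands_hz=bands,
        contrast_mn_db=c_mn,
        contrast_sd_db=c_sd,
        flatness_mn=f_mn,
        flatness_sd=f_sd,
        rms_mn_db=r_mn,
        rms_sd_db=r_sd,
    )
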