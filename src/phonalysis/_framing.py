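"""Internal frame-level signal helpers: framing and normalized autocorrelation.

The autocorrelation is window-corrected (the signal's windowed
autocorrelation divided by the analysis window's own autocorrelation),
so a perfectly periodic frame scores ~1.0 at its period lag instead of
being biased down by the finite window.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames (n_frames, frame_len); read-only view."""
    x = np.asarray(x, dtype=float)
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    return sliding_window_view(x, frame_len)[::hop]


def frame_times(n_frames: int, hop_s: float) -> np.ndarray:
    """Start time of each frame in seconds."""
    return np.arange(n_frames) * hop_s


def frame_rms(frames: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(frames**2, axis=1))


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def autocorr_peak(
    frames: np.ndarray, lag_min: int, lag_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Best-lag normalized autocorrelation per frame.

    Returns ``(lags, peaks)``: the parabolic-interpolated lag (in
    samples, float) and the window-corrected normalized autocorrelation
    value there, clipped to [0, 1]. Frames are mean-subtracted and
    Hann-windowed before correlation.
    """
    n_frames, flen = frames.shape
    lag_max = min(lag_max, flen - 2)
    if lag_max <= lag_min:
        raise ValueError("lag range empty for this frame length")

    w = hann(flen, sym=False)
    xw = (frames - frames.mean(axis=1, keepdims=True)) * w
    nfft = _next_pow2(2 * flen)
    spec = np.fft.rfft(xw, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : lag_max + 2]
    acw = np.fft.irfft(np.abs(np.fft.rfft(w, n=nfft)) ** 2, n=nfft)[: lag_max + 2]

    ac0 = ac[:, 0].copy()
    ac0[ac0 <= 0] = np.inf  # silent frame -> r = 0 everywhere
    r = (ac / ac0[:, None]) / (acw / acw[0])[None, :]

    search = r[:, lag_min : lag_max + 1]
    rmax = search.max(axis=1)
    # sub-harmonic guard: a period-doubled lag scores as high as the true
    # period for periodic signals, so take the SHORTEST lag within a small
    # margin of the maximum rather than the argmax itself
    best = np.argmax(search >= (rmax[:, None] - 0.01), axis=1) + lag_min

    # parabolic interpolation around the integer peak
    i = np.clip(best, lag_min + 1, lag_max - 1)
    y0 = np.take_along_axis(r, (i - 1)[:, None], axis=1)[:, 0]
    y1 = np.take_along_axis(r, i[:, None], axis=1)[:, 0]
    y2 = np.take_along_axis(r, (i + 1)[:, None], axis=1)[:, 0]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(np.nan_to_num(delta), -1.0, 1.0)
    lags = i + delta
    peaks = y1 - 0.25 * (y0 - y2) * delta
    # frames whose argmax sat at the search edge keep the integer estimate
    at_edge = (best == lag_min) | (best == lag_max)
    lags = np.where(at_edge, best.astype(float), lags)
    peaks = np.where(at_edge, np.take_along_axis(r, best[:, None], axis=1)[:, 0], peaks)
    return lags, np.clip(peaks, 0.0, 1.0)
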