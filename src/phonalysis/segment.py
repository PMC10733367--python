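"""Voicing detection and extraction of the fixed-length analysis segment.

A sustained-phonation recording typically contains silence, breaths and
an onset transient around the held vowel. Analysis uses only a steady
excerpt: the longest contiguous voiced run is located, its first
``discard_s`` seconds are dropped to remove onset transients, and up to
``keep_s`` seconds of what follows are retained. Recordings with no
voiced run are not analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._framing import autocorr_peak, frame_rms, frame_signal, frame_times
from .errors import InvalidInput, NoVoicedSegment, SegmentTooShort

__all__ = ["VoicingTrack", "PhonationSegment", "voicing_track", "extract_phonation"]

#: normalized-autocorrelation threshold above which a frame counts as voiced
DEFAULT_VOICING_THRESHOLD = 0.45
#: frames more than this far (dB) below the loudest frame are silence
_SILENCE_FLOOR_DB = 40.0


@dataclass
class VoicingTrack:
    """Per-frame voicing evidence: periodicity, f0 candidate, RMS, voiced flag."""

    frame_times_s: np.ndarray
    periodicity: np.ndarray
    f0_candidate_hz: np.ndarray
    rms: np.ndarray
    voiced: np.ndarray
    frame_s: float
    hop_s: float


@dataclass
class PhonationSegment:
    """The analyzed voiced excerpt: contiguous samples cut from the recording."""

    samples: np.ndarray
    sample_rate_hz: int
    source_start_s: float
    retained_s: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @classmethod
    def from_samples(cls, samples: np.ndarray, sample_rate_hz: int) -> "PhonationSegment":
        """Wrap raw samples as a segment without running segmentation (for direct analysis)."""
        samples = np.asarray(samples, dtype=float)
        return cls(
            samples=samples,
            sample_rate_hz=sample_rate_hz,
            source_start_s=0.0,
            retained_s=len(samples) / sample_rate_hz,
        )


def voicing_track(
    samples: np.ndarray,
    sample_rate_hz: int,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    f0_range_hz: tuple[float, float] = (60.0, 500.0),
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> VoicingTrack:
    """Frame-wise voicing detection from normalized autocorrelation.

    A frame is voiced iff its window-corrected autocorrelation peak in
    the pitch lag range is at least ``voicing_threshold`` and its RMS is
    within 40 dB of the loudest frame.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InvalidInput("empty audio")
    flen = int(round(frame_s * sample_rate_hz))
    hop = int(round(hop_s * sample_rate_hz))
    frames = frame_signal(samples, flen, hop)
    if len(frames) < 2:
        raise InvalidInput("recording shorter than two analysis frames")

    lag_min = max(2, int(np.floor(sample_rate_hz / f0_range_hz[1])))
    lag_max = int(np.ceil(sample_rate_hz / f0_range_hz[0]))
    lags, peaks = autocorr_peak(frames, lag_min, lag_max)
    rms = frame_rms(frames)
    floor = np.max(rms) * 10.0 ** (-_SILENCE_FLOOR_DB / 20.0)
    with np.errstate(divide="ignore"):
        f0 = np.where(lags > 0, sample_rate_hz / lags, 0.0)
    voiced = (peaks >= voicing_threshold) & (rms >= floor) & (rms > 0)
    return VoicingTrack(
        frame_times_s=frame_times(len(frames), hop_s),
        periodicity=peaks,
        f0_candidate_hz=f0,
        rms=rms,
        voiced=voiced,
        frame_s=frame_s,
        hop_s=hop_s,
    )


def _voiced_runs(voiced: np.ndarray, bridge_frames: int) -> list[tuple[int, int]]:
    """Contiguous voiced runs [start, end) in frame indices, bridging short gaps."""
    v = voiced.copy()
    # bridge unvoiced gaps of <= bridge_frames flanked by voiced frames
    if bridge_frames > 0:
        i = 0
        n = len(v)
        while i < n:
            if not v[i]:
                j = i
                while j < n and not v[j]:
                    j += 1
                if 0 < i and j < n and (j - i) <= bridge_frames:
                    v[i:j] = True
                i = j
            else:
                i += 1
    runs = []
    i = 0
    while i < len(v):
        if v[i]:
            j = i
            while j < len(v) and v[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def extract_phonation(
    samples: np.ndarray,
    sample_rate_hz: int,
    discard_s: float = 0.75,
    keep_s: float = 2.5,
    min_retained_s: float = 0.5,
    bridge_s: float = 0.1,
    strict: bool = False,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> PhonationSegment:
    """Cut the analysis segment out of a recording.

    Locates the longest contiguous voiced run (unvoiced gaps up to
    ``bridge_s`` are bridged), discards its initial ``discard_s``
    seconds and returns up to ``keep_s`` seconds of what follows. If
    less than ``keep_s`` remains, the available portion (>=
    ``min_retained_s``) is returned with a warning — or, in strict
    mode, a :class:`SegmentTooShort` error.
    """
    track = voicing_track(samples, sample_rate_hz, voicing_threshold=voicing_threshold)
    bridge_frames = int(round(bridge_s / track.hop_s))
    runs = _voiced_runs(track.voiced, bridge_frames)
    if not runs:
        raise NoVoicedSegment("no voiced segment detected; recording not analyzed")

    start_f, end_f = max(runs, key=lambda r: r[1] - r[0])
    run_start_s = track.frame_times_s[start_f]
    run_end_s = track.frame_times_s[end_f - 1] + track.frame_s
    run_end_s = min(run_end_s, len(samples) / sample_rate_hz)

    available_s = (run_end_s - run_start_s) - discard_s
    if available_s < min_retained_s:
        raise SegmentTooShort(
            f"voiced run of {run_end_s - run_start_s:.2f} s leaves "
            f"{available_s:.2f} s after the {discard_s:.2f} s discard"
        )
    retained_s = min(keep_s, available_s)
    if retained_s < keep_s:
        if strict:
            raise SegmentTooShort(
                f"only {retained_s:.2f} s available after discard (need {keep_s:.2f} s)"
            )
        warnings.warn(
            f"retained only {retained_s:.2f} s of the requested {keep_s:.2f} s",
            stacklevel=2,
        )
    start_sample = int(round((run_start_s + discard_s) * sample_rate_hz))
    n_keep = int(round(retained_s * sample_rate_hz))
    cut = np.asarray(samples, dtype=float)[start_sample : start_sample + n_keep]
    return PhonationSegment(
        samples=cut,
        sample_rate_hz=sample_rate_hz,
        source_start_s=start_sample / sample_rate_hz,
        retained_s=len(cut) / sample_rate_hz,
    )
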