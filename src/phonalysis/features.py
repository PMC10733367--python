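"""Assemble the per-recording feature row from a phonation segment.

One segment yields one flat feature dict: MFCC mean/SD at each
configured upper frequency bound (columns suffixed ``_8k`` / ``_12k``),
the Energy Ratio, octave-band spectral contrast, flatness, RMS
intensity, and the voice-quality comparators. Column names are fixed so
feature CSVs from different runs line up.
"""

from __future__ import annotations

from dataclasses import asdict

from .quality import voice_quality_set
from .segment import PhonationSegment
from .spectral import (
    energy_ratio_db,
    filterbank_for_segment,
    mfcc_frames,
    mfcc_summary,
    spectral_shape_set,
    welch_psd,
)

__all__ = ["fmax_suffix", "extract_feature_row", "mfcc_column_names"]


def fmax_suffix(fmax_hz: float) -> str:
    """Column suffix for an MFCC upper bound: 8000.0 -> '8k'."""
    k = fmax_hz / 1000.0
    return f"{k:g}k"


def mfcc_column_names(n_coeff: int, fmax_hz: float) -> list[str]:
    s = fmax_suffix(fmax_hz)
    return [f"mfcc_mn_{k}_{s}" for k in range(1, n_coeff + 1)] + [
        f"mfcc_sd_{k}_{s}" for k in range(1, n_coeff + 1)
    ]


def extract_feature_row(
    segment: PhonationSegment,
    fmax_list: tuple[float, ...] = (8000.0, 12000.0),
    fmin_hz: float = 133.0,
    n_filters: int = 40,
    n_coeff: int = 13,
    mel_variant: str = "slaney",
    er_split_hz: float = 4000.0,
    er_fmax_hz: float = 12000.0,
    welch_window_s: float = 0.020,
    welch_overlap: float = 0.5,
) -> dict:
    """Compute every feature column for one segment."""
    row: dict = {"retained_s": segment.retained_s}

    for fmax in fmax_list:
        fb = filterbank_for_segment(
            segment, fmax, fmin_hz=fmin_hz, n_filters=n_filters, mel_variant=mel_variant
        )
        summ = mfcc_summary(mfcc_frames(segment, fb, n_coeff=n_coeff))
        s = fmax_suffix(fmax)
        for k in range(1, n_coeff + 1):
            row[f"mfcc_mn_{k}_{s}"] = summ.mean(k)
            row[f"mfcc_sd_{k}_{s}"] = summ.sd(k)

    psd = welch_psd(segment, window_s=welch_window_s, overlap_fraction=welch_overlap)
    row["er_db"] = energy_ratio_db(psd, split_hz=er_split_hz, fmax_hz=er_fmax_hz).er_db

    shape = spectral_shape_set(segment)
    for (lo, hi), mn, sd in zip(shape.bands_hz, shape.contrast_mn_db, shape.contrast_sd_db):
        row[f"contrast_{lo:g}_{hi:g}_mn"] = float(mn)
        row[f"contrast_{lo:g}_{hi:g}_sd"] = float(sd)
    row["flatness_mn"] = shape.flatness_mn
    row["flatness_sd"] = shape.flatness_sd
    row["rms_mn_db"] = shape.rms_mn_db
    row["rms_sd_db"] = shape.rms_sd_db

    row.update(asdict(voice_quality_set(segment)))
    return row
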