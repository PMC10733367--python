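"""Shared fixtures: synthetic recordings and cohorts (session-scoped, seeded)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phonalysis.config import RunConfig
from phonalysis.pipeline import (
    cohort_spec_from_config,
    extract_features_for_recordings,
)
from phonalysis.segment import PhonationSegment, extract_phonation
from phonalysis.synth import AspirationParams, SpeakerProfile, simulate_cohort, simulate_phonation

FS = 32000


@pytest.fixture(scope="session")
def clean_male_recording():
    """4 s male /a/ at 115 Hz, no jitter/shimmer/noise."""
    return simulate_phonation(
        SpeakerProfile.male(f0_hz=115.0), AspirationParams(noise_gain=0.0), FS, seed=4
    )


@pytest.fixture(scope="session")
def clean_male_segment(clean_male_recording):
    return extract_phonation(clean_male_recording.samples, FS)


@pytest.fixture(scope="session")
def breathy_male_segment():
    rec = simulate_phonation(
        SpeakerProfile.male(f0_hz=115.0), AspirationParams(noise_gain=0.5), FS, seed=4
    )
    return extract_phonation(rec.samples, FS)


@pytest.fixture(scope="session")
def white_noise_segment():
    rng = np.random.default_rng(0)
    return PhonationSegment.from_samples(0.1 * rng.standard_normal(FS * 3), FS)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort_table(default_config) -> pd.DataFrame:
    """The default synthetic cohort (2 groups x 2 sexes x 30): metadata + features."""
    recordings, manifest = simulate_cohort(cohort_spec_from_config(default_config))
    features, statuses = extract_features_for_recordings(recordings, default_config)
    assert (statuses["status"] == "ok").all()
    return manifest[["subject_id", "group", "sex", "age", "noise_gain"]].merge(
        features, on="subject_id"
    )


@pytest.fixture(scope="session")
def highband_noise_cohort_table() -> pd.DataFrame:
    """Cohort whose aspiration noise is band-limited to 8-12 kHz."""
    config = RunConfig(seed=2, n_per_cell=15, noise_band_hz=(8000.0, 12000.0))
    recordings, manifest = simulate_cohort(cohort_spec_from_config(config))
    features, _ = extract_features_for_recordings(recordings, config)
    return manifest[["subject_id", "group", "sex"]].merge(features, on="subject_id")


@pytest.fixture(scope="session")
def aspiration_sweep_features():
    """Feature values along a 6-point noise_gain sweep, all else fixed (same seed)."""
    from phonalysis.quality import (
        cepstral_peak_prominence,
        cycle_series,
        harmonicity_hnr,
        jitter_local_abs,
        pitch_contour,
        shimmer_local_db,
    )
    from phonalysis.spectral import (
        energy_ratio_db,
        filterbank_for_segment,
        mfcc_frames,
        mfcc_summary,
        welch_psd,
    )

    profile = SpeakerProfile.male(f0_hz=115.0, jitter_fraction=0.003, shimmer_db=0.25)
    gains = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)
    rows = []
    for gain in gains:
        rec = simulate_phonation(profile, AspirationParams(noise_gain=gain), FS, seed=42)
        seg = extract_phonation(rec.samples, FS)
        psd = welch_psd(seg)
        contour = pitch_contour(seg)
        cycles = cycle_series(seg, contour)
        rows.append(
            {
                "noise_gain": gain,
                "er_db": energy_ratio_db(psd).er_db,
                "mfcc2_8k": mfcc_summary(
                    mfcc_frames(seg, filterbank_for_segment(seg, 8000.0))
                ).mean(2),
                "mfcc2_12k": mfcc_summary(
                    mfcc_frames(seg, filterbank_for_segment(seg, 12000.0))
                ).mean(2),
                "hnr": harmonicity_hnr(seg)[0],
                "cpp": cepstral_peak_prominence(seg)[0],
                "jitter": jitter_local_abs(cycles),
                "shimmer": shimmer_local_db(cycles),
                "band_low_power": float(
                    np.trapezoid(psd.pxx[psd.freqs_hz <= 4000], psd.freqs_hz[psd.freqs_hz <= 4000])
                ),
                "band_high_power": float(
                    np.trapezoid(
                        psd.pxx[(psd.freqs_hz >= 4000) & (psd.freqs_hz <= 12000)],
                        psd.freqs_hz[(psd.freqs_hz >= 4000) & (psd.freqs_hz <= 12000)],
                    )
                ),
            }
        )
    return pd.DataFrame(rows)
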