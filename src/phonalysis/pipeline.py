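"""End-to-end orchestration: simulate -> segment -> extract -> analyze.

Each stage reads and writes plain files (WAV, CSV, JSON) so stages can
be re-run independently; per-recording failures are recorded in a run
manifest and never abort the batch.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile
import scipy.signal

from .config import RunConfig
from .errors import (
    InsufficientBandwidth,
    InvalidParams,
    JoinError,
    NoVoicedSegment,
    PhonalysisError,
    SegmentTooShort,
)
from .features import extract_feature_row
from .segment import extract_phonation
from .stats import (
    bootstrap_auc_ci,
    correlation_screen,
    descriptive_table,
    ols_aic_select,
    one_way_anova,
)
from .synth import CohortSpec, GroupSeverity, LabeledRecording, simulate_cohort

__all__ = [
    "cohort_spec_from_config",
    "run_simulate",
    "extract_features_for_recordings",
    "run_extract",
    "run_analyze",
    "run_all",
    "AUC_METRICS",
]

log = logging.getLogger("phonalysis")

#: the scalar metrics evaluated by ROC analysis, per fmax tag
AUC_METRICS = ("mfcc_mn_2_12k", "mfcc_mn_2_8k", "er_db")


def cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    return CohortSpec(
        n_per_cell=config.n_per_cell,
        group_severity={
            "control": GroupSeverity(
                noise_gain_median=config.control_noise_gain_median,
                noise_gain_sigma=config.noise_gain_sigma,
                jitter_fraction=config.jitter_fraction,
                shimmer_db=config.shimmer_db,
                noise_band_hz=config.noise_band_hz,
            ),
            "case": GroupSeverity(
                noise_gain_median=config.case_noise_gain_median,
                noise_gain_sigma=config.noise_gain_sigma,
                jitter_fraction=config.jitter_fraction,
                shimmer_db=config.shimmer_db,
                noise_band_hz=config.noise_band_hz,
            ),
        },
        sample_rate_hz=config.sample_rate_hz,
        duration_s=config.duration_s,
        seed=config.seed,
    )


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate the cohort and write WAVs plus the manifest CSV.

    Returns the manifest path. Deterministic under the config seed.
    """
    out_dir = Path(out_dir)
    wav_dir = out_dir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    recordings, manifest = simulate_cohort(cohort_spec_from_config(config))
    for rec in recordings:
        path = wav_dir / f"{rec.metadata['subject_id']}.wav"
        pcm = np.clip(rec.samples * 32767.0, -32768, 32767).astype(np.int16)
        scipy.io.wavfile.write(path, rec.sample_rate_hz, pcm)
        manifest.loc[
            manifest["subject_id"] == rec.metadata["subject_id"], "wav_path"
        ] = str(path.relative_to(out_dir))
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    config.to_yaml(out_dir / "config.yaml")
    log.info("simulated %d recordings into %s", len(recordings), wav_dir)
    return manifest_path


def _segment_and_extract(samples: np.ndarray, fs: int, config: RunConfig) -> dict:
    segment = extract_phonation(
        samples,
        fs,
        discard_s=config.discard_s,
        keep_s=config.keep_s,
        min_retained_s=config.min_retained_s,
        bridge_s=config.bridge_s,
        strict=config.strict_segmentation,
        voicing_threshold=config.voicing_threshold,
    )
    return extract_feature_row(
        segment,
        fmax_list=config.fmax_list,
        fmin_hz=config.fmin_hz,
        n_filters=config.n_filters,
        n_coeff=config.n_coeff,
        mel_variant=config.mel_variant,
        er_split_hz=config.er_split_hz,
        er_fmax_hz=config.er_fmax_hz,
        welch_window_s=config.welch_window_s,
        welch_overlap=config.welch_overlap,
    )


def _classify_failure(exc: Exception) -> str:
    if isinstance(exc, NoVoicedSegment):
        return "no_voiced_segment"
    if isinstance(exc, SegmentTooShort):
        return "too_short"
    return "error"


def extract_features_for_recordings(
    recordings: list[LabeledRecording], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory extraction: (features, run manifest) for simulated recordings."""
    feature_rows, status_rows = [], []
    for rec in recordings:
        sid = rec.metadata.get("subject_id", "")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                row = _segment_and_extract(rec.samples, rec.sample_rate_hz, config)
            row["subject_id"] = sid
            feature_rows.append(row)
            status_rows.append(
                {"subject_id": sid, "status": "ok", "warnings": len(caught)}
            )
        except PhonalysisError as exc:
            status_rows.append(
                {"subject_id": sid, "status": _classify_failure(exc), "warnings": 0}
            )
    features = pd.DataFrame(feature_rows)
    if len(features):
        features = features[
            ["subject_id"] + [c for c in features.columns if c != "subject_id"]
        ]
    return features, pd.DataFrame(status_rows)


def _load_wav(path: Path, config: RunConfig) -> tuple[np.ndarray, int]:
    fs, data = scipy.io.wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    target = config.sample_rate_hz
    if fs != target:
        if fs / 2.0 < max(config.fmax_list):
            raise InsufficientBandwidth(
                f"{path.name}: source Nyquist {fs / 2:.0f} Hz below requested fmax"
            )
        g = np.gcd(int(target), int(fs))
        data = scipy.signal.resample_poly(data, int(target) // g, int(fs) // g)
        fs = target
    return data, fs


def run_extract(
    config: RunConfig, manifest_path: str | Path, out_dir: str | Path
) -> tuple[Path, Path]:
    """Extract features for every recording in a manifest of WAV files.

    Writes ``features.csv`` (one row per successfully analyzed
    recording) and ``run_manifest.csv`` (per-recording status); returns
    both paths. A failed recording affects only its own row.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)

    feature_rows, status_rows = [], []
    for _, meta in manifest.iterrows():
        sid = meta["subject_id"]
        wav = Path(meta["wav_path"])
        if not wav.is_absolute():
            wav = base / wav
        try:
            samples, fs = _load_wav(wav, config)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                row = _segment_and_extract(samples, fs, config)
            row["subject_id"] = sid
            feature_rows.append(row)
            status_rows.append({"subject_id": sid, "status": "ok", "warnings": len(caught)})
        except (PhonalysisError, OSError, ValueError) as exc:
            log.warning("recording %s failed: %s", sid, exc)
            status_rows.append(
                {"subject_id": sid, "status": _classify_failure(exc), "warnings": 0}
            )
    features = pd.DataFrame(feature_rows)
    if len(features):
        features = features[
            ["subject_id"] + [c for c in features.columns if c != "subject_id"]
        ]
    features_path = out_dir / "features.csv"
    run_manifest_path = out_dir / "run_manifest.csv"
    features.to_csv(features_path, index=False)
    pd.DataFrame(status_rows).to_csv(run_manifest_path, index=False)
    config.to_yaml(out_dir / "config.yaml")
    return features_path, run_manifest_path


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def analyze_cohort(config: RunConfig, table: pd.DataFrame) -> dict:
    """Run the full statistical report on a joined feature + metadata table.

    Descriptive mean/SD per (sex, group) cell; scalar-statistic AUC
    with stratified bootstrap CI per metric and sex (cases expected
    lower, so AUC > 0.5 means the marker separates in the pathological
    direction); the correlation screen of interpretable features
    against MFCC features; AIC model selection for MFCC2 among controls
    (sex and age factors); and one-way ANOVA of MFCC2 across groups.
    """
    report: dict = {"n_subjects": int(len(table))}

    metrics = [m for m in AUC_METRICS if m in table.columns]
    desc = descriptive_table(table, metrics, by=["sex", "group"])
    report["descriptive"] = desc.to_dict(orient="records")

    groups = sorted(table["group"].unique())
    auc_rows = []
    if "case" in groups and "control" in groups:
        for metric in metrics:
            for sex in sorted(table["sex"].unique()):
                sub = table[table["sex"] == sex]
                if sub["group"].nunique() < 2:
                    continue
                roc = bootstrap_auc_ci(
                    sub[metric].values,
                    sub["group"].values,
                    positive_label="case",
                    direction="positive_lower",
                    n_boot=config.n_boot,
                    alpha=config.alpha,
                    seed=config.seed,
                )
                auc_rows.append(
                    {
                        "metric": metric,
                        "sex": sex,
                        "auc": roc.auc,
                        "ci_low": roc.ci_low,
                        "ci_high": roc.ci_high,
                        "n_cases": roc.n_cases,
                        "n_controls": roc.n_controls,
                    }
                )
    else:
        warnings.warn("case or control group empty: descriptive tables only", stacklevel=2)
    report["auc"] = auc_rows

    mfcc_cols = [c for c in table.columns if c.startswith(("mfcc_mn_", "mfcc_sd_"))]
    other_cols = [
        c
        for c in table.columns
        if c.startswith(("contrast_", "flatness", "rms_", "pitch_", "jitter", "shimmer", "hnr", "cpp"))
        or c == "er_db"
    ]
    if len(table) >= 10:
        screened = correlation_screen(
            table,
            mfcc_cols,
            other_cols,
            method=config.correlation_method,
            threshold=config.correlation_threshold,
        )
    else:
        warnings.warn("fewer than 10 subjects: correlation screen skipped", stacklevel=2)
        screened = pd.DataFrame(columns=mfcc_cols)
    report["correlation_screen"] = {
        "method": config.correlation_method,
        "threshold": config.correlation_threshold,
        "retained_features": list(screened.index),
    }
    report["_correlation_matrix"] = screened

    controls = table[table["group"] == "control"]
    mfcc2_col = f"mfcc_mn_2_{int(max(config.fmax_list) / 1000)}k"
    if len(controls) >= 10 and mfcc2_col in controls.columns:
        best, fits = ols_aic_select(controls, mfcc2_col, ["sex", "age"])
        report["model_selection"] = {
            "response": mfcc2_col,
            "selected_factors": list(best.factors),
            "coefficients": best.coefficients,
            "p_values": best.p_values,
            "aic": best.aic,
            "candidates": [{"factors": list(f.factors), "aic": f.aic} for f in fits],
        }
    if len(groups) >= 2 and all((table["group"] == g).sum() >= 2 for g in groups):
        f_stat, p = one_way_anova([table.loc[table["group"] == g, mfcc2_col].values for g in groups])
        report["anova_mfcc2_by_group"] = {"F": f_stat, "p": p, "groups": groups}
    return report


def run_analyze(
    config: RunConfig,
    features_path: str | Path,
    manifest_path: str | Path,
    out_dir: str | Path,
) -> Path:
    """Join features with metadata and write the report directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features = pd.read_csv(features_path)
    meta_cols = ["subject_id", "group", "sex", "age"]
    meta = pd.read_csv(manifest_path)[meta_cols]
    unmatched = sorted(set(features["subject_id"]) - set(meta["subject_id"]))
    if unmatched:
        raise JoinError(f"feature rows without metadata: {unmatched}")
    table = meta.merge(features, on="subject_id", how="inner")

    report = analyze_cohort(config, table)
    corr = report.pop("_correlation_matrix")
    corr.to_csv(out_dir / "correlations.csv")
    pd.DataFrame(report["descriptive"]).to_csv(out_dir / "descriptive.csv", index=False)
    pd.DataFrame(report["auc"]).to_csv(out_dir / "auc.csv", index=False)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(_json_safe(report), indent=2, sort_keys=True) + "\n")
    config.to_yaml(out_dir / "config.yaml")
    return report_path


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> extract -> analyze; returns the report path."""
    out_dir = Path(out_dir)
    manifest_path = run_simulate(config, out_dir)
    features_path, _ = run_extract(config, manifest_path, out_dir)
    return run_analyze(config, features_path, manifest_path, out_dir / "report")
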