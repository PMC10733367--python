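"""Run configuration: one validated object covering the whole pipeline.

Loaded from / saved to YAML; every run writes its resolved configuration
next to its outputs so results are reproducible from the artifacts
alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # cohort simulation
    seed: int = 0
    n_per_cell: int = 30
    sample_rate_hz: int = 32000
    duration_s: float = 4.0
    control_noise_gain_median: float = 0.03
    case_noise_gain_median: float = 0.18
    noise_gain_sigma: float = 0.4
    jitter_fraction: float = 0.003
    shimmer_db: float = 0.25
    noise_band_hz: tuple[float, float] | None = None

    # segmentation
    discard_s: float = 0.75
    keep_s: float = 2.5
    min_retained_s: float = 0.5
    bridge_s: float = 0.1
    strict_segmentation: bool = False
    voicing_threshold: float = 0.45

    # MFCC
    fmin_hz: float = 133.0
    fmax_list: tuple[float, ...] = (8000.0, 12000.0)
    n_filters: int = 40
    n_coeff: int = 13
    mel_variant: str = "slaney"

    # Welch / Energy Ratio
    welch_window_s: float = 0.020
    welch_overlap: float = 0.5
    er_split_hz: float = 4000.0
    er_fmax_hz: float = 12000.0

    # statistics
    n_boot: int = 2000
    alpha: float = 0.05
    correlation_method: str = "spearman"
    correlation_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise InvalidParams("n_per_cell must be >= 1")
        if self.sample_rate_hz < 2 * max(self.fmax_list):
            raise InvalidParams("sample_rate_hz below 2 x max fmax")
        if self.er_split_hz >= self.er_fmax_hz:
            raise InvalidParams("er_split_hz must be below er_fmax_hz")
        if self.mel_variant not in ("slaney", "htk"):
            raise InvalidParams(f"unknown mel_variant {self.mel_variant!r}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise InvalidParams(f"unknown correlation_method {self.correlation_method!r}")
        if not (0 < self.alpha < 1):
            raise InvalidParams("alpha must be in (0, 1)")
        self.fmax_list = tuple(float(f) for f in self.fmax_list)
        if self.noise_band_hz is not None:
            self.noise_band_hz = (float(self.noise_band_hz[0]), float(self.noise_band_hz[1]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParams(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fmax_list"] = list(self.fmax_list)
        if self.noise_band_hz is not None:
            data["noise_band_hz"] = list(self.noise_band_hz)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def replace(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update(kwargs)
        return RunConfig(**data)
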