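"""YAML configuration covering every tunable threshold and default.

The configuration mirrors the pipeline stages: probe geometry, simulator
(cohort size, noise levels, optical properties), preprocessing thresholds,
the two model hyperparameter sets (grid-search selections as defaults),
and evaluation settings.  Unknown keys are rejected so typos cannot
silently fall back to defaults, and a stable hash of the effective
configuration is recorded in run manifests for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class GeometryConfig:
    rows: int = 4
    cols: int = 8
    pitch_mm: float = 13.0
    pad_gap_mm: float = 26.0
    masked_corner: tuple[int, int] | None = (0, 7)
    max_nn: int = 3
    tolerance_mm: float = 0.5


@dataclass
class SimulateConfig:
    n_subjects: int = 7
    n_runs: int = 5
    locus_jitter_mm: float = 10.0
    amplitude_mean_uM: float = 1.0
    amplitude_sd_uM: float = 0.25
    mua_mm: tuple[float, float] = (0.01, 0.01)
    musp_mm: tuple[float, float] = (1.0, 1.0)
    refractive_index: float = 1.4
    cardiac_hz: float = 1.1
    cardiac_dmua: float = 1e-4
    respiratory_hz: float = 0.25
    respiratory_dmua: float = 3e-5
    mayer_hz: float = 0.1
    mayer_dmua: float = 6e-5
    local_dmua: float = 8e-5
    local_cutoff_hz: float = 0.35
    trial_gain_sd: float = 0.35
    trial_latency_sd_s: float = 0.5
    noise_floor: float = 0.003
    phase_noise_rad: float = 2e-3
    bad_channel_fraction: float = 0.0


@dataclass
class PreprocessSettings:
    cv_threshold: float = 7.5
    frac_threshold: float = 0.30
    short_sds_mm: float = 30.0
    max_sds_mm: float = 30.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.5
    filter_order: int = 3
    target_fs_hz: float = 2.0
    frames_per_example: int = 20
    conversion: str = "mbll"


@dataclass
class ModelConfig:
    n_conv_layers: int = 1
    n_filters: int = 16
    temporal_kernel: int = 4
    spatial_kernel: int = 3
    n_fc_layers: int = 2
    fc_size: int = 100
    dropout_rate: float = 0.4
    batch_size: int = 50
    n_epochs: int = 60
    learning_rate: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        for name in ("n_filters", "fc_size", "batch_size", "n_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class EvaluateConfig:
    scheme: str = "subject_independent"
    n_repeats: int = 10
    n_epochs: int | None = None  # override for reduced-epoch evaluation


@dataclass
class Config:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    cnn3d: ModelConfig = field(default_factory=ModelConfig)
    cnn1d: ModelConfig = field(
        default_factory=lambda: ModelConfig(n_filters=8, dropout_rate=0.8)
    )
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys under {path}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path) -> Config:
    """Load and validate a YAML config; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    sections = {
        "geometry": GeometryConfig,
        "simulate": SimulateConfig,
        "preprocess": PreprocessSettings,
        "cnn3d": ModelConfig,
        "cnn1d": ModelConfig,
        "evaluate": EvaluateConfig,
    }
    unknown = set(raw) - set(sections)
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    return Config(**kwargs)
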