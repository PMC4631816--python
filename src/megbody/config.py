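"""Run configuration: YAML-backed parameter blocks for the full pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .simulate import SimulationConfig


class ConfigError(ValueError):
    """Raised when a run configuration is missing or malformed."""


@dataclass(frozen=True)
class DecodingConfig:
    k_folds: int = 10
    svm_c: float = 1.0
    n_random_partitions: int = 20
    feature_win_ms: float = 20.0
    feature_step_ms: float = 10.0
    feature_range_ms: tuple[float, float] = (-100.0, 500.0)


@dataclass(frozen=True)
class InverseConfig:
    lam: float = 0.1
    shrinkage: float = 0.1
    train_window_ms: tuple[float, float] = (140.0, 240.0)
    f_window_ms: tuple[float, float] = (180.0, 200.0)


@dataclass(frozen=True)
class RunConfig:
    """All parameter blocks for a cohort run, plus the master seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    n_subjects: int = 9
    seed: int = 0

    REQUIRED_BLOCKS = ("simulation", "preprocessing", "inverse", "decoding")

    def content_hash(self) -> str:
        """Stable short hash of the full configuration (recorded in outputs)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_BLOCK_TYPES = {
    "simulation": SimulationConfig,
    "preprocessing": PreprocessConfig,
    "inverse": InverseConfig,
    "decoding": DecodingConfig,
}

_TUPLE_FIELDS = {
    "bandpass", "baseline", "train_window_ms", "f_window_ms", "feature_range_ms",
}


def _build_block(cls, raw: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in raw.items()
    }
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; every block must be present."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    missing = [b for b in RunConfig.REQUIRED_BLOCKS if b not in raw]
    if missing:
        raise ConfigError(f"config missing required block(s): {missing}")
    blocks = {
        name: _build_block(cls, raw.get(name) or {})
        for name, cls in _BLOCK_TYPES.items()
    }
    return RunConfig(
        **blocks,
        n_subjects=int(raw.get("n_subjects", 9)),
        seed=int(raw.get("seed", 0)),
    )


def smoke_config(seed: int = 0) -> RunConfig:
    """Tiny preset (1 subject, 16 channels, 64 vertices) for fast end-to-end runs."""
    return RunConfig(
        simulation=SimulationConfig(
            n_channels=16, n_vertices=64, repetitions=5, n_shared=3, n_unique=2,
            n_background=5, sfreq=250.0,
        ),
        n_subjects=1,
        seed=seed,
    )
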