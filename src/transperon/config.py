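"""Parameter containers for simulation and detection, with YAML round-tripping.

All physical lengths are micrometres; array axes are ordered (z, y, x).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

NOISE_MODELS = ("none", "poisson", "gaussian", "poisson+gaussian")


def _triple(value, name: str) -> tuple[float, float, float]:
    if isinstance(value, (int, float)):
        value = (value, value, value)
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValidationError(f"{name} must be a scalar or a (z, y, x) triple")
    return t


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic microscopy generator.

    ``true_rho`` is the ground-truth fraction of reference-channel (A) spots
    that have a jittered partner in channel B; it is the quantity the
    co-localization pipeline is asked to recover.
    """

    n_cells: int = 150
    spots_per_cell_mean: float = 50.0
    spots_per_cell_mean_b: float | None = None  # defaults to channel A's mean
    true_rho: float = 0.5
    jitter_sigma: float = 0.1
    nuclear_fraction: float | None = None  # None → uniform over whole cell
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    psf_sigma: tuple[float, float, float] = (0.35, 0.13, 0.13)
    cell_radius: tuple[float, float, float] = (2.8, 3.5, 3.5)
    nucleus_radius_frac: float = 0.45
    min_spot_separation: float = 0.0  # enforce ≥ this distance between spots
    background_level: float = 100.0
    peak_intensity: float = 1000.0
    nuclear_stain_level: float = 400.0
    noise_model: str = "poisson"
    gaussian_noise_sigma: float = 10.0
    field_shape: tuple[int, int, int] | None = None  # voxels; None → auto
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.spots_per_cell_mean < 0:
            raise ValidationError("spots_per_cell_mean must be >= 0")
        if self.spots_per_cell_mean_b is not None and self.spots_per_cell_mean_b < 0:
            raise ValidationError("spots_per_cell_mean_b must be >= 0")
        if not 0.0 <= self.true_rho <= 1.0:
            raise ValidationError("true_rho must lie in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.nuclear_fraction is not None and not 0 <= self.nuclear_fraction <= 1:
            raise ValidationError("nuclear_fraction must lie in [0, 1]")
        object.__setattr__(self, "voxel_size", _triple(self.voxel_size, "voxel_size"))
        object.__setattr__(self, "psf_sigma", _triple(self.psf_sigma, "psf_sigma"))
        object.__setattr__(self, "cell_radius", _triple(self.cell_radius, "cell_radius"))
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size entries must be > 0")
        if any(v <= 0 for v in self.psf_sigma):
            raise ValidationError("psf_sigma entries must be > 0")
        if any(v <= 0 for v in self.cell_radius):
            raise ValidationError("cell_radius entries must be > 0")
        if not 0 < self.nucleus_radius_frac < 1:
            raise ValidationError("nucleus_radius_frac must lie in (0, 1)")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.field_shape is not None:
            shape = tuple(int(v) for v in self.field_shape)
            if len(shape) != 3 or any(v <= 0 for v in shape):
                raise ValidationError("field_shape must be a positive (z, y, x) triple")
            object.__setattr__(self, "field_shape", shape)

    @property
    def mean_b(self) -> float:
        if self.spots_per_cell_mean_b is None:
            return self.spots_per_cell_mean
        return self.spots_per_cell_mean_b


@dataclass(frozen=True)
class DetectionParams:
    """Settings for LoG candidate detection plus Gaussian refinement."""

    smoothing_sigma: tuple[float, float, float] = (0.35, 0.13, 0.13)
    threshold_mode: str = "robust-zscore"
    threshold_value: float = 5.0
    min_separation: float = 0.3
    fit_window: int = 9
    quality_min: float = 0.3

    def __post_init__(self):
        object.__setattr__(
            self, "smoothing_sigma", _triple(self.smoothing_sigma, "smoothing_sigma")
        )
        if any(v <= 0 for v in self.smoothing_sigma):
            raise ValidationError("smoothing_sigma entries must be > 0")
        if self.threshold_mode not in ("absolute", "robust-zscore"):
            raise ValidationError("threshold_mode must be 'absolute' or 'robust-zscore'")
        if self.min_separation <= 0:
            raise ValidationError("min_separation must be > 0")
        if self.fit_window < 3 or self.fit_window % 2 == 0:
            raise ValidationError("fit_window must be an odd integer >= 3")
        if not 0 <= self.quality_min <= 1:
            raise ValidationError("quality_min must lie in [0, 1]")


def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def config_to_dict(cfg) -> dict:
    """Serializable plain-dict view of a config dataclass."""
    return _asdict(cfg)


def config_from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return data


def save_yaml_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(cfg), fh, sort_keys=True)


def config_hash(data) -> str:
    """Stable short hash of a config (dataclass or plain dict)."""
    if dataclasses.is_dataclass(data):
        data = _asdict(data)
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
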