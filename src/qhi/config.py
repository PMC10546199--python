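"""Run configuration: YAML schema, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import constants

__all__ = ["RunConfig", "load_config", "config_hash"]


class PathsConfig(BaseModel):
    data_dir: str
    output_dir: str


class PhysicsConfig(BaseModel):
    n: float = constants.DEFAULT_REFRACTIVE_INDEX
    lambda_lsi_nm: float = constants.LSI_WAVELENGTH_NM
    exposure_s: float = constants.DEFAULT_EXPOSURE_S
    raw_rate_hz: float = constants.DEFAULT_RAW_RATE_HZ
    wavelengths_nm: tuple[float, float, float] = constants.SFDI_WAVELENGTHS_NM
    fx_pair: tuple[float, float] = constants.SFDI_FX_PAIR
    pixel_pitch_mm: float = constants.PIXEL_PITCH_MM

    @field_validator("n", "lambda_lsi_nm", "exposure_s", "raw_rate_hz",
                     "pixel_pitch_mm")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v


class LutConfig(BaseModel):
    rd_points: int = 512
    k2_n_db: int = 256
    k2_n_mua: int = 128
    k2_n_musp: int = 128
    db_max: float = 20e-6


class FilterConfig(BaseModel):
    gaussian_window: int = 15
    contrast_window: int = 5
    moving_average: int = 50


class SimulateConfig(BaseModel):
    scene: str = "brain"
    shape: tuple[int, int] = (256, 256)
    cycles: int = 3
    noise_sd: float = 0.0
    m0: float = 60000.0
    mean_counts: float = 60.0
    oversample: int = 2
    substeps: int = 64
    beta_frames: int = 8
    #: list of [modality, cycle, index] frames to drop from the dataset
    drop: list[tuple[str, int, int]] = Field(default_factory=list)


class RunConfig(BaseModel):
    paths: PathsConfig
    physics: PhysicsConfig = Field(default_factory=PhysicsConfig)
    luts: LutConfig = Field(default_factory=LutConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls.model_validate(d)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration, echoed into every output."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
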