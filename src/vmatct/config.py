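"""YAML run configuration: schema, validation, defaults.

The configuration mirrors the algorithm defaults (mu=2, delta=1, alpha=1,
beta=0.3, stop threshold r=0.005, N_stop=20, 10 inner denoising loops);
an empty file therefore yields a fully usable configuration.  Unknown
keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .denoise import BM3DParams, DenoiseConfig
from .geometry import ConeBeamGeometry
from .local_filter import LocalFilterKernel
from .metrics import SsimParams
from .pipeline import ReconConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    source_to_axis_distance_mm: float = Field(1000.0, gt=0)
    source_to_detector_distance_mm: float = Field(1600.0, gt=0)
    detector_rows: int = Field(96, ge=1)
    detector_cols: int = Field(96, ge=1)
    detector_pixel_pitch_mm: float = Field(2.5, gt=0)
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = Field(2.0, gt=0)

    def build(self) -> ConeBeamGeometry:
        return ConeBeamGeometry(**self.model_dump())


class DenoiseBlock(_Strict):
    mu: float = Field(2.0, gt=0)
    delta: float = Field(1.0, gt=0)
    alpha: float = Field(1.0, gt=0)
    beta: float = Field(0.3, gt=0)
    inner_loops: int = Field(10, ge=0)

    def build(self) -> DenoiseConfig:
        return DenoiseConfig(**self.model_dump())


class BM3DBlock(_Strict):
    block_size: int = Field(8, ge=4)
    search_radius: int = Field(16, ge=4)
    max_group: int = Field(16, ge=1)
    hard_threshold_multiplier: float = Field(2.7, ge=0)
    noise_sigma: float | None = None
    ref_step: int = Field(4, ge=1)

    def build(self) -> BM3DParams:
        return BM3DParams(**self.model_dump())


class KernelBlock(_Strict):
    taps: tuple[float, ...] = (-1.0, 2.0, -1.0)
    normalization: float = 1.0

    def build(self) -> LocalFilterKernel:
        return LocalFilterKernel(self.taps, self.normalization)


class ReconBlock(_Strict):
    relaxation: float = Field(1.0, gt=0)
    stop_threshold: float = Field(0.005, gt=0)
    max_iterations: int = Field(20, ge=1)


class SsimBlock(_Strict):
    window_sigma: float = Field(1.5, gt=0)
    window_size: int = Field(11, ge=3)
    dynamic_range: float | None = None
    C1: float | None = None
    C2: float | None = None

    def build(self) -> SsimParams:
        return SsimParams(**self.model_dump())


class RunConfig(_Strict):
    """Top-level, schema-versioned run configuration."""

    schema_version: int = SCHEMA_VERSION
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    denoise: DenoiseBlock = Field(default_factory=DenoiseBlock)
    bm3d: BM3DBlock = Field(default_factory=BM3DBlock)
    kernel: KernelBlock = Field(default_factory=KernelBlock)
    recon: ReconBlock = Field(default_factory=ReconBlock)
    ssim: SsimBlock = Field(default_factory=SsimBlock)
    seed: int = 1

    def build_geometry(self) -> ConeBeamGeometry:
        return self.geometry.build()

    def build_recon_config(self) -> ReconConfig:
        return ReconConfig(
            denoise=self.denoise.build(),
            bm3d=self.bm3d.build(),
            kernel=self.kernel.build(),
            relaxation=self.recon.relaxation,
            stop_threshold=self.recon.stop_threshold,
            max_iterations=self.recon.max_iterations)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        bad = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors())
        raise ConfigError(f"invalid config: {bad}") from exc
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.schema_version}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
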