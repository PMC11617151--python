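"""Pipeline configuration: schema-validated YAML via pydantic models."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ParameterError

__all__ = ["PipelineConfig", "load_config", "default_config"]


class SplitConfig(BaseModel):
    strategy: str = "random"            # random | by_experiment
    train_fraction: float = Field(0.8, gt=0.0, lt=1.0)
    train_experiment: str = "exp1"

    @field_validator("strategy")
    @classmethod
    def _check_strategy(cls, v):
        if v not in ("random", "by_experiment"):
            raise ValueError(f"unknown split strategy {v!r}")
        return v


class TransformConfig(BaseModel):
    sg_window_bands: int = 15
    sg_poly_order: int = 2
    continuum_lo_nm: int | None = None
    continuum_hi_nm: int | None = None


class EvaluateConfig(BaseModel):
    estimators: list[str] | None = None          # None -> all 14
    spectral_sets: list[str] | None = None       # None -> all 8
    chl_metrics: list[str] | None = None         # None -> all 6
    cv_splits: int = Field(5, ge=2)
    cv_repeats: int = Field(10, ge=1)
    band_step_nm: int = Field(1, ge=1)           # ML feature subsampling


class ImportanceConfig(BaseModel):
    features: str = "svi"                         # svi | reflectance
    cutoff: float | None = 1.0
    n_clusters: int | None = None
    n_iterations: int = Field(10_000, ge=1)
    band_step_nm: int = Field(1, ge=1)

    @field_validator("features")
    @classmethod
    def _check_features(cls, v):
        if v not in ("svi", "reflectance"):
            raise ValueError(f"unknown importance feature set {v!r}")
        return v


class GeneratorConfig(BaseModel):
    """Synthetic-trial overrides; defaults follow the two study designs."""

    scale_collections: float = Field(1.0, gt=0, le=1.0)  # thin collections for quick runs
    spectral_noise_sd: float = 0.004
    paired_rmsd_pct: float = 9.0


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: Path = Path("runs/latest")
    simulate: bool = True
    spectra_csv: Path | None = None               # used when simulate=false
    chlorophyll_csv: Path | None = None
    scale: str = "plot"
    split: SplitConfig = SplitConfig()
    transform: TransformConfig = TransformConfig()
    evaluate: EvaluateConfig = EvaluateConfig()
    importance: ImportanceConfig = ImportanceConfig()
    generator: GeneratorConfig = GeneratorConfig()

    @field_validator("scale")
    @classmethod
    def _check_scale(cls, v):
        if v not in ("sample", "leaf", "plot", "entry"):
            raise ValueError(f"unknown scale {v!r}")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ParameterError(f"invalid configuration: {exc}") from exc


def default_config() -> PipelineConfig:
    return PipelineConfig()
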