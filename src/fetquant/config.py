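"""Analysis configuration (validated, JSON round-trippable)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .phantom import DEFAULT_METHOD_PROFILES, MethodProfile

__all__ = ["MethodProfileConfig", "CohortConfig", "AnalysisConfig"]


class MethodProfileConfig(BaseModel):
    scale_err_mean: float
    scale_err_sd: float
    scale_err_max: float
    gradient_surface_mean: float = 0.0
    gradient_surface_sd: float = 0.0
    gradient_center_mean: float = 0.0
    gradient_center_sd: float = 0.0
    nodule_prob: float = 0.0
    nodule_amplitude_mean: float = 0.1
    nodule_amplitude_sd: float = 0.03
    nodule_fwhm_mm: float = 25.0
    void_prob: float = 0.0
    void_amplitude: float = -0.35
    void_radius_mm: float = 8.0

    def to_profile(self) -> MethodProfile:
        return MethodProfile(**self.model_dump())


def _default_profiles() -> dict[str, MethodProfileConfig]:
    return {
        label: MethodProfileConfig(**vars(profile))
        for label, profile in DEFAULT_METHOD_PROFILES.items()
    }


class CohortConfig(BaseModel):
    n_subjects: int = Field(default=20, ge=1)
    followup_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = Field(default=0.02, ge=0.0)
    method_profiles: dict[str, MethodProfileConfig] = Field(
        default_factory=_default_profiles
    )

    @field_validator("spacing_mm")
    @classmethod
    def _positive_spacing(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("spacing must be positive")
        return v


class AcceptanceConfig(BaseModel):
    t_mean_abs: float = 0.05
    t_max_abs: float = 0.1
    ratio_rel_pct: float = 5.0
    btv_abs_ml: float = 2.0
    btv_rel_pct: float = 10.0
    peak_mm: float = 10.0


class AnalysisConfig(BaseModel):
    """Full pipeline configuration.

    Either a synthetic cohort is generated from ``cohort`` or existing
    studies are read from ``cohort_dir`` (a directory previously written by
    :func:`fetquant.io.write_cohort`).
    """

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    cohort_dir: Optional[str] = None
    reference_label: str = "CTAC"
    threshold_ratio: float = Field(default=1.6, gt=1.0)
    min_component_ml: float = 0.1
    acceptance: AcceptanceConfig = Field(default_factory=AcceptanceConfig)
    smoothing_fwhm_mm: float = 5.0
    binarization_level: float = 0.5
    stability_band_pct: float = 2.0
    followup_ratio_points: float = 5.0
    followup_btv_points: float = 10.0
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
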