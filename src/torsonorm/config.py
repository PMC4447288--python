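"""Pipeline configuration: the single source of all tunables.

Defaults reproduce the documented detector rules; every threshold that the
rule-based scheme leaves open (search bands, adaptive thresholds, smoothing)
is surfaced here so a run can be audited and reproduced from its echoed
config.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class PipelineConfig(BaseModel):
    # segmentation
    body_threshold: float = Field(0.5, gt=0)
    bladder_min_suv: float = Field(5.0, gt=0)
    bladder_rel_factor: float = Field(3.0, gt=0)
    bladder_z_fraction: float = Field(0.4, gt=0, le=1)
    bladder_x_fraction: float = Field(0.5, gt=0, le=1)
    liver_rel_factor: float = Field(1.3, gt=0)
    liver_min_region: int = Field(20, ge=1)
    liver_z_fraction: float = Field(0.40, ge=0, lt=1)
    # landmark detection
    ns_band_fraction: float = Field(0.35, gt=0, le=1)
    ac_smooth_window: int = Field(3, ge=1)
    ac_max_relative_depth: float = Field(0.6, gt=0, le=1)
    thigh_min_component: int = Field(50, ge=1)
    bl_fallback_fraction: float = Field(0.30, gt=0, lt=1)
    # registration
    slab_mode: str = Field("piecewise")  # "piecewise" (exact) or "global" (12-dof LS)
    angular_step: int = Field(15, ge=1, le=120)
    level_spacing: int = Field(5, ge=1)
    tps_lambda: float = Field(0.0, ge=0)
    # scoring
    sd_floor: float = Field(0.05, gt=0)
    # reproducibility
    seed: int = Field(0, ge=0)

    @field_validator("slab_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("piecewise", "global"):
            raise ValueError("slab_mode must be 'piecewise' or 'global'")
        return v

    @model_validator(mode="after")
    def _check_angles(self) -> "PipelineConfig":
        if 360 % self.angular_step != 0:
            raise ValueError(f"angular_step must divide 360, got {self.angular_step}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return self.model_dump()
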