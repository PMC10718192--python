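"""Validated run configuration (YAML/JSON) for the simulation pipeline.

Every stochastic stage derives its randomness from the single ``seed`` field,
so a configuration file fully determines a run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .perfusion import MSI_PARAMETERS, BandSelection
from .phantom import PHASE_LABELS, OcclusionProtocol, StudyDesign

__all__ = ["RunConfig", "load_config", "save_config"]


class DesignConfig(BaseModel):
    measurements_per_participant: int = Field(16, ge=1)
    participants_per_distance: int = Field(4, ge=1)
    distances_mm: list[float] = [35.0, 45.0, 55.0]

    def to_design(self) -> StudyDesign:
        return StudyDesign(
            self.measurements_per_participant,
            self.participants_per_distance,
            tuple(self.distances_mm),
        )


class PhaseConfig(BaseModel):
    label: Literal[PHASE_LABELS]  # type: ignore[valid-type]
    duration_min: float = Field(gt=0)


class ProtocolConfig(BaseModel):
    phases: list[PhaseConfig] = [
        PhaseConfig(label="baseline", duration_min=2.0),
        PhaseConfig(label="venous", duration_min=2.0),
        PhaseConfig(label="reperfusion1", duration_min=5.0),
        PhaseConfig(label="arterial", duration_min=2.0),
        PhaseConfig(label="reperfusion2", duration_min=5.0),
    ]
    frames_per_min: int = Field(600, ge=1)
    reference_blocks_per_min: int = Field(1, ge=1)

    def to_protocol(self) -> OcclusionProtocol:
        return OcclusionProtocol(
            phases=tuple((p.label, p.duration_min) for p in self.phases),
            frames_per_min=self.frames_per_min,
            reference_blocks_per_min=self.reference_blocks_per_min,
        )


class SelectionConfig(BaseModel):
    s1_bands: list[float]
    s2_bands: list[float]


class MarkerConfig(BaseModel):
    per_measurement: int = Field(8, ge=1, le=8)
    #: pixel diameter of the circular reference object used to size markers
    reference_object_diameter_px: float = Field(6.0, gt=0)

    @property
    def radius_px(self) -> float:
        return self.reference_object_diameter_px / 2.0


class SplitConfig(BaseModel):
    calib_fraction: float = Field(0.7, gt=0, lt=1)
    n_candidates: int = Field(1000, ge=1)


class NoiseConfig(BaseModel):
    target_snr_db: float | None = 30.0


class RunConfig(BaseModel):
    """Top-level configuration of a simulate/analyze run."""

    design: DesignConfig = DesignConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    marker: MarkerConfig = MarkerConfig()
    split: SplitConfig = SplitConfig()
    noise: NoiseConfig = NoiseConfig()
    selections: dict[str, SelectionConfig] | None = None
    shape: list[int] = [64, 64]
    reference_mode: Literal["tissue", "affine-rr"] = "tissue"
    snr_frames: int = Field(200, ge=0)
    cv_folds: int = Field(5, ge=2)
    seed: int = 0

    @field_validator("shape")
    @classmethod
    def _shape_2d(cls, v: list[int]) -> list[int]:
        if len(v) != 2 or any(s < 8 for s in v):
            raise ValueError("shape must be [H, W] with H, W >= 8")
        return v

    @field_validator("selections")
    @classmethod
    def _known_parameters(cls, v):
        if v is not None:
            unknown = set(v) - set(MSI_PARAMETERS)
            if unknown:
                raise ValueError(f"unknown parameters {sorted(unknown)}")
        return v

    def to_selections(self):
        from .perfusion import default_selections

        sel = default_selections()
        if self.selections:
            for param, sc in self.selections.items():
                sel[param] = BandSelection(param, tuple(sc.s1_bands), tuple(sc.s2_bands))
        return sel


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
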