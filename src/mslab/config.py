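"""Study configuration: validated YAML round-trip of all pipeline settings."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .bloch import SlabAcquisition
from .recon import ReconConfig

__all__ = ["StudyConfig", "load_config", "save_config"]


class PulseSettings(BaseModel):
    tbw_ex: float = 20.0
    tbw_ref: float = 8.0
    duration_ex_ms: float = 7.18
    duration_ref_ms: float = 10.24
    n_samples: int = 256


class GeometrySettings(BaseModel):
    n_slabs: int = 9
    slices_per_slab: int = 10
    slice_thickness_mm: float = 1.5
    overlap_slices: int = 2
    tr_ms: float = 2000.0
    te_ms: float = 78.0
    ordering: str = "interleaved"

    @field_validator("ordering")
    @classmethod
    def _check_ordering(cls, v: str) -> str:
        if v not in ("sequential", "interleaved"):
            raise ValueError("ordering must be sequential or interleaved")
        return v

    def to_acquisition(self) -> SlabAcquisition:
        return SlabAcquisition(
            n_slabs=self.n_slabs,
            slices_per_slab=self.slices_per_slab,
            slice_thickness=self.slice_thickness_mm,
            overlap_slices=self.overlap_slices,
            TR=self.tr_ms,
            ordering=self.ordering,
            TE=self.te_ms,
        )


class PhantomSettings(BaseModel):
    nx: int = 48
    ny: int = 48
    seed: int = 7
    noise_std: float = 0.0


class ReconSettings(BaseModel):
    methods: list[str] = Field(default_factory=lambda: ["wa", "pen", "npen"])
    alpha0: float = 0.2
    beta0: float = 0.4
    decay: float = 1.5
    beta_floor: float = 0.03
    max_outer_iters: int = 15
    burn_in: int = 3
    cg_iters: int = 30
    cg_tol: float = 1e-4
    sigma_k: float = 0.2
    threshold: float = 0.8

    @field_validator("methods")
    @classmethod
    def _check_methods(cls, v):
        for m in v:
            if m not in ("wa", "pen", "npen"):
                raise ValueError(f"unknown method {m!r}")
        return v

    def to_recon_config(self) -> ReconConfig:
        return ReconConfig(
            alpha0=self.alpha0, beta0=self.beta0, decay=self.decay,
            beta_floor=self.beta_floor, max_outer_iters=self.max_outer_iters,
            burn_in=self.burn_in, cg_iters=self.cg_iters, cg_tol=self.cg_tol,
            sigma_k=self.sigma_k,
        )


class StudyConfig(BaseModel):
    """Top-level configuration for the simulation -> reconstruction pipeline."""

    geometry: GeometrySettings = Field(default_factory=GeometrySettings)
    pulses: PulseSettings = Field(default_factory=PulseSettings)
    phantom: PhantomSettings = Field(default_factory=PhantomSettings)
    recon: ReconSettings = Field(default_factory=ReconSettings)
    seed: int = 7
    out_dir: str = "mslab_out"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig.model_validate(raw)


def save_config(cfg: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
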