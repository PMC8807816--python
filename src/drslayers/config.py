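"""Flat run configuration: one file drives generation, preprocessing and evaluation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run, serializable to a flat YAML mapping.

    Generator: ``preset`` selects the phantom thickness ramp or the two-
    stratum animal study; counts and noise follow the study designs.
    Preprocessing: stitching crossover and whether the NIR segment is
    rescaled to meet the VIS segment. Evaluation: grouped k-fold settings.
    """

    seed: int = 0
    preset: str = "animal"  # "phantom" | "animal"
    # phantom generator
    n_locations: int = 15
    n_orientations: int = 4
    n_repeats: int = 3
    # animal generator
    n_per_class: int = 100
    thickness_max: float = 6.0
    include_zero_thickness: bool = True
    thickness_jitter_sd: float = 0.0
    # shared generator noise
    noise_sd: float = 0.01
    speckle_scale: float = 0.15
    pixel_mm: float = 0.05
    # preprocessing
    crossover_nm: float = 1000.0
    rescale_nir: bool = True
    # ultrasound segmentation
    contact_guard_rows: int = 3
    path_exclusion_margin: int = 2
    # cross-validation
    cv_folds: int = 10
    cv_iterations: int = 20

    def __post_init__(self) -> None:
        if self.preset not in ("phantom", "animal"):
            raise ValueError("preset must be 'phantom' or 'animal'")

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, for output provenance."""
        text = "\n".join(f"{k}={v}" for k, v in sorted(self.as_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML mapping; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))
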