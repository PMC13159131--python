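"""Pipeline configuration: one flat, validated key-value document.

Keys mirror the per-module defaults (frame interval, localization
noise, detection threshold, linker gates, MSD fit windows, α
thresholds, population QC floor, bootstrap size, cluster scales).
Unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # acquisition / simulation
    dt: float = 0.1                 # frame interval, s (10 Hz)
    sigma_loc: float = 0.03         # localization noise s.d., µm
    pixel_size: float = 0.107       # µm/px
    psf_sigma: float = 0.1          # PSF s.d., µm
    photons_per_spot: float = 300.0
    background: float = 20.0
    bleach_prob: float = 0.0
    density: float = 0.2            # spots/µm²
    field_size: float = 25.6        # µm
    # detection
    threshold_factor: float = 5.0
    # linking
    r_max: float = 2.5              # µm
    gap_max: int = 1
    min_len: int = 20               # frames
    # msd / classification
    n_fit_D: int = 4
    alpha_max_lag: int = 10
    confined_max: float = 0.7
    directed_min: float = 1.3
    # population stats
    min_traj: int = 1000
    n_boot: int = 2000
    # clustering
    eps: float = 0.05               # µm
    min_pts: int = 10
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("dt", "pixel_size", "psf_sigma", "photons_per_spot",
                    "field_size", "threshold_factor", "r_max", "eps")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"config: {name} must be > 0, got {getattr(self, name)}")
        nonneg = ("sigma_loc", "background", "bleach_prob", "density")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"config: {name} must be >= 0, got {getattr(self, name)}")
        if self.gap_max < 0:
            raise ValueError(f"config: gap_max must be >= 0, got {self.gap_max}")
        if self.min_len < 2:
            raise ValueError(f"config: min_len must be >= 2, got {self.min_len}")
        if self.n_fit_D < 2:
            raise ValueError(f"config: n_fit_D must be >= 2, got {self.n_fit_D}")
        if self.alpha_max_lag < 3:
            raise ValueError(f"config: alpha_max_lag must be >= 3, got {self.alpha_max_lag}")
        if not (0.0 < self.confined_max < self.directed_min < 2.5):
            raise ValueError(
                "config: need 0 < confined_max < directed_min < 2.5, got "
                f"({self.confined_max}, {self.directed_min})"
            )
        if self.min_traj < 1:
            raise ValueError(f"config: min_traj must be >= 1, got {self.min_traj}")
        if self.n_boot < 1:
            raise ValueError(f"config: n_boot must be >= 1, got {self.n_boot}")
        if self.min_pts < 1:
            raise ValueError(f"config: min_pts must be >= 1, got {self.min_pts}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"config: unknown keys {unknown}; valid keys: {sorted(known)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if d is None:
            d = {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration (for run provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
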