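"""Simulation and pipeline configuration objects (YAML/JSON round-trip)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic chip-image generator.

    The generator emulates single cancer cells and aggregates embedded in the
    ~500 µm-wide gel channel of an 8-chip device, imaged in bright-field plus
    two viability-stain channels (DAPI: all nuclei; TRITC: dead cells),
    growing over days and dying under drug following a four-parameter
    logistic (4PL) viability curve.

    Parameters
    ----------
    channel_width_px, channel_height_px
        Rendered region-of-interest size in pixels. The default mirrors the
        ~1000×300 px chip ROI at a 4x objective.
    seeding_density
        Cells per chip at day 0 (devices are seeded with 300–5000 cells).
    base_radius_px, radius_cv
        Day-0 mean cell radius (px) and its coefficient of variation.
    growth_rate
        Per-day multiplicative radius factor (>1 means growth).
    aggregate_fraction_per_day
        Fraction of cells newly recruited into multicellular clusters per
        day of culture (capped at 0.8 overall).
    baseline_death_fraction
        Drug-independent dead fraction present at every timepoint.
    drug_bottom, drug_top, drug_ic50, drug_hill
        4PL viability-vs-dose parameters; viability is the expected live
        fraction, dose in µM, ``drug_ic50`` at the curve midpoint.
    stain_unevenness_amplitude
        Amplitude in [0, 1] of a smooth multiplicative field applied to the
        fluorescence channels only (mimics uneven staining in 3D gels).
    noise_sd
        Gaussian detector-noise SD in intensity units of the output bit
        depth, added last to every channel.
    bit_depth
        8 or 16; output TIFFs use the matching unsigned integer dtype.
    seed
        Master seed; a fixed seed makes every rendered byte reproducible.
    """

    channel_width_px: int = 1024
    channel_height_px: int = 320
    seeding_density: int = 300
    base_radius_px: float = 4.0
    radius_cv: float = 0.25
    growth_rate: float = 1.12
    aggregate_fraction_per_day: float = 0.06
    baseline_death_fraction: float = 0.02
    drug_bottom: float = 0.05
    drug_top: float = 1.0
    drug_ic50: float = 1.0
    drug_hill: float = 1.5
    stain_unevenness_amplitude: float = 0.15
    noise_sd: float = 300.0
    bit_depth: int = 16
    pixel_size_um: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_width_px <= 0 or self.channel_height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.seeding_density <= 0:
            raise ConfigurationError("seeding_density must be positive")
        if self.base_radius_px <= 0:
            raise ConfigurationError("base_radius_px must be positive")
        if not 0.0 <= self.drug_bottom <= self.drug_top <= 1.0:
            raise ConfigurationError("require 0 <= drug_bottom <= drug_top <= 1")
        if self.drug_ic50 <= 0:
            raise ConfigurationError("drug_ic50 must be positive")
        if not 0.0 <= self.stain_unevenness_amplitude <= 1.0:
            raise ConfigurationError("stain_unevenness_amplitude must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
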