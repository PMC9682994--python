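"""Pipeline configuration: one flat record of every tunable parameter.

Defaults follow the published protocol this toolkit implements:
max_edge_length 0.8 on fractional/unit-box coordinates, 2500 landscape
samples per homology dimension (5 levels × 500 grid points), a 0.95
noise-similarity threshold, the 60 %/40 % cluster purity rule, 100 forest
estimators and an 85/15 train/test split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    max_edge_length: float = 0.8
    landscape_levels: int = 5
    landscape_grid_points: int = 500
    noise_similarity_threshold: float = 0.95
    purity_cage_threshold: float = 0.60
    purity_non_cage_threshold: float = 0.40
    n_estimators: int = 100
    test_fraction: float = 0.15
    master_seed: int = 0
    coordinate_mode: str = "as_stored"  # or "normalized_cartesian"
    bond_tolerance: float = 0.4
    apply_molecule_cleanup: bool = True  # bond/component/cycle stages; off for bond-free fixtures

    def __post_init__(self) -> None:
        if self.max_edge_length <= 0:
            raise ValueError("max_edge_length must be positive")
        if self.landscape_levels * self.landscape_grid_points != 2500:
            raise ValueError("landscape levels × grid points must equal 2500")
        for name in ("noise_similarity_threshold", "purity_cage_threshold",
                     "purity_non_cage_threshold", "test_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1) and not (name == "noise_similarity_threshold" and v == 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.coordinate_mode not in ("as_stored", "normalized_cartesian"):
            raise ValueError(f"bad coordinate_mode {self.coordinate_mode!r}")

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Flat key=value file."""
        lines = [f"{k}={v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            default = getattr(cls, "__dataclass_fields__")[key].default
            if isinstance(default, bool):
                values[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(raw)
            elif isinstance(default, float):
                values[key] = float(raw)
            else:
                values[key] = raw
        return cls(**values)

    def subseed(self, stage: str) -> int:
        """Named per-stage sub-seed derived deterministically from the master seed."""
        h = 2166136261
        for ch in stage.encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return (self.master_seed * 1000003 + h) % (2**31 - 1)
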