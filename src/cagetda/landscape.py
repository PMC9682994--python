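"""Persistence landscapes and the 5000-point fingerprint vector.

A diagram feature (b, d) contributes the tent function
Λ(t) = max(0, min(t − b, d − t)); the k-th landscape level λ_k(t) is the
k-th largest tent value at t.  Levels are sampled on a uniform grid over
[0, max_edge_length].  The fingerprint concatenates 2500 samples from the
B1 (window) landscape with 2500 from the B2 (cavity) landscape — by default
5 levels × 500 grid points per dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rips import PersistenceDiagram

DEFAULT_LEVELS = 5
DEFAULT_GRID_POINTS = 500
FINGERPRINT_LENGTH = 5000


@dataclass
class PersistenceLandscape:
    """Sampled landscape: ``levels`` is an (L, T) array, λ_1 first."""

    dim: int
    levels: np.ndarray
    grid: np.ndarray
    max_edge_length: float

    @property
    def n_samples(self) -> int:
        return int(self.levels.size)


@dataclass
class Fingerprint:
    """Fixed-length landscape vector: 2500 B1 samples then 2500 B2 samples."""

    values: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FINGERPRINT_LENGTH,):
            raise ValueError(f"fingerprint must have length {FINGERPRINT_LENGTH}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("fingerprint values must be finite and non-negative")


def compute_landscape(
    diagram: PersistenceDiagram,
    dim: int,
    levels: int = DEFAULT_LEVELS,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> PersistenceLandscape:
    """Sample the first ``levels`` landscape levels of one homology dimension.

    Essential (capped) features participate like ordinary features: their
    death was already bounded at max_edge_length by the diagram stage.
    """
    if dim not in (1, 2):
        raise ValueError("landscapes are computed for homology dimensions 1 and 2")
    if levels < 1 or grid_points < 2:
        raise ValueError("need levels >= 1 and grid_points >= 2")
    grid = np.linspace(0.0, diagram.max_edge_length, grid_points)
    pairs = diagram.in_dim(dim)
    out = np.zeros((levels, grid_points))
    if len(pairs):
        b, d = pairs[:, 0][:, None], pairs[:, 1][:, None]
        tents = np.maximum(0.0, np.minimum(grid[None, :] - b, d - grid[None, :]))
        k = min(levels, len(pairs))
        # descending sort along the feature axis -> top-k tent values per t
        top = -np.sort(-tents, axis=0)[:k]
        out[:k] = top
    return PersistenceLandscape(dim=dim, levels=out, grid=grid,
                                max_edge_length=diagram.max_edge_length)


def landscape_fingerprint(
    lands_b1: PersistenceLandscape, lands_b2: PersistenceLandscape, provenance: dict | None = None
) -> Fingerprint:
    """Concatenate B1 then B2 landscape samples into the 5000-vector."""
    half = FINGERPRINT_LENGTH // 2
    for lands, want_dim in ((lands_b1, 1), (lands_b2, 2)):
        if lands.dim != want_dim:
            raise ValueError(f"expected a dimension-{want_dim} landscape, got {lands.dim}")
        if lands.n_samples != half:
            raise ValueError(
                f"expected {half} samples per dimension (levels × grid points), "
                f"got {lands.n_samples}"
            )
    values = np.concatenate([lands_b1.levels.ravel(), lands_b2.levels.ravel()])
    return Fingerprint(values=values, provenance=provenance or {})


def fingerprint_from_diagram(
    diagram: PersistenceDiagram,
    levels: int = DEFAULT_LEVELS,
    grid_points: int = DEFAULT_GRID_POINTS,
    provenance: dict | None = None,
) -> Fingerprint:
    """Diagram → (B1, B2) landscapes → fingerprint in one step."""
    return landscape_fingerprint(
        compute_landscape(diagram, 1, levels, grid_points),
        compute_landscape(diagram, 2, levels, grid_points),
        provenance=provenance,
    )


def write_fingerprint_matrix(
    path: str | Path, ids: list[str], matrix: np.ndarray, params: dict
) -> None:
    """CSV (id column first, 5000 value columns) plus a JSON parameter sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix, columns=[f"f{i}" for i in range(matrix.shape[1])])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False, float_format="%.10g")
    Path(str(path) + ".json").write_text(json.dumps(params, indent=1) + "\n")


def read_fingerprint_matrix(path: str | Path) -> tuple[list[str], np.ndarray, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    params = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df["id"].astype(str).tolist(), df.drop(columns="id").to_numpy(float), params
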