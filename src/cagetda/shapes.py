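"""Labelled synthetic point clouds emulating the shape classes of cage mining.

Real inputs to the pipeline are fractional coordinates of single molecules,
which live on a unit-box scale; the fixtures therefore place every cloud in
the unit box (centred at 0.5) so the production default max_edge_length of
0.8 is directly meaningful.

Families
--------
ring
    points on a circle — a 2D "window" molecule; one dominant B1 feature.
cage_sphere
    near-uniform (Fibonacci lattice) sampling of a hollow sphere — an
    idealised 3D cage; one dominant B2 feature.
cage_polyhedron
    vertices (optionally with edge midpoints) of a named polyhedron —
    cage morphologies with both windows and a cavity.
bowl
    hemisphere sampling — open cavity, between ring and cage.
grid
    planar n×m lattice, optionally stacked in parallel layers (the
    single/quadruple grid archetypes used for noise removal).
chain
    collinear points — fully linear, no topological signal.

Default point counts and radii were chosen so that each family's
characteristic feature persists well inside the [0, 0.8] filtration window
while a single cloud's persistence stays around half a second on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .landscape import fingerprint_from_diagram
from .rips import rips_diagram
from .structure import PointCloud

FAMILIES = ("ring", "cage_sphere", "cage_polyhedron", "bowl", "grid", "chain")

#: family -> coarse class used by the purity rule / binary classifier
FAMILY_LABELS = {
    "ring": "ring",
    "cage_sphere": "cage",
    "cage_polyhedron": "cage",
    "bowl": "non_cage",
    "grid": "non_cage",
    "chain": "non_cage",
}

_DEF_N = {"ring": 24, "cage_sphere": 36, "cage_polyhedron": 18, "bowl": 24,
          "grid": 16, "chain": 10}

# vertex sets at unit circumradius
_PHI = (1 + 5**0.5) / 2
_POLYHEDRA = {
    "tetrahedron": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) / 3**0.5,
    "cube": np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float
    ) / 3**0.5,
    "octahedron": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    ),
    "dodecahedron": np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        + [[0, sy / _PHI, sz * _PHI] for sy in (-1, 1) for sz in (-1, 1)]
        + [[sx / _PHI, sy * _PHI, 0] for sx in (-1, 1) for sy in (-1, 1)]
        + [[sx * _PHI, 0, sz / _PHI] for sx in (-1, 1) for sz in (-1, 1)],
        float,
    ) / 3**0.5,
}


@dataclass(frozen=True)
class ShapeSpec:
    """Deterministic recipe for one synthetic cloud."""

    family: str
    n_points: int | None = None
    radius: float = 0.3
    spacing: float = 0.15
    sigma: float = 0.01
    seed: int = 0
    polyhedron: str = "octahedron"
    edge_midpoints: bool = True
    layers: int = 1
    layer_gap: float = 0.15

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}; choose from {FAMILIES}")
        n = self.n_points if self.n_points is not None else _DEF_N[self.family]
        minimum = 2 if self.family == "chain" else 4
        if n < minimum:
            raise ValueError(f"{self.family} needs at least {minimum} points")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n(self) -> int:
        return self.n_points if self.n_points is not None else _DEF_N[self.family]


def make_shape(spec: ShapeSpec) -> tuple[PointCloud, str]:
    """Generate one cloud; returns (cloud, label) with label per FAMILY_LABELS."""
    n = spec.n
    if spec.family == "ring":
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = spec.radius * np.c_[np.cos(theta), np.sin(theta), np.zeros(n)]
    elif spec.family == "cage_sphere":
        pts = spec.radius * _fibonacci_sphere(n)
    elif spec.family == "bowl":
        hemi = _fibonacci_sphere(2 * n)
        pts = spec.radius * hemi[hemi[:, 2] >= 0][:n]
        if len(pts) < 4:
            raise ValueError("bowl sampling produced too few points")
    elif spec.family == "cage_polyhedron":
        verts = _POLYHEDRA[spec.polyhedron] * spec.radius
        pts = _with_edge_midpoints(verts) if spec.edge_midpoints else verts
    elif spec.family == "grid":
        side = max(2, int(round(n ** 0.5)))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        layer = np.c_[xs.ravel(), ys.ravel(), np.zeros(side * side)] * spec.spacing
        layer -= layer.mean(axis=0)
        pts = np.vstack([layer + [0, 0, k * spec.layer_gap] for k in range(spec.layers)])
        pts -= pts.mean(axis=0)
    elif spec.family == "chain":
        step = min(spec.spacing, 0.9 / (n - 1))  # keep the chain inside the unit box
        pts = np.c_[np.arange(n) * step, np.zeros(n), np.zeros(n)]
        pts -= pts.mean(axis=0)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.sigma, size=pts.shape)
    pts = pts + 0.5  # centre of the unit box
    note = f"synthetic {spec.family} (sigma={spec.sigma}, seed={spec.seed})"
    return PointCloud(pts, scale_note=note), FAMILY_LABELS[spec.family]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]


def _with_edge_midpoints(verts: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(verts))
    edge = d[d > 1e-9].min()
    mids = [
        (verts[i] + verts[j]) / 2
        for i in range(len(verts))
        for j in range(i + 1, len(verts))
        if abs(d[i, j] - edge) < 1e-6 * (1 + edge)
    ]
    return np.vstack([verts, mids])


def noise_archetype_specs() -> dict[str, ShapeSpec]:
    """The three noiseless grid archetypes used for bottleneck denoising."""
    return {
        "single_grid": ShapeSpec("grid", n_points=16, spacing=0.2, sigma=0.0),
        "quadruple_grid": ShapeSpec("grid", n_points=16, spacing=0.2, sigma=0.0,
                                    layers=4, layer_gap=0.2),
        "lattice": ShapeSpec("grid", n_points=25, spacing=0.16, sigma=0.0),
    }


def make_labeled_dataset(
    counts: dict[str, int],
    sigma: float = 0.01,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, list[str], list[str], list[ShapeSpec]]:
    """Fingerprints + labels for a mixed synthetic population.

    Returns (matrix of shape (m, 5000), family labels, coarse labels, specs).
    Reproducible end-to-end from ``seed``; each instance draws its jitter from
    an independent spawned seed.
    """
    families = [f for f, c in counts.items() if c > 0]
    if len(families) < 2:
        raise ValueError("need nonzero counts for at least two shape families")
    cfg = config or PipelineConfig()
    children = np.random.SeedSequence(seed).spawn(sum(counts[f] for f in families))
    rows, fam_labels, coarse_labels, specs = [], [], [], []
    k = 0
    for family in families:
        for _ in range(counts[family]):
            spec = ShapeSpec(family, sigma=sigma,
                             seed=int(children[k].generate_state(1)[0] % (2**31 - 1)))
            k += 1
            try:
                cloud, label = make_shape(spec)
                diag = rips_diagram(cloud, cfg.max_edge_length)
                fp = fingerprint_from_diagram(
                    diag, cfg.landscape_levels, cfg.landscape_grid_points,
                    provenance={"spec": spec.family, "seed": spec.seed},
                )
            except Exception as exc:
                raise RuntimeError(f"fixture generation failed for {spec}") from exc
            rows.append(fp.values)
            fam_labels.append(family)
            coarse_labels.append(label)
            specs.append(spec)
    return np.vstack(rows), fam_labels, coarse_labels, specs


def write_xyz(cloud: PointCloud, path: str | Path, comment: str = "") -> None:
    """Serialize a fixture as XYZ with the dummy element symbol ``X``."""
    lines = [str(len(cloud.points)), comment or cloud.scale_note]
    lines += [f"X {x:.8f} {y:.8f} {z:.8f}" for x, y, z in cloud.points]
    Path(path).write_text("\n".join(lines) + "\n")
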