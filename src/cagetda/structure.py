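"""Molecular structure I/O and clean-up ahead of the topological analysis.

The pipeline operates on a *single isolated molecule*: entries read from CIF
often carry solvent molecules or several copies of the cage in the asymmetric
unit, so the stages here perceive connectivity from covalent radii, keep only
the heaviest bonded component, check that the molecule contains at least one
cycle (fully linear molecules cannot enclose a window or cavity) and finally
emit the bare point cloud the filtration is built on.  No symmetry expansion
or periodic-image handling is performed anywhere.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .elements import KNOWN_ELEMENTS, atomic_mass, covalent_radius

log = logging.getLogger(__name__)

DEFAULT_BOND_TOLERANCE = 0.4  # Å added on top of the covalent-radius sum

#: conventional single-bond valences used by the missing-hydrogen heuristic
_VALENCE = {"C": 4, "N": 3, "O": 2}


class FormatError(ValueError):
    """Raised when a structure file violates its format."""


@dataclass
class MolecularStructure:
    """Atoms + coordinates of one entry, Cartesian (Å) or fractional."""

    identifier: str
    elements: list[str]
    coordinates: np.ndarray  # (n, 3) float
    coordinate_mode: str = "cartesian"  # or "fractional"
    cell: tuple[float, float, float, float, float, float] | None = None
    bonds: set[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("structure must contain at least one atom")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match {n} atoms"
            )
        unknown = sorted(set(self.elements) - KNOWN_ELEMENTS)
        if unknown:
            raise ValueError(f"unknown element symbol(s): {', '.join(unknown)}")
        if self.coordinate_mode not in ("cartesian", "fractional"):
            raise ValueError(f"bad coordinate_mode {self.coordinate_mode!r}")
        if self.coordinate_mode == "fractional" and self.cell is None:
            raise ValueError("fractional coordinates require a cell")
        if self.bonds is not None:
            for i, j in self.bonds:
                if i == j or not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i}, {j}) does not index valid distinct atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def cell_matrix(self) -> np.ndarray:
        """3×3 matrix M with Cartesian = fractional @ M (rows are cell vectors)."""
        if self.cell is None:
            raise ValueError("structure has no cell")
        a, b, c, al, be, ga = self.cell
        al, be, ga = (math.radians(x) for x in (al, be, ga))
        cx = c * math.cos(be)
        cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 1e-9 * c * c:
            raise ValueError("degenerate cell (zero volume)")
        return np.array(
            [
                [a, 0.0, 0.0],
                [b * math.cos(ga), b * math.sin(ga), 0.0],
                [cx, cy, math.sqrt(cz_sq)],
            ]
        )

    def cartesian_coordinates(self) -> np.ndarray:
        if self.coordinate_mode == "cartesian":
            return self.coordinates.copy()
        return self.coordinates @ self.cell_matrix()

    def bond_graph(self) -> nx.Graph:
        if self.bonds is None:
            raise ValueError("bonds have not been perceived; call infer_bonds first")
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g


@dataclass
class PointCloud:
    """Bare coordinates consumed by the Rips filtration."""

    points: np.ndarray
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("points must be a non-empty n×3 array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")

    def to_csv(self, path: str | Path) -> None:
        p = Path(path)
        np.savetxt(p, self.points, delimiter=",", header="x,y,z", comments="")
        p.with_suffix(p.suffix + ".json").write_text(
            json.dumps({"scale_note": self.scale_note}) + "\n"
        )


# ---------------------------------------------------------------------------
# readers


def read_structure(path: str | Path, format: str = "auto") -> MolecularStructure:
    """Read one XYZ or CIF file into a :class:`MolecularStructure`.

    XYZ yields Cartesian mode without a cell; CIF yields fractional mode with
    the cell stored.  All atoms of the file's asymmetric-unit content are
    returned; no symmetry expansion is performed.
    """
    path = Path(path)
    if format == "auto":
        format = "cif" if path.suffix.lower() == ".cif" else "xyz"
    if format == "xyz":
        return _read_xyz(path)
    if format == "cif":
        return _read_cif(path)
    raise ValueError(f"unknown format {format!r}")


def _read_xyz(path: Path) -> MolecularStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (line 1)")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: line 1 is not an atom count") from None
    rows = [ln for ln in lines[2 : 2 + declared]]
    if len(rows) < declared or any(not r.strip() for r in rows):
        raise FormatError(
            f"{path}: declared {declared} atoms but fewer coordinate rows (line {len(lines)})"
        )
    elements, coords = [], []
    for k, row in enumerate(rows):
        parts = row.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom row (line {k + 3})")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise FormatError(f"{path}: non-numeric coordinate (line {k + 3})") from None
        elements.append(parts[0])
        coords.append(xyz)
    return MolecularStructure(
        identifier=path.stem,
        elements=elements,
        coordinates=np.array(coords),
        coordinate_mode="cartesian",
    )


def _read_cif(path: Path) -> MolecularStructure:
    from gemmi import cif  # deferred: only CIF users need gemmi

    try:
        doc = cif.read_file(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with line info
        raise FormatError(f"{path}: {exc}") from None

    def cell_value(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise FormatError(f"{path}: missing {tag}")
        return cif.as_number(raw)

    cell = tuple(
        cell_value(f"_cell_{t}")
        for t in ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma")
    )
    table = block.find(
        "_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    if len(table) == 0:
        table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise FormatError(f"{path}: no _atom_site_fract_{{x,y,z}} loop found")
    elements, coords = [], []
    for row in table:
        sym = row[0].strip("'\"")
        # labels like "C12" or symbols with charge like "Cu2+" -> bare symbol
        sym = "".join(ch for ch in sym if ch.isalpha())
        sym = sym[:2].capitalize() if len(sym) >= 2 and sym[:2].capitalize() in KNOWN_ELEMENTS else sym[:1].upper()
        elements.append(sym)
        coords.append([cif.as_number(row[i]) for i in (1, 2, 3)])
    return MolecularStructure(
        identifier=block.name or path.stem,
        elements=elements,
        coordinates=np.array(coords),
        coordinate_mode="fractional",
        cell=cell,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# clean-up operations


def infer_bonds(s: MolecularStructure, tolerance: float = DEFAULT_BOND_TOLERANCE) -> MolecularStructure:
    """Perceive bonds: i–j bonded iff d(i,j) ≤ r_cov(i) + r_cov(j) + tolerance.

    Distances are Cartesian Å (fractional coordinates are transformed through
    the cell first).  Returns a copy with ``bonds`` set.
    """
    radii = np.array([covalent_radius(e) for e in s.elements])
    xyz = s.cartesian_coordinates()
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return replace(s, bonds={(int(i), int(j)) for i, j in zip(ii, jj)})


def heaviest_component(s: MolecularStructure) -> MolecularStructure:
    """Keep the bonded component with the greatest total atomic mass.

    Ties go to the larger atom count, then to the component containing the
    lowest atom index.  Solvent molecules and duplicate cages are discarded;
    surviving atoms are re-indexed contiguously.
    """
    if s.bonds is None:
        raise ValueError("bonds required; call infer_bonds first")
    if not s.bonds and s.n_atoms > 1:
        log.warning("%s: no bonds on a multi-atom structure; atoms treated as components",
                    s.identifier)
    comps = list(nx.connected_components(s.bond_graph()))

    def key(comp: set[int]) -> tuple[float, int, int]:
        mass = sum(atomic_mass(s.elements[i]) for i in comp)
        return (-mass, -len(comp), min(comp))

    keep = sorted(sorted(comps, key=min), key=key)[0]
    order = sorted(keep)
    remap = {old: new for new, old in enumerate(order)}
    bonds = {
        (min(remap[i], remap[j]), max(remap[i], remap[j]))
        for i, j in s.bonds
        if i in remap and j in remap
    }
    return replace(
        s,
        elements=[s.elements[i] for i in order],
        coordinates=s.coordinates[order],
        bonds=bonds,
    )


def contains_cycle(s: MolecularStructure) -> bool:
    """True iff the bond graph has at least one cycle (edges − atoms + components > 0)."""
    if s.bonds is None:
        raise ValueError("bonds required; call infer_bonds first")
    n_comp = nx.number_connected_components(s.bond_graph())
    return len(s.bonds) - s.n_atoms + n_comp > 0


def flag_missing_hydrogens(s: MolecularStructure) -> list[tuple[int, int]]:
    """Triage heuristic: C/N/O atoms with fewer neighbours than single-bond valence.

    Returns (atom index, deficit) pairs.  Unsaturated/aromatic atoms are
    flagged as false positives by construction — the list is meant for manual
    triage, not automatic correction, and hydrogen addition is deliberately
    not implemented.
    """
    if s.bonds is None:
        raise ValueError("bonds required; call infer_bonds first")
    degree = dict(s.bond_graph().degree())
    flags = []
    for i, el in enumerate(s.elements):
        want = _VALENCE.get(el)
        if want is not None and degree[i] < want:
            flags.append((i, want - degree[i]))
    return flags


def to_point_cloud(s: MolecularStructure, mode: str = "as_stored") -> PointCloud:
    """Emit the coordinates the filtration runs on.

    ``as_stored`` passes coordinates through unchanged (fractional for CIF
    inputs — the scale on which the default max_edge_length of 0.8 was tuned).
    ``normalized_cartesian`` converts to Cartesian Å and rescales uniformly so
    the bounding-box diagonal is 1, making the same default meaningful for
    cell-free inputs.
    """
    if mode == "as_stored":
        if s.coordinate_mode == "fractional":
            s.cell_matrix()  # validates non-degenerate cell
            _warn_if_split_across_cell(s)
        return PointCloud(s.coordinates.copy(),
                          scale_note=f"as_stored ({s.coordinate_mode})")
    if mode == "normalized_cartesian":
        xyz = s.cartesian_coordinates()
        extent = xyz.max(axis=0) - xyz.min(axis=0)
        diag = float(np.linalg.norm(extent))
        if diag <= 0:
            return PointCloud(np.zeros_like(xyz),
                              scale_note="normalized_cartesian (degenerate extent)")
        xyz = (xyz - xyz.min(axis=0)) / diag
        return PointCloud(xyz, scale_note=f"normalized_cartesian (diagonal was {diag:.4g} Å)")
    raise ValueError(f"unknown point-cloud mode {mode!r}")


def _warn_if_split_across_cell(s: MolecularStructure) -> None:
    # A molecule wrapped across the cell boundary has bonded pairs far apart
    # in fractional space; raw fractional distances would then be distorted.
    if not s.bonds:
        return
    for i, j in s.bonds:
        if np.any(np.abs(s.coordinates[i] - s.coordinates[j]) > 0.5):
            log.warning(
                "%s: bonded atoms %d-%d are > 0.5 apart along a fractional axis; "
                "the molecule may be split across the cell boundary", s.identifier, i, j
            )
            return
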