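"""Vietoris–Rips filtrations and persistent homology in dimensions 0–2.

A simplex enters the filtration at its diameter (maximum pairwise distance
among its vertices); simplices are built up to dimension 3, which is exactly
what is needed to resolve the death times of 2-dimensional classes (cavities).
Homology is computed over GF(2).

The pairing is obtained by reducing the *coboundary* matrix of each dimension
with the clearing optimisation — the standard persistent-cohomology route,
which yields the identical persistence pairing to boundary-matrix reduction
but avoids the expensive zero-reductions that dominate Rips complexes.  An
independent classical boundary-matrix implementation lives in
:mod:`cagetda.reference` and is held against this one in the test suite.

Dimension-0 pairs are read off a union-find sweep over the edges (every
vertex is born at 0; an edge that merges two components kills one class).
The single surviving class per connected component is *essential*: its death
is capped at ``max_edge_length`` and flagged, so the cap is reversible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import PointCloud

log = logging.getLogger(__name__)

DEFAULT_MAX_EDGE_LENGTH = 0.8


@dataclass
class Filtration:
    """Rips filtration: per-dimension simplex arrays sorted by (value, lex)."""

    max_edge_length: float
    simplices: dict[int, np.ndarray]  # dim -> (m, dim+1) vertex indices
    values: dict[int, np.ndarray]  # dim -> (m,) filtration values

    def n_simplices(self, dim: int | None = None) -> int:
        if dim is None:
            return sum(len(v) for v in self.values.values())
        return len(self.values.get(dim, ()))


@dataclass
class PersistenceDiagram:
    """Multiset of (dim, birth, death) features; one essential B0 class per component."""

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    essential: np.ndarray
    max_edge_length: float

    def __post_init__(self) -> None:
        self.dims = np.asarray(self.dims, dtype=int)
        self.births = np.asarray(self.births, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.essential = np.asarray(self.essential, dtype=bool)

    def __len__(self) -> int:
        return len(self.dims)

    def in_dim(self, dim: int, include_essential: bool = True) -> np.ndarray:
        """(m, 2) array of (birth, death) for one homology dimension."""
        mask = self.dims == dim
        if not include_essential:
            mask &= ~self.essential
        return np.column_stack([self.births[mask], self.deaths[mask]])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "max_edge_length": self.max_edge_length,
            "features": [
                {"dim": int(k), "birth": float(b), "death": float(d), "essential": bool(e)}
                for k, b, d, e in zip(self.dims, self.births, self.deaths, self.essential)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PersistenceDiagram":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        feats = payload["features"]
        return cls(
            dims=np.array([f["dim"] for f in feats], dtype=int),
            births=np.array([f["birth"] for f in feats]),
            deaths=np.array([f["death"] for f in feats]),
            essential=np.array([f["essential"] for f in feats], dtype=bool),
            max_edge_length=payload["max_edge_length"],
        )

    @classmethod
    def from_features(
        cls, features: list[tuple[int, float, float, bool]], max_edge_length: float
    ) -> "PersistenceDiagram":
        features = sorted(features)
        return cls(
            dims=np.array([f[0] for f in features], dtype=int),
            births=np.array([f[1] for f in features]),
            deaths=np.array([f[2] for f in features]),
            essential=np.array([f[3] for f in features], dtype=bool),
            max_edge_length=max_edge_length,
        )


# ---------------------------------------------------------------------------
# filtration construction


def build_rips_filtration(
    cloud: PointCloud, max_edge_length: float = DEFAULT_MAX_EDGE_LENGTH
) -> Filtration:
    """All simplices of dimension ≤ 3 with diameter ≤ max_edge_length."""
    if max_edge_length <= 0:
        raise ValueError("max_edge_length must be positive")
    pts = cloud.points
    n = len(pts)
    if n == 1:
        return Filtration(
            max_edge_length,
            {0: np.zeros((1, 1), dtype=np.int32)},
            {0: np.zeros(1)},
        )
    dist = squareform(pdist(pts))
    if np.any(pdist(pts) == 0):
        log.info("point cloud contains duplicate points (zero-length edges)")

    simplices: dict[int, np.ndarray] = {0: np.arange(n, dtype=np.int32)[:, None]}
    values: dict[int, np.ndarray] = {0: np.zeros(n)}

    within = dist <= max_edge_length
    ii, jj = np.nonzero(np.triu(within, k=1))
    edges = np.column_stack([ii, jj]).astype(np.int32)
    if len(edges):
        simplices[1], values[1] = _sorted(edges, dist[ii, jj])

    # adjacency bitmasks: triangles/tetrahedra are cliques
    adj = [0] * n
    for i, j in edges:
        adj[i] |= 1 << int(j)
        adj[j] |= 1 << int(i)

    tris = []
    for i, j in edges:
        m = (adj[int(i)] & adj[int(j)]) >> (int(j) + 1)
        k = int(j) + 1
        while m:
            step = (m & -m).bit_length() - 1
            k += step
            tris.append((int(i), int(j), k))
            m >>= step + 1
            k += 1
    if tris:
        t = np.array(tris, dtype=np.int32)
        v = np.maximum(
            dist[t[:, 0], t[:, 1]],
            np.maximum(dist[t[:, 0], t[:, 2]], dist[t[:, 1], t[:, 2]]),
        )
        simplices[2], values[2] = _sorted(t, v)

        tets = []
        for i, j, k in tris:
            m = (adj[i] & adj[j] & adj[k]) >> (k + 1)
            l = k + 1
            while m:
                step = (m & -m).bit_length() - 1
                l += step
                tets.append((i, j, k, l))
                m >>= step + 1
                l += 1
        if tets:
            q = np.array(tets, dtype=np.int32)
            v = dist[q[:, 0], q[:, 1]]
            for a in range(4):
                for b in range(a + 1, 4):
                    v = np.maximum(v, dist[q[:, a], q[:, b]])
            simplices[3], values[3] = _sorted(q, v)

    return Filtration(max_edge_length, simplices, values)


def _sorted(simp: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # order by filtration value, ties broken by lexicographic vertex order
    keys = tuple(simp[:, c] for c in range(simp.shape[1] - 1, -1, -1)) + (vals,)
    order = np.lexsort(keys)
    return simp[order], vals[order]


# ---------------------------------------------------------------------------
# persistence computation


def compute_persistence_diagram(f: Filtration, max_dim: int = 2) -> PersistenceDiagram:
    """Persistence pairing of a Rips filtration (zero-persistence pairs dropped)."""
    if max_dim > 2:
        raise ValueError("homology dimensions above 2 are not supported")
    cap = f.max_edge_length
    features: list[tuple[int, float, float, bool]] = []

    n = f.n_simplices(0)
    edges = f.simplices.get(1, np.empty((0, 2), dtype=np.int32))
    evals = f.values.get(1, np.empty(0))

    # dimension 0: union-find over edges in filtration order
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merging = np.zeros(len(edges), dtype=bool)
    for e in range(len(edges)):
        ra, rb = find(int(edges[e, 0])), find(int(edges[e, 1]))
        if ra != rb:
            parent[ra] = rb
            merging[e] = True
            if evals[e] > 0:
                features.append((0, 0.0, float(evals[e]), False))
    n_components = len({find(v) for v in range(n)})
    features.extend((0, 0.0, cap, True) for _ in range(n_components))

    if max_dim >= 1 and len(edges):
        tris = f.simplices.get(2, np.empty((0, 3), dtype=np.int32))
        tvals = f.values.get(2, np.empty(0))
        cof1 = _cofacet_masks(edges, tris)
        pairs1, zero1 = _reduce_coboundary(cof1, cleared=set(np.nonzero(merging)[0]),
                                           n_rows=len(tris))
        for col, row in pairs1.items():
            b, d = float(evals[col]), float(tvals[row])
            if d > b:
                features.append((1, b, d, False))
        for col in zero1:
            if float(evals[col]) < cap:
                features.append((1, float(evals[col]), cap, True))

        if max_dim >= 2 and len(tris):
            tets = f.simplices.get(3, np.empty((0, 4), dtype=np.int32))
            qvals = f.values.get(3, np.empty(0))
            cof2 = _cofacet_masks(tris, tets)
            pairs2, zero2 = _reduce_coboundary(cof2, cleared=set(pairs1.values()),
                                               n_rows=len(tets))
            for col, row in pairs2.items():
                b, d = float(tvals[col]), float(qvals[row])
                if d > b:
                    features.append((2, b, d, False))
            for col in zero2:
                if float(tvals[col]) < cap:
                    features.append((2, float(tvals[col]), cap, True))

    return PersistenceDiagram.from_features(features, cap)


def _cofacet_masks(faces: np.ndarray, cofaces: np.ndarray) -> list[int]:
    """Bitmask of reversed coface row indices for each face (by sorted position)."""
    pos = {tuple(s): i for i, s in enumerate(map(tuple, faces))}
    masks = [0] * len(faces)
    m = len(cofaces)
    d1 = cofaces.shape[1] if len(cofaces) else 0
    for r, cof in enumerate(map(tuple, cofaces)):
        bit = 1 << (m - 1 - r)  # earliest coface gets the highest bit
        for drop in range(d1):
            face = cof[:drop] + cof[drop + 1 :]
            masks[pos[face]] |= bit
    return masks


def _reduce_coboundary(
    cofacet_masks: list[int], cleared: set[int], n_rows: int
) -> tuple[dict[int, int], list[int]]:
    """Reduce the coboundary matrix, columns in reverse filtration order.

    Returns ({column position: paired coface position}, [unpaired column
    positions]).  Columns in ``cleared`` are deaths found one dimension down
    and are skipped (their reduced columns are zero by the clearing lemma).
    """
    pivot_col: dict[int, int] = {}
    pairs: dict[int, int] = {}
    zeros: list[int] = []
    for col in range(len(cofacet_masks) - 1, -1, -1):
        if col in cleared:
            continue
        bits = cofacet_masks[col]
        while bits:
            piv = bits.bit_length() - 1
            other = pivot_col.get(piv)
            if other is None:
                pivot_col[piv] = bits
                pairs[col] = n_rows - 1 - piv  # back to filtration position
                break
            bits ^= other
        else:
            zeros.append(col)
    return pairs, zeros


def betti_at(f: Filtration, t: float) -> tuple[int, int, int]:
    """Betti numbers (B0, B1, B2) of the subcomplex at filtration value ≤ t.

    Computed directly from GF(2) boundary-matrix ranks of the sublevel
    complex — an independent route from the persistence pairing, suitable for
    cross-checks; cost grows quickly with complex size.
    """
    if not (0 <= t <= f.max_edge_length):
        raise ValueError(f"t={t} outside [0, {f.max_edge_length}]")
    counts, ranks = [], []
    for dim in range(4):
        vals = f.values.get(dim)
        counts.append(0 if vals is None else int(np.sum(vals <= t)))
    for dim in (1, 2, 3):
        if counts[dim] == 0:
            ranks.append(0)
            continue
        faces = f.simplices[dim - 1][: counts[dim - 1]]
        pos = {tuple(s): i for i, s in enumerate(map(tuple, faces))}
        cols = []
        for s in map(tuple, f.simplices[dim][: counts[dim]]):
            bits = 0
            for drop in range(dim + 1):
                bits |= 1 << pos[s[:drop] + s[drop + 1 :]]
            cols.append(bits)
        ranks.append(_gf2_rank(cols))
    b0 = counts[0] - ranks[0]
    b1 = counts[1] - ranks[0] - ranks[1]
    b2 = counts[2] - ranks[1] - ranks[2]
    return b0, b1, b2


def _gf2_rank(cols: list[int]) -> int:
    pivots: dict[int, int] = {}
    rank = 0
    for bits in cols:
        while bits:
            piv = bits.bit_length() - 1
            if piv not in pivots:
                pivots[piv] = bits
                rank += 1
                break
            bits ^= pivots[piv]
    return rank


def rips_diagram(
    cloud: PointCloud, max_edge_length: float = DEFAULT_MAX_EDGE_LENGTH, max_dim: int = 2
) -> PersistenceDiagram:
    """Convenience: filtration + persistence in one call."""
    return compute_persistence_diagram(
        build_rips_filtration(cloud, max_edge_length), max_dim=max_dim
    )
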