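"""Bottleneck distances between diagrams and archetype-based noise removal.

Grid-like coordination compounds (single and quadruple grids, extended
lattices) qualify structurally as cages but are not what a chemist means by
one; they appear in large numbers and degrade the clustering.  They are
removed by comparing each candidate's diagram against a small set of noise
archetypes: a candidate whose similarity to any archetype reaches the
threshold (default 0.95) is dropped before clustering.

Similarity is defined as 1 − d_B/max_edge_length clamped to [0, 1], where
d_B is the larger of the dimension-1 and dimension-2 bottleneck distances —
max_edge_length being the only natural length scale of the pipeline.  At the
defaults (threshold 0.95, max_edge_length 0.8) removal therefore means
d_B ≤ 0.04.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .rips import PersistenceDiagram

log = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.95
#: which homology dimensions enter the combined (max) bottleneck distance
SIMILARITY_DIMS = (1, 2)


def bottleneck_distance(d1: PersistenceDiagram, d2: PersistenceDiagram, dim: int) -> float:
    """Exact bottleneck distance between the dimension-``dim`` sub-diagrams.

    Minimum over perfect matchings (unmatched points projected to their
    nearest diagonal point ((b+d)/2, (b+d)/2)) of the maximum sup-norm
    displacement.  Solved exactly by binary search over the finite set of
    candidate costs with a bipartite-feasibility check at each step.
    """
    if dim not in (0, 1, 2):
        raise ValueError("dim must be 0, 1 or 2")
    return _bottleneck(d1.in_dim(dim), d2.in_dim(dim))


def _bottleneck(p1: np.ndarray, p2: np.ndarray) -> float:
    n1, n2 = len(p1), len(p2)
    if n1 == 0 and n2 == 0:
        return 0.0
    diag1 = (p1[:, 1] - p1[:, 0]) / 2 if n1 else np.empty(0)
    diag2 = (p2[:, 1] - p2[:, 0]) / 2 if n2 else np.empty(0)
    if n1 == 0:
        return float(diag2.max())
    if n2 == 0:
        return float(diag1.max())
    cross = np.maximum(
        np.abs(p1[:, 0][:, None] - p2[:, 0][None, :]),
        np.abs(p1[:, 1][:, None] - p2[:, 1][None, :]),
    )
    candidates = np.unique(np.concatenate([[0.0], cross.ravel(), diag1, diag2]))
    lo, hi = 0, len(candidates) - 1
    if _feasible(candidates[lo], cross, diag1, diag2):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(candidates[mid], cross, diag1, diag2):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def _feasible(c: float, cross: np.ndarray, diag1: np.ndarray, diag2: np.ndarray) -> bool:
    """Perfect matching of cost ≤ c?  Left = P1 ∪ diag copies, right = P2 ∪ diag copies."""
    n1, n2 = len(diag1), len(diag2)
    tol = 1e-12 + 1e-9 * c
    rows, cols = [], []
    ii, jj = np.nonzero(cross <= c + tol)
    rows.extend(ii.tolist())
    cols.extend(jj.tolist())
    for i in np.nonzero(diag1 <= c + tol)[0]:  # P1 point -> its diagonal slot
        rows.append(int(i))
        cols.append(n2 + int(i))
    for j in np.nonzero(diag2 <= c + tol)[0]:  # diagonal slot -> P2 point
        rows.append(n1 + int(j))
        cols.append(int(j))
    for j in range(n2):  # diagonal-to-diagonal always free
        for i in range(n1):
            rows.append(n1 + j)
            cols.append(n2 + i)
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n1 + n2, n1 + n2)
    )
    matching = maximum_bipartite_matching(graph, perm_type="column")
    return int((matching >= 0).sum()) == n1 + n2


def diagram_similarity(
    d1: PersistenceDiagram, d2: PersistenceDiagram, max_edge_length: float | None = None
) -> float:
    """Similarity in [0, 1]: 1 − max(d_B over dims 1, 2)/max_edge_length, clamped."""
    if d1.max_edge_length != d2.max_edge_length:
        raise ValueError(
            f"diagrams were computed at different max_edge_length "
            f"({d1.max_edge_length} vs {d2.max_edge_length})"
        )
    if max_edge_length is None:
        max_edge_length = d1.max_edge_length
    elif max_edge_length != d1.max_edge_length:
        raise ValueError("max_edge_length does not match the diagrams' provenance")
    db = max(bottleneck_distance(d1, d2, dim) for dim in SIMILARITY_DIMS)
    return float(np.clip(1.0 - db / max_edge_length, 0.0, 1.0))


@dataclass
class NoiseExemplarSet:
    """Labelled archetype diagrams plus the removal threshold."""

    exemplars: list[tuple[str, PersistenceDiagram]]
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise ValueError("need at least one noise exemplar")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must lie in (0, 1]")

    @classmethod
    def from_json_files(cls, paths: dict[str, str | Path],
                        threshold: float = DEFAULT_SIMILARITY_THRESHOLD) -> "NoiseExemplarSet":
        return cls(
            [(label, PersistenceDiagram.from_json(Path(p))) for label, p in paths.items()],
            threshold=threshold,
        )


def filter_noise(
    diagrams: dict[str, PersistenceDiagram], exemplars: NoiseExemplarSet
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Split ids into (kept, removed); removed entries carry (id, exemplar, similarity).

    A structure is removed iff its similarity to *any* exemplar reaches the
    threshold; the reported exemplar is the best-matching one.
    """
    if not diagrams:
        log.info("filter_noise called with an empty diagram set")
        return [], []
    kept, removed = [], []
    for sid, diag in diagrams.items():
        best_label, best_sim = None, -1.0
        for label, ex in exemplars.exemplars:
            sim = diagram_similarity(diag, ex)
            if sim > best_sim:
                best_label, best_sim = label, sim
        if best_sim >= exemplars.threshold:
            removed.append((sid, best_label, best_sim))
        else:
            kept.append(sid)
    return kept, removed


def removal_report_csv(removed: list[tuple[str, str, float]], path: str | Path) -> None:
    lines = ["id,exemplar,similarity"]
    lines += [f"{sid},{label},{sim:.6f}" for sid, label, sim in removed]
    Path(path).write_text("\n".join(lines) + "\n")
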