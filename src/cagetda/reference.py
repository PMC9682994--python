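"""Brute-force reference implementations used as validation oracles.

Each function here recomputes a quantity that the main modules obtain by a
faster route, using the most literal textbook algorithm available:

* :func:`rips_diagram_bruteforce` — explicit global boundary matrix over
  GF(2), classic left-to-right column reduction, no clearing, no union-find;
* :func:`bottleneck_bruteforce` — exhaustive enumeration over all partial
  matchings with diagonal projections;
* :func:`ward_bruteforce` — agglomeration that recomputes the Ward variance
  increase of every candidate pair at every step.

They are exponential or cubic and intended for tiny inputs only; the test
suite holds the production code against them.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .rips import PersistenceDiagram


def rips_diagram_bruteforce(points: np.ndarray, max_edge_length: float) -> PersistenceDiagram:
    """Persistence diagram (dims 0–2) by global boundary-matrix reduction."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for dim in range(4):
        for verts in combinations(range(n), dim + 1):
            diam = max((dist[a][b] for a, b in combinations(verts, 2)), default=0.0)
            if diam <= max_edge_length:
                simplices.append((diam, dim, verts))
    simplices.sort()  # value, then dim (faces precede cofaces on ties), then lex
    index = {s[2]: i for i, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for _, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            columns.append({index[verts[:k] + verts[k + 1 :]] for k in range(dim + 1)})

    low_to_col: dict[int, int] = {}
    pair_of: dict[int, int] = {}
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            other = low_to_col.get(low)
            if other is None:
                low_to_col[low] = j
                pair_of[low] = j
                break
            col ^= columns[other]
        columns[j] = col

    features: list[tuple[int, float, float, bool]] = []
    for i, (value, dim, _) in enumerate(simplices):
        if columns[i]:  # i is a death simplex
            continue
        if dim > 2:
            continue
        j = pair_of.get(i)
        if j is None:
            features.append((dim, value, max_edge_length, True))
        else:
            death = simplices[j][0]
            if death > value:
                features.append((dim, value, death, False))
    return PersistenceDiagram.from_features(features, max_edge_length)


def bottleneck_bruteforce(points1: np.ndarray, points2: np.ndarray) -> float:
    """Exact bottleneck distance by enumerating every matching.

    ``points1``/``points2`` are (m, 2) arrays of (birth, death) pairs.
    Unmatched points pay their sup-norm distance to the diagonal, (d − b)/2.
    Exponential: keep each diagram at ≤ ~6 points.
    """
    p1 = np.asarray(points1, dtype=float).reshape(-1, 2)
    p2 = np.asarray(points2, dtype=float).reshape(-1, 2)
    diag1 = (p1[:, 1] - p1[:, 0]) / 2
    diag2 = (p2[:, 1] - p2[:, 0]) / 2
    best = np.inf
    idx2 = range(len(p2))
    for k in range(min(len(p1), len(p2)) + 1):
        for sub1 in combinations(range(len(p1)), k):
            for sub2 in combinations(idx2, k):
                for perm in permutations(sub2):
                    cost = 0.0
                    for a, b in zip(sub1, perm):
                        cost = max(cost, float(np.max(np.abs(p1[a] - p2[b]))))
                    un1 = [i for i in range(len(p1)) if i not in sub1]
                    un2 = [i for i in range(len(p2)) if i not in sub2]
                    if un1:
                        cost = max(cost, float(diag1[un1].max()))
                    if un2:
                        cost = max(cost, float(diag2[un2].max()))
                    best = min(best, cost)
    return 0.0 if best is np.inf else best


def ward_bruteforce(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Ward agglomeration recomputing every pairwise variance increase.

    Returns the merge sequence as (members A, members B, height) with the
    same height convention as SciPy's ward linkage:
    sqrt(2 |A||B| / (|A|+|B|)) · ‖centroid_A − centroid_B‖.
    Ties broken toward the pair containing the lowest member index.
    """
    X = np.asarray(X, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            mu_a, mu_b = X[ca].mean(axis=0), X[cb].mean(axis=0)
            h = np.sqrt(2 * len(ca) * len(cb) / (len(ca) + len(cb))) * np.linalg.norm(mu_a - mu_b)
            key = (h, min(min(ca), min(cb)), min(max(min(ca), min(cb)), 10**9))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), float(best[0][0])))
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
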