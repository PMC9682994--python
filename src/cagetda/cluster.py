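"""Ward hierarchical clustering of fingerprints and purity-based labelling.

The unsupervised route: agglomerate landscape fingerprints under Ward's
minimum-variance linkage, inspect the dendrogram, cut at a chosen cluster
count or height, then turn partial visual ground truth into per-cluster
verdicts with the 60/40 purity rule — a cluster whose labelled members are
more than 60 % cages is called all-cage, one below 40 % all-non-cage, and
anything in between stays unclassified.  Boundary fractions of exactly 40 %
or 60 % are unclassified (the rule's inequalities are strict).

Distances are Euclidean on raw fingerprints; an optional standardization
switch exists but defaults off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    """Ward merge tree: SciPy linkage matrix + leaf structure ids."""

    linkage: np.ndarray  # (n-1, 4): child a, child b, height, merged size
    ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def merges(self) -> list[tuple[int, int, float, int]]:
        """Ordered merge records (cluster id A, cluster id B, distance, size)."""
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"ids": self.ids, "merges": self.merges()}, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths."""

        heights = {i: 0.0 for i in range(self.n_leaves)}

        def node(idx: int, parent_h: float) -> str:
            if idx < self.n_leaves:
                return f"{self.ids[idx]}:{parent_h:.6g}"
            a, b, h, _ = self.linkage[idx - self.n_leaves]
            return f"({node(int(a), h)},{node(int(b), h)}):{parent_h - h:.6g}"

        root = self.n_leaves + len(self.linkage) - 1
        top = float(self.linkage[-1, 2]) if len(self.linkage) else 0.0
        return node(root, top).rsplit(":", 1)[0] + ";"


def ward_dendrogram(
    X: np.ndarray, ids: list[str] | None = None, standardize: bool = False
) -> Dendrogram:
    """Agglomerative Ward clustering of the fingerprint matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
    if len(bad):
        raise ValueError(f"non-finite fingerprint rows: {bad.tolist()}")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if ids is None:
        ids = [str(i) for i in range(len(X))]
    if len(ids) != len(X):
        raise ValueError("ids length does not match matrix rows")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, ids=list(ids))


def cut_clusters(
    d: Dendrogram, k: int | None = None, height: float | None = None
) -> dict[str, int]:
    """Cut the tree into exactly k clusters, or undo all merges above a height.

    Cluster indices are stable: clusters are numbered 0.. in order of their
    smallest member's leaf position.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not (1 <= k <= d.n_leaves):
            raise ValueError(f"k must lie in [1, {d.n_leaves}]")
        raw = hierarchy.cut_tree(d.linkage, n_clusters=k).ravel()
    else:
        if height < 0:
            raise ValueError("height must be non-negative")
        raw = hierarchy.fcluster(d.linkage, t=height, criterion="distance")
    remap: dict[int, int] = {}
    for leaf in range(len(raw)):
        remap.setdefault(int(raw[leaf]), len(remap))
    return {d.ids[leaf]: remap[int(raw[leaf])] for leaf in range(len(raw))}


@dataclass
class ClusterInfo:
    members: list[str]
    n_labelled: int
    cage_fraction: float | None  # None when no labelled members
    verdict: str  # cage / non_cage / unclassified


@dataclass
class ClusterLabeling:
    clusters: dict[int, ClusterInfo]
    report: dict


def label_clusters(
    assignment: dict[str, int],
    truth: dict[str, str],
    full_truth: dict[str, str] | None = None,
    cage_threshold: float = 0.60,
    non_cage_threshold: float = 0.40,
) -> ClusterLabeling:
    """Apply the purity rule to each cluster and account for accuracy.

    ``truth`` is the (possibly partial) visual ground truth used to decide
    verdicts; ``full_truth``, when given, is used for the accuracy report
    (correct members of classified clusters) and the false-negative list
    (true cages inside non_cage-verdict clusters).
    """
    bad = {v for v in truth.values()} - {"cage", "non_cage"}
    if bad:
        raise ValueError(f"truth labels outside cage/non_cage: {sorted(bad)}")
    missing = [sid for sid in truth if sid not in assignment]
    if missing:
        raise ValueError(f"labelled ids absent from the assignment: {missing[:5]}")

    clusters: dict[int, ClusterInfo] = {}
    for cid in sorted(set(assignment.values())):
        members = sorted(sid for sid, c in assignment.items() if c == cid)
        labelled = [sid for sid in members if sid in truth]
        if not labelled:
            clusters[cid] = ClusterInfo(members, 0, None, "unclassified")
            continue
        frac = sum(truth[sid] == "cage" for sid in labelled) / len(labelled)
        if frac > cage_threshold:
            verdict = "cage"
        elif frac < non_cage_threshold:
            verdict = "non_cage"
        else:
            verdict = "unclassified"
        clusters[cid] = ClusterInfo(members, len(labelled), frac, verdict)

    n_cage = sum(len(c.members) for c in clusters.values() if c.verdict == "cage")
    n_non = sum(len(c.members) for c in clusters.values() if c.verdict == "non_cage")
    n_un = sum(len(c.members) for c in clusters.values() if c.verdict == "unclassified")
    report: dict = {
        "n_labelled_cage": n_cage,
        "n_labelled_non_cage": n_non,
        "n_unclassified": n_un,
    }
    if full_truth is not None:
        correct = total = 0
        false_negatives: list[str] = []
        for c in clusters.values():
            if c.verdict == "unclassified":
                continue
            for sid in c.members:
                want = full_truth.get(sid)
                if want is None:
                    continue
                total += 1
                correct += want == c.verdict
                if c.verdict == "non_cage" and want == "cage":
                    false_negatives.append(sid)
        report["accuracy"] = correct / total if total else float("nan")
        report["n_false_negatives"] = len(false_negatives)
        report["false_negatives"] = false_negatives
    return ClusterLabeling(clusters=clusters, report=report)


def assignment_to_csv(assignment: dict[str, int], path: str | Path) -> None:
    lines = ["id,cluster"] + [f"{sid},{cid}" for sid, cid in sorted(assignment.items())]
    Path(path).write_text("\n".join(lines) + "\n")
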