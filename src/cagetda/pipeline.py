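"""End-to-end batch pipeline binding the stages into the two workflows.

For each input structure file: read → (bond perception → heaviest component
→ cyclicity filter) → point cloud → Rips persistence → landscapes →
fingerprint; then either bottleneck denoising + Ward clustering
(unsupervised), random-forest prediction (supervised), or stop after the
fingerprint matrix (fingerprint_only).  Structure-level failures never abort
the batch: they are logged with the structure id and tallied in the run
manifest, which records config, seeds and per-stage counts so a run can be
re-executed identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .distance import NoiseExemplarSet, filter_noise, removal_report_csv
from .landscape import fingerprint_from_diagram, write_fingerprint_matrix
from .rips import PersistenceDiagram, rips_diagram
from .structure import contains_cycle, heaviest_component, infer_bonds, read_structure, to_point_cloud

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    ids: list[str]
    fingerprints: np.ndarray | None
    diagrams: dict[str, PersistenceDiagram]
    manifest: dict


def fingerprint_structures(
    paths: list[str | Path], config: PipelineConfig
) -> PipelineResult:
    """Run read → clean → persistence → fingerprint over a batch of files."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    diagrams: dict[str, PersistenceDiagram] = {}
    counts = {"read": 0, "failed": 0, "dropped_linear": 0, "passed": 0}
    for path in sorted(Path(p) for p in paths):
        sid = path.stem
        counts["read"] += 1
        try:
            s = read_structure(path)
            if config.apply_molecule_cleanup:
                s = infer_bonds(s, config.bond_tolerance)
                s = heaviest_component(s)
                if not contains_cycle(s):
                    counts["dropped_linear"] += 1
                    log.info("%s: fully linear (no cycle); dropped", sid)
                    continue
            cloud = to_point_cloud(s, config.coordinate_mode)
            diag = rips_diagram(cloud, config.max_edge_length)
            fp = fingerprint_from_diagram(
                diag, config.landscape_levels, config.landscape_grid_points,
                provenance={"id": sid},
            )
        except Exception as exc:
            counts["failed"] += 1
            log.error("%s: %s", sid, exc)
            continue
        counts["passed"] += 1
        ids.append(sid)
        rows.append(fp.values)
        diagrams[sid] = diag
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": counts,
    }
    X = np.vstack(rows) if rows else None
    return PipelineResult(ids=ids, fingerprints=X, diagrams=diagrams, manifest=manifest)


def run_pipeline(
    inputs: list[str | Path],
    config: PipelineConfig,
    mode: str = "fingerprint_only",
    out_dir: str | Path = ".",
    exemplars: NoiseExemplarSet | None = None,
    n_clusters: int | None = None,
    model_path: str | Path | None = None,
) -> PipelineResult:
    """Execute one workflow; writes artifacts and a JSON manifest to out_dir."""
    if mode not in ("unsupervised", "supervised", "fingerprint_only"):
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = fingerprint_structures(inputs, config)
    result.manifest["mode"] = mode
    counts = result.manifest["counts"]

    if result.fingerprints is not None:
        write_fingerprint_matrix(
            out / "fingerprints.csv", result.ids, result.fingerprints,
            params={
                "max_edge_length": config.max_edge_length,
                "levels": config.landscape_levels,
                "grid_points": config.landscape_grid_points,
            },
        )

    if mode == "unsupervised" and result.fingerprints is not None:
        ids, X = result.ids, result.fingerprints
        if exemplars is not None:
            kept, removed = filter_noise(result.diagrams, exemplars)
            counts["dropped_noise"] = len(removed)
            removal_report_csv(removed, out / "noise_removed.csv")
            keep_mask = [sid in set(kept) for sid in ids]
            ids = [sid for sid, m in zip(ids, keep_mask) if m]
            X = X[np.array(keep_mask, dtype=bool)]
        else:
            counts["dropped_noise"] = 0
        if len(ids) >= 2:
            from .cluster import assignment_to_csv, cut_clusters, ward_dendrogram

            dendro = ward_dendrogram(X, ids)
            dendro.to_json(out / "dendrogram.json")
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            if n_clusters is not None:
                assignment = cut_clusters(dendro, k=min(n_clusters, len(ids)))
                assignment_to_csv(assignment, out / "clusters.csv")
        counts["classified"] = len(ids)

    if mode == "supervised" and result.fingerprints is not None:
        from .forest import load_model, predict

        if model_path is None:
            raise ValueError("supervised mode requires a trained model path")
        model = load_model(model_path)
        labels, proba = predict(model, result.fingerprints)
        lines = ["id,label,probability_cage"]
        lines += [f"{sid},{lab},{p:.6f}" for sid, lab, p in zip(result.ids, labels, proba)]
        (out / "predictions.csv").write_text("\n".join(lines) + "\n")
        counts["classified"] = int(np.sum(labels == "cage"))

    # stage counts must sum: read = passed + dropped + failed
    assert counts["read"] == counts["passed"] + counts["dropped_linear"] + counts["failed"]
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1) + "\n")
    return result
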