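"""Xe/Kr screening reports: join cage classes with adsorption uptakes.

Selectivity for a 20/80 Xe/Kr bulk mixture is

    s = (x_Xe / x_Kr) / (y_Xe / y_Kr)

with adsorbed-phase fractions x computed from the uptakes
(x_Xe = q_Xe / (q_Xe + q_Kr)) and bulk fractions y (default 0.2/0.8).
Structures split into krypton-selective (s < 1), the 1–10 band that holds
the bulk of materials (closed interval), and xenon-selective (s > 10); the
per-cluster boxplot statistics are computed over the s > 10 structures only,
with Tukey 1.5×IQR outliers listed separately.  Near-zero krypton uptake
inflates the selectivity variance, so q_Kr = 0 is reported as an
infinite-selectivity sentinel with a warning rather than an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BAND_LOW, BAND_HIGH = 1.0, 10.0


@dataclass
class UptakeRecord:
    structure_id: str
    q_xe: float  # mol kg^-1
    q_kr: float  # mol kg^-1
    y_xe: float = 0.2
    y_kr: float = 0.8
    temperature_K: float = 298.0
    pressure_bar: float = 10.0

    def __post_init__(self) -> None:
        if self.q_xe < 0 or self.q_kr < 0:
            raise ValueError("uptakes must be non-negative")
        if not (self.y_xe > 0 and self.y_kr > 0 and
                math.isclose(self.y_xe + self.y_kr, 1.0, abs_tol=1e-9)):
            raise ValueError("bulk molar fractions must be positive and sum to 1")


def xe_kr_selectivity(r: UptakeRecord) -> float:
    """Adsorption selectivity s; inf when q_Kr = 0, requires q_Xe + q_Kr > 0."""
    if r.q_xe + r.q_kr == 0:
        raise ValueError(f"{r.structure_id}: both uptakes are zero; selectivity undefined")
    if r.q_kr == 0:
        log.warning("%s: zero krypton uptake -> infinite selectivity sentinel",
                    r.structure_id)
        return math.inf
    return (r.q_xe / r.q_kr) / (r.y_xe / r.y_kr)


def classify_selectivity(s: float) -> str:
    if s < BAND_LOW:
        return "kr_selective"
    if s <= BAND_HIGH:
        return "band"
    return "xe_selective"


@dataclass
class ScreeningReport:
    per_structure: pd.DataFrame  # id, cluster, s, selectivity_class, q_xe, q_kr
    cluster_stats: pd.DataFrame  # over-10 boxplot statistics per cluster
    top_structures: pd.DataFrame  # ranked by (s, q_xe) descending
    excluded: list[str]  # ids dropped (both uptakes zero)


def build_report(
    records: list[UptakeRecord], clusters: dict[str, int] | None = None
) -> ScreeningReport:
    """Selectivity classes per structure + per-cluster over-10 boxplot stats."""
    ids = [r.structure_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate structure ids: {sorted(dupes)}")
    clusters = clusters or {}
    rows, excluded = [], []
    for r in records:
        if r.q_xe + r.q_kr == 0:
            log.warning("%s: both uptakes zero; record excluded", r.structure_id)
            excluded.append(r.structure_id)
            continue
        s = xe_kr_selectivity(r)
        rows.append({
            "id": r.structure_id,
            "cluster": clusters.get(r.structure_id, "unclustered"),
            "selectivity": s,
            "selectivity_class": classify_selectivity(s),
            "q_xe": r.q_xe,
            "q_kr": r.q_kr,
        })
    per_structure = pd.DataFrame(
        rows, columns=["id", "cluster", "selectivity", "selectivity_class", "q_xe", "q_kr"]
    )

    stats_rows = []
    if len(per_structure):
        over10 = per_structure[per_structure["selectivity"] > BAND_HIGH]
        for cid, grp in over10.groupby("cluster"):
            s = grp["selectivity"].to_numpy(float)
            finite = s[np.isfinite(s)]
            if len(finite) == 0:
                continue
            q1, med, q3 = np.percentile(finite, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = grp.loc[np.isfinite(s) & ((s < lo) | (s > hi)), "id"].tolist()
            outliers += grp.loc[~np.isfinite(s), "id"].tolist()
            stats_rows.append({
                "cluster": cid, "n": len(grp),
                "min": finite.min(), "q1": q1, "median": med, "q3": q3,
                "max": finite.max(), "mean": finite.mean(),
                "outliers": ";".join(outliers),
            })
    cluster_stats = pd.DataFrame(
        stats_rows,
        columns=["cluster", "n", "min", "q1", "median", "q3", "max", "mean", "outliers"],
    )
    top = per_structure.sort_values(
        ["selectivity", "q_xe"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return ScreeningReport(per_structure, cluster_stats, top, excluded)


def read_uptake_csv(path: str | Path) -> list[UptakeRecord]:
    """id,q_xe,q_kr[,y_xe,y_kr,temperature_K,pressure_bar] per row."""
    df = pd.read_csv(path)
    optional = {"y_xe": 0.2, "y_kr": 0.8, "temperature_K": 298.0, "pressure_bar": 10.0}
    records = []
    for _, row in df.iterrows():
        kwargs = {k: float(row[k]) if k in df.columns else v for k, v in optional.items()}
        records.append(UptakeRecord(str(row["id"]), float(row["q_xe"]), float(row["q_kr"]),
                                    **kwargs))
    return records


def write_report(report: ScreeningReport, prefix: str | Path) -> None:
    prefix = Path(prefix)
    report.per_structure.to_csv(prefix.with_suffix(".structures.csv"), index=False)
    report.cluster_stats.to_csv(prefix.with_suffix(".clusters.csv"), index=False)
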