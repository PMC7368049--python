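"""Differential-expression filtering and insulator-occupancy association.

The differential-expression table (edgeR-style: gene_id, logFC, PValue,
log10CPM) is consumed, not produced. Genes pass the filter when P <= 0.05
and expression >= 1 log10 CPM; survivors are grouped by which of the three
insulator proteins (BEAF-32, dCTCF, GAF) occupy their promoters, rolled up
into four display groups (one factor / two factors / all three / none),
and the up- vs down-regulation balance of the groups is compared with
Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .occupancy import OccupancyRecord
from .stats import StatTestResult, fisher_exact_2x2

__all__ = [
    "DEGRecord",
    "OccupancyGroups",
    "filter_deg",
    "group_by_occupancy",
    "group_trends",
]

DEFAULT_FACTORS = ("BEAF-32", "dCTCF", "GAF")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    logFC: float
    p_value: float
    log10_cpm: float

    @property
    def direction(self) -> str:
        return "up" if self.logFC > 0 else "down"


@dataclass
class OccupancyGroups:
    """DEGs partitioned by promoter insulator content.

    ``subsets`` maps each factor subset (frozenset) to its member gene ids;
    ``display`` rolls the subsets up into the four groups used for the
    trend comparison: one / two / three factors and none.
    """

    subsets: dict[frozenset, list[str]] = field(default_factory=dict)

    @property
    def display(self) -> dict[str, list[str]]:
        out = {"one_factor": [], "two_factors": [], "three_factors": [], "none": []}
        key = {0: "none", 1: "one_factor", 2: "two_factors", 3: "three_factors"}
        for sub, members in self.subsets.items():
            out[key[len(sub)]].extend(members)
        return out

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.subsets.values())


def filter_deg(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_expr: float = 1.0,
    bh_fdr: bool = False,
) -> list[DEGRecord]:
    """Keep genes with P <= alpha and log10 CPM >= min_expr.

    P values are used unadjusted by default (matching the source tables);
    ``bh_fdr=True`` applies Benjamini-Hochberg before thresholding instead.
    """
    df = table.rename(
        columns={c: c.lower().replace("value", "_value") for c in table.columns}
    )
    p_col = next(c for c in df.columns if c in ("p_value", "p", "pvalue"))
    cpm_col = next(c for c in df.columns if "cpm" in c)
    fc_col = next(c for c in df.columns if "logfc" in c or c == "logfc")
    p = df[p_col].to_numpy(dtype=float)
    if bh_fdr:
        from scipy.stats import false_discovery_control

        p = false_discovery_control(p, method="bh")
    keep = (p <= alpha) & (df[cpm_col].to_numpy(dtype=float) >= min_expr)
    return [
        DEGRecord(
            gene_id=str(r[0]), logFC=float(r[1]), p_value=float(r[2]),
            log10_cpm=float(r[3]),
        )
        for r in zip(
            df["gene_id"][keep], df[fc_col][keep], df[p_col][keep], df[cpm_col][keep]
        )
    ]


def group_by_occupancy(
    degs: list[DEGRecord],
    occupancy: dict[str, list[OccupancyRecord]],
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> OccupancyGroups:
    """Assign each DEG to exactly one factor subset (a partition).

    DEGs absent from the occupancy table count as unoccupied ("none"): a
    gene with no called promoter peak has no occupancy records.
    """
    groups = OccupancyGroups()
    for k in range(len(factors) + 1):
        for sub in combinations(factors, k):
            groups.subsets[frozenset(sub)] = []
    for deg in degs:
        recs = occupancy.get(deg.gene_id, [])
        present = frozenset(r.factor for r in recs if r.occupied and r.factor in factors)
        groups.subsets[present].append(deg.gene_id)
    return groups


def group_trends(
    groups: OccupancyGroups,
    degs: list[DEGRecord],
) -> tuple[pd.DataFrame, dict[tuple[str, str], StatTestResult]]:
    """Direction-of-change summary per display group + pairwise Fisher tests.

    Each pairwise test is the 2x2 table (up, down) x (group A, group B);
    a significant P says the two groups shift in different directions
    under insulator disruption.
    """
    by_id = {d.gene_id: d for d in degs}
    rows = []
    updown: dict[str, tuple[int, int]] = {}
    for label, members in groups.display.items():
        fcs = [by_id[g].logFC for g in members if g in by_id]
        up = sum(1 for v in fcs if v > 0)
        down = len(fcs) - up
        updown[label] = (up, down)
        rows.append({
            "group": label,
            "n": len(fcs),
            "median_logFC": float(np.median(fcs)) if fcs else float("nan"),
            "up_fraction": up / len(fcs) if fcs else float("nan"),
        })
    tests = {}
    labels = [r["group"] for r in rows if r["n"] > 0]
    for a, b in combinations(labels, 2):
        ua, da = updown[a]
        ub, db = updown[b]
        tests[(a, b)] = fisher_exact_2x2(ua, da, ub, db)
    return pd.DataFrame(rows), tests
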