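"""Per-cluster marker testing, effect-size ranking, and cluster reports.

Each cluster is characterized agnostically of marker identity: every marker
is tested (two-sided Mann-Whitney, cluster members vs all other non-discarded
cells, on preprocessed values), p-values are Benjamini-Hochberg adjusted
within the cluster, and significant markers are ranked by the magnitude of
the standardized mean difference

    d = (mean_in - mean_out) / pooled SD.

Tiers bin |d| at conventional effect-size cut points (default 0.8 / 0.5 /
0.2 -> tiers 1/2/3; significant markers below the last cut get tier 4), so a
"tier 1" marker is a strong, reliable discriminator of the cluster and a
low-tier marker a weak but statistically solid one.  Markers significantly
*depleted* in a cluster (d < 0) characterize cells by absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterResult
from .io import DISCARDED, CellTable, ValidationError
from .shrinkage import PreprocessedMatrix

__all__ = [
    "MarkerRanking",
    "ClusterReport",
    "rank_markers",
    "negative_markers",
    "build_report",
    "effect_size",
]


def effect_size(inside: np.ndarray, outside: np.ndarray) -> float:
    """Pooled-SD standardized mean difference; antisymmetric under swapping."""
    n1, n2 = len(inside), len(outside)
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 observations on each side")
    v1, v2 = inside.var(ddof=1), outside.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((inside.mean() - outside.mean()) / pooled)


@dataclass
class MarkerRanking:
    """Ranked markers for one cluster.

    ``table`` has one row per marker: effect_size, p_value, p_adjusted,
    significant, rank (1..k over significant markers by |effect_size|
    descending, ties alphabetical; <NA> otherwise), tier (1..4 for significant
    markers by |effect_size| thresholds), direction (+1 enriched / -1
    depleted).
    """

    cluster_id: int
    table: pd.DataFrame
    alpha: float
    n_in: int
    n_out: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].sort_values("rank")

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.significant().head(k)


def _as_values(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, PreprocessedMatrix):
        return matrix.values, list(matrix.marker_names)
    X = np.asarray(matrix, float)
    return X, [f"marker_{j}" for j in range(X.shape[1])]


def rank_markers(
    matrix,
    labels: np.ndarray,
    cluster_id: int,
    alpha: float = 0.05,
    tier_thresholds: tuple[float, ...] = (0.8, 0.5, 0.2),
    marker_names: list[str] | None = None,
) -> MarkerRanking:
    """Test and rank every marker for one cluster against all other kept cells.

    DISCARDED cells are excluded from the comparison population.  Returns a
    :class:`MarkerRanking`; markers with BH-adjusted p >= alpha stay unranked.
    """
    X, names = _as_values(matrix)
    if marker_names is not None:
        names = list(marker_names)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels length must equal matrix rows")
    inside = labels == cluster_id
    if not inside.any():
        raise ValidationError(f"cluster {cluster_id} absent from labels")
    outside = (labels != cluster_id) & (labels != DISCARDED)
    if inside.sum() < 2 or outside.sum() < 2:
        raise ValidationError("cluster and complement must each have >= 2 cells")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")

    d = np.empty(X.shape[1])
    p = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[inside, j], X[outside, j]
        d[j] = effect_size(a, b)
        if np.ptp(X[inside | outside, j]) == 0:
            p[j] = 1.0  # constant marker carries no evidence
        else:
            p[j] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    significant = p_adj < alpha

    df = pd.DataFrame(
        {
            "marker": names,
            "effect_size": d,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": significant,
            "direction": np.where(d >= 0, 1, -1),
        }
    )
    df["rank"] = pd.array([pd.NA] * len(df), dtype="Int64")
    sig = df[significant].sort_values(
        ["effect_size", "marker"],
        key=lambda s: -s.abs() if s.name == "effect_size" else s,
    )
    df.loc[sig.index, "rank"] = np.arange(1, len(sig) + 1)

    tiers = pd.array([pd.NA] * len(df), dtype="Int64")
    cuts = tuple(tier_thresholds)
    for i in np.flatnonzero(significant):
        mag = abs(d[i])
        tier = len(cuts) + 1
        for t, cut in enumerate(cuts, start=1):
            if mag >= cut:
                tier = t
                break
        tiers[i] = tier
    df["tier"] = tiers
    return MarkerRanking(
        cluster_id=int(cluster_id),
        table=df,
        alpha=alpha,
        n_in=int(inside.sum()),
        n_out=int(outside.sum()),
    )


def negative_markers(
    matrix,
    labels: np.ndarray,
    cluster_id: int,
    alpha: float = 0.05,
    tier_thresholds: tuple[float, ...] = (0.8, 0.5, 0.2),
    marker_names: list[str] | None = None,
) -> list[str]:
    """Significantly depleted markers (d < 0) for a cluster, strongest first."""
    r = rank_markers(matrix, labels, cluster_id, alpha, tier_thresholds, marker_names)
    neg = r.table[(r.table["significant"]) & (r.table["effect_size"] < 0)]
    return list(neg.sort_values("effect_size")["marker"])


@dataclass
class ClusterReport:
    """Three-part characterization of one cluster.

    A: ranked marker table; B: spatial coordinates of member cells (tissue
    map); C: raw-intensity distribution summary (median, IQR) of each
    diagnostic marker in-cluster vs the whole population.
    """

    cluster_id: int
    ranking: MarkerRanking  # part A
    coordinates: pd.DataFrame  # part B: cell_id, x, y
    diagnostics: pd.DataFrame  # part C


def _median_iqr(v: np.ndarray) -> tuple[float, float]:
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return float(q2), float(q3 - q1)


def build_report(
    table: CellTable,
    matrix,
    result: ClusterResult,
    rankings: list[MarkerRanking],
    diagnostic_markers: list[str] | None = None,
) -> list[ClusterReport]:
    """Assemble per-cluster reports (parts A/B/C) for every non-reserved cluster.

    Part C compares raw (not preprocessed) intensities, as median and IQR,
    between cluster members and the full population.
    """
    diagnostic_markers = list(diagnostic_markers or [])
    for name in diagnostic_markers:
        if name not in table.marker_names:
            raise ValidationError(f"diagnostic marker {name!r} not in panel")
    X, _ = _as_values(matrix)
    if not (table.n_cells == X.shape[0] == result.n_cells):
        raise ValidationError("table, matrix and result disagree on n_cells")
    by_id = {r.cluster_id: r for r in rankings}
    reports = []
    for cid in result.cluster_ids:
        members = result.labels == cid
        coords = pd.DataFrame(
            {
                "cell_id": table.cell_id[members],
                "x": table.x[members],
                "y": table.y[members],
            }
        )
        rows = []
        for name in diagnostic_markers:
            v = table.marker(name)
            med_in, iqr_in = _median_iqr(v[members])
            med_all, iqr_all = _median_iqr(v)
            rows.append(
                {
                    "marker": name,
                    "cluster_median": med_in,
                    "cluster_iqr": iqr_in,
                    "population_median": med_all,
                    "population_iqr": iqr_all,
                }
            )
        diag_cols = [
            "marker",
            "cluster_median",
            "cluster_iqr",
            "population_median",
            "population_iqr",
        ]
        diagnostics = pd.DataFrame(rows, columns=diag_cols)
        if cid not in by_id:
            raise ValidationError(f"no ranking provided for cluster {cid}")
        reports.append(
            ClusterReport(
                cluster_id=int(cid),
                ranking=by_id[cid],
                coordinates=coords,
                diagnostics=diagnostics,
            )
        )
    return reports
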