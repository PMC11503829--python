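"""Data containers and CSV readers/writers for segmented single-cell marker tables.

The pipeline's universal input is a :class:`CellTable`: one row per segmented
cell carrying a unique id, spatial coordinates in pixels (image convention:
origin top-left, x rightward, y downward) and one column of non-negative mean
intensity per marker, as exported by multiplexed-imaging platforms after
nuclear segmentation.  No unit conversion is applied; the analysis is
scale-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "RunConfig",
    "FormatError",
    "ValidationError",
    "read_cell_table",
    "write_results",
    "read_config",
    "write_config",
]

NOISE = -1
"""Reserved label for cells the density clusterer leaves unassigned."""

DISCARDED = -2
"""Reserved label for cells excluded upfront by the statistical discard step."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass
class CellTable:
    """Per-cell marker intensities plus spatial coordinates.

    Parameters
    ----------
    cell_id : array-like
        Unique identifier per cell.
    x, y : array-like of float
        Pixel coordinates, origin top-left.
    markers : ndarray of shape (n_cells, n_markers)
        Non-negative raw mean intensities.
    marker_names : sequence of str
        Ordered, unique channel labels; length equals the marker column count.
    metadata : DataFrame, optional
        Non-marker columns preserved from the source file.
    """

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    markers: np.ndarray
    marker_names: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        self.marker_names = list(self.marker_names)
        if self.markers.ndim != 2:
            raise ValidationError("markers must be a 2-D (n_cells, n_markers) matrix")
        n = self.markers.shape[0]
        if n < 1 or self.markers.shape[1] < 1:
            raise ValidationError("need at least one cell and one marker")
        if len(self.cell_id) != n or len(self.x) != n or len(self.y) != n:
            raise ValidationError("cell_id/x/y length must equal the number of marker rows")
        if len(set(map(str, self.cell_id))) != n:
            dupes = pd.Series(self.cell_id).duplicated()
            raise ValidationError(
                f"duplicate cell_id values, e.g. {self.cell_id[dupes.to_numpy()][0]!r}"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("marker_names must be unique")
        if len(self.marker_names) != self.markers.shape[1]:
            raise ValidationError("marker_names length must equal marker column count")
        if not np.all(np.isfinite(self.markers)):
            raise ValidationError("marker intensities must be finite")
        if np.any(self.markers < 0):
            r, c = np.argwhere(self.markers < 0)[0]
            raise ValidationError(
                f"negative intensity at cell_id={self.cell_id[r]!r}, "
                f"marker={self.marker_names[c]!r}"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    def marker(self, name: str) -> np.ndarray:
        """Return the intensity column for one marker by name."""
        try:
            j = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in panel") from None
        return self.markers[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_id, "x": self.x, "y": self.y})
        for j, name in enumerate(self.marker_names):
            df[name] = self.markers[:, j]
        return df


@dataclass
class RunConfig:
    """Tunable parameters of the full analysis run.

    contraction
        Shrinkage factor λ in (0, 1]; 1 leaves log-values untouched, values
        near 0 collapse each mixture component onto its center.
    max_components
        Largest per-marker mixture size tried during model selection.
    min_cluster_fraction, min_cluster_floor
        The minimum-cluster-size rule max(floor, ceil(fraction * n_cells));
        defaults 5e-5 (i.e. 0.005 %) and 20 cells.
    umap_neighbors, umap_min_dist
        Embedding locality parameters.
    z_max
        Robust-z cutoff for the upfront statistical discard of aberrant cells.
    seed
        Global random seed; per-stage seeds are derived by fixed offsets.
    counterstain
        Optional name of the nuclear counterstain channel (e.g. DAPI); cells
        with non-positive counterstain are discarded.
    diagnostic_markers
        Optional marker subset for part C of the cluster report.
    tier_thresholds
        Strictly decreasing |effect size| cut points mapping to tiers 1, 2, 3
        (significant markers below the last cut get tier 4).
    """

    contraction: float = 0.7
    max_components: int = 5
    pseudocount: float = 1.0
    shrink_target: str = "mean"
    merge_threshold: float = 4.0
    min_cluster_fraction: float = 5e-5
    min_cluster_floor: int = 20
    umap_neighbors: int = 30
    umap_min_dist: float = 0.05
    z_max: float = 5.0
    alpha: float = 0.05
    seed: int = 0
    counterstain: str | None = None
    diagnostic_markers: list[str] = field(default_factory=list)
    tier_thresholds: tuple[float, ...] = (0.8, 0.5, 0.2)

    def __post_init__(self) -> None:
        if not (0 < self.contraction <= 1):
            raise ValidationError("contraction must be in (0, 1]")
        if self.max_components < 1:
            raise ValidationError("max_components must be >= 1")
        if self.min_cluster_floor < 2:
            raise ValidationError("min_cluster_floor must be >= 2")
        if self.min_cluster_fraction < 0:
            raise ValidationError("min_cluster_fraction must be >= 0")
        t = tuple(self.tier_thresholds)
        if any(b >= a for a, b in zip(t, t[1:])):
            raise ValidationError("tier_thresholds must be strictly decreasing")
        if self.shrink_target not in ("mean", "median"):
            raise ValidationError("shrink_target must be 'mean' or 'median'")


def read_cell_table(
    path: str | Path,
    coordinate_columns: tuple[str, str] = ("x", "y"),
    marker_columns: Sequence[str] | str = "auto",
    id_column: str = "cell_id",
) -> CellTable:
    """Read a segmented single-cell CSV into a :class:`CellTable`.

    ``marker_columns="auto"`` selects every numeric column except the id and
    coordinate columns; non-marker metadata columns are preserved on the
    returned table but excluded from the marker matrix.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse {path}: {e}") from e
    required = [id_column, *coordinate_columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} in header")

    if isinstance(marker_columns, str) and marker_columns == "auto":
        candidates = [c for c in df.columns if c not in required]
        marker_cols = [c for c in candidates if pd.api.types.is_numeric_dtype(df[c])]
    else:
        marker_cols = list(marker_columns)
        absent = [c for c in marker_cols if c not in df.columns]
        if absent:
            raise FormatError(f"{path}: declared marker column(s) {absent} not in header")
    if not marker_cols:
        raise FormatError(f"{path}: no marker columns found")

    markers = np.empty((len(df), len(marker_cols)), dtype=float)
    for j, c in enumerate(marker_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"{path}: non-numeric intensity {df[c].iloc[i]!r} at "
                f"cell_id={df[id_column].iloc[i]!r}, marker={c!r}"
            )
        if col.isna().any():
            i = int(np.argmax(col.isna().to_numpy()))
            raise ValidationError(
                f"{path}: missing intensity at cell_id={df[id_column].iloc[i]!r}, marker={c!r}"
            )
        markers[:, j] = col.to_numpy()

    meta_cols = [c for c in df.columns if c not in required and c not in marker_cols]
    metadata = df[meta_cols].copy() if meta_cols else None
    return CellTable(
        cell_id=df[id_column].to_numpy(),
        x=df[coordinate_columns[0]].to_numpy(dtype=float),
        y=df[coordinate_columns[1]].to_numpy(dtype=float),
        markers=markers,
        marker_names=marker_cols,
        metadata=metadata,
    )


def write_results(result, rankings, path: str | Path, table: CellTable | None = None) -> dict:
    """Write per-cell labels/embedding and per-cluster rankings as CSV.

    Produces ``<path>/cells.csv`` (cell_id, x, y, cluster, umap_1, umap_2) and
    ``<path>/markers.csv`` (cluster, marker, effect_size, p_value, p_adjusted,
    rank, tier).  Reading the per-cell file back reproduces the labels exactly.

    Parameters
    ----------
    result : ClusterResult
    rankings : sequence of MarkerRanking
    path : output directory (created if absent)
    table : the CellTable the run consumed; supplies cell ids/coordinates.
    """
    labels = np.asarray(result.labels)
    emb = np.asarray(result.embedding, dtype=float)
    n = len(labels)
    if emb.shape != (n, 2):
        raise ValidationError("embedding must have shape (n_cells, 2)")
    if table is not None and table.n_cells != n:
        raise ValidationError("labels length must equal the table's n_cells")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    cells = pd.DataFrame(
        {
            "cell_id": table.cell_id if table is not None else np.arange(n),
            "x": table.x if table is not None else np.full(n, np.nan),
            "y": table.y if table is not None else np.full(n, np.nan),
            "cluster": labels.astype(int),
            "umap_1": emb[:, 0],
            "umap_2": emb[:, 1],
        }
    )
    cells.to_csv(out / "cells.csv", index=False)

    rows = []
    for r in rankings:
        df = r.table.copy()
        df.insert(0, "cluster", r.cluster_id)
        rows.append(df)
    cols = ["cluster", "marker", "effect_size", "p_value", "p_adjusted", "rank", "tier"]
    markers = pd.concat(rows, ignore_index=True)[cols] if rows else pd.DataFrame(columns=cols)
    markers.to_csv(out / "markers.csv", index=False)
    return {"cells": out / "cells.csv", "markers": out / "markers.csv"}


def write_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as a flat key=value file."""
    lines = []
    for k, v in asdict(config).items():
        if isinstance(v, (list, tuple)):
            v = ",".join(str(x) for x in v)
        lines.append(f"{k} = {v if v is not None else ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    """Read a flat key=value config file into a RunConfig."""
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: expected 'key = value', got {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        if k not in RunConfig.__dataclass_fields__:
            raise FormatError(f"{path}: unknown config key {k!r}")
        kwargs[k] = v
    defaults = RunConfig()
    typed: dict = {}
    for k, v in kwargs.items():
        if k == "diagnostic_markers":
            typed[k] = [s for s in v.split(",") if s]
        elif k == "tier_thresholds":
            typed[k] = tuple(float(s) for s in v.split(",") if s)
        elif k == "counterstain":
            typed[k] = v or None
        elif k == "shrink_target":
            typed[k] = v
        else:
            cur = getattr(defaults, k)
            typed[k] = type(cur)(float(v)) if isinstance(cur, (int, float)) else v
    return RunConfig(**typed)
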