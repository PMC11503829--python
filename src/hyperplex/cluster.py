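"""Embedding and density clustering of preprocessed marker matrices.

The standardized, shrunk markers are combined into a 2-D latent space by UMAP
and clustered there by HDBSCAN.  Two reserved labels exist alongside the
contiguous cluster ids: ``NOISE`` (-1) for cells the density clusterer leaves
unassigned, and ``DISCARDED`` (-2) for cells excluded upfront on a statistical
basis (aberrant total intensity, or non-positive counterstain).

The minimum cluster size follows the rule max(floor, ceil(fraction * n)) with
defaults floor = 20 cells and fraction = 0.005 % = 5e-5, so the floor
dominates until runs approach half a million cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, isinf

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from .io import DISCARDED, NOISE, ValidationError
from .shrinkage import PreprocessedMatrix

__all__ = [
    "ClusterResult",
    "RobustOutlierFilter",
    "UmapHdbscan",
    "min_cluster_size",
    "discard_outliers",
    "embed",
    "cluster",
]


def min_cluster_size(n_cells: int, fraction: float = 5e-5, floor: int = 20) -> int:
    """Smallest admissible cluster: max(floor, ceil(fraction * n_cells))."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if fraction < 0 or floor < 2:
        raise ValidationError("fraction must be >= 0 and floor >= 2")
    return max(int(floor), ceil(fraction * n_cells))


@dataclass
class ClusterResult:
    """Per-cell labels (NOISE = -1, DISCARDED = -2, clusters 0..k-1) + 2-D embedding."""

    labels: np.ndarray
    embedding: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.shape != (len(self.labels), 2):
            raise ValidationError("embedding must have shape (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= 0]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def counts(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_discarded": int(np.sum(self.labels == DISCARDED)),
            "n_noise": int(np.sum(self.labels == NOISE)),
            "n_clustered": int(np.sum(self.labels >= 0)),
        }


class RobustOutlierFilter(BaseEstimator):
    """Upfront statistical discard of aberrant cells.

    A cell is flagged when the robust z-score of its total standardized
    intensity — (t - median) / (1.4826 * MAD) — exceeds ``z_max`` in absolute
    value.  Median/MAD centering keeps the rule insensitive to the outliers it
    is meant to catch.  ``z_max=inf`` disables the filter.

    ``predict`` follows the sklearn outlier convention: +1 inlier, -1 outlier.
    """

    def __init__(self, z_max: float = 5.0):
        self.z_max = z_max

    def fit(self, X, y=None):
        if not (self.z_max > 0):
            raise ValidationError("z_max must be > 0")
        X = np.asarray(X, float)
        if not np.all(np.isfinite(X)):
            raise ValidationError("matrix must be finite")
        total = X.sum(axis=1)
        self.median_ = float(np.median(total))
        self.mad_ = float(np.median(np.abs(total - self.median_)))
        self.scale_ = 1.4826 * self.mad_
        return self

    def score_samples(self, X) -> np.ndarray:
        """Robust z-scores of total intensity (unsigned magnitude)."""
        total = np.asarray(X, float).sum(axis=1)
        if self.scale_ == 0:
            return np.zeros(len(total))
        return np.abs(total - self.median_) / self.scale_

    def predict(self, X) -> np.ndarray:
        if isinf(self.z_max):
            return np.ones(len(np.asarray(X)), dtype=int)
        z = self.score_samples(X)
        return np.where(z > self.z_max, -1, 1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


def discard_outliers(
    matrix: PreprocessedMatrix | np.ndarray,
    z_max: float = 5.0,
    counterstain: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean keep-mask over cells; False marks cells to DISCARD.

    Cells whose robust z of total standardized intensity exceeds ``z_max``
    are dropped, as are cells with non-positive raw counterstain intensity
    when a counterstain column is supplied.
    """
    X = matrix.values if isinstance(matrix, PreprocessedMatrix) else np.asarray(matrix, float)
    keep = RobustOutlierFilter(z_max=z_max).fit_predict(X) == 1
    if counterstain is not None:
        keep &= np.asarray(counterstain, float) > 0
    return keep


def embed(
    matrix: PreprocessedMatrix | np.ndarray,
    n_neighbors: int = 30,
    min_dist: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding; deterministic for fixed input and seed."""
    import umap  # deferred: numba compilation is slow at import

    X = matrix.values if isinstance(matrix, PreprocessedMatrix) else np.asarray(matrix, float)
    if X.shape[0] <= n_neighbors:
        raise ValidationError(f"n_cells={X.shape[0]} must exceed n_neighbors={n_neighbors}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("matrix must be finite")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    emb = reducer.fit_transform(X)
    return np.asarray(emb, dtype=float)


def cluster(
    embedding: np.ndarray, min_cluster_size: int, allow_single_cluster: bool = False
) -> np.ndarray:
    """HDBSCAN on the embedding; labels relabeled 0..k-1 by decreasing size.

    Unassigned points get ``NOISE`` (-1).  Every returned cluster has at
    least ``min_cluster_size`` members.  With the default
    ``allow_single_cluster=False`` the root of the density hierarchy is never
    returned as a cluster (diffuse uniform data comes back all noise); set it
    to True for degenerate single-population inputs.
    """
    emb = np.asarray(embedding, float)
    if not np.all(np.isfinite(emb)):
        raise ValidationError("embedding must be finite")
    if min_cluster_size > len(emb):
        raise ValidationError("min_cluster_size exceeds the number of cells")
    raw = HDBSCAN(
        min_cluster_size=int(min_cluster_size),
        allow_single_cluster=allow_single_cluster,
        copy=True,
    ).fit_predict(emb)
    labels = np.full(len(raw), NOISE, dtype=int)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    # deterministic relabeling: largest cluster first, old id breaks ties
    order = ids[np.lexsort((ids, -counts))]
    for new, old in enumerate(order):
        labels[raw == old] = new
    return labels


class UmapHdbscan(ClusterMixin, BaseEstimator):
    """UMAP embedding followed by HDBSCAN density clustering.

    Parameters mirror the run configuration: ``n_neighbors``/``min_dist`` for
    the embedding, ``min_cluster_fraction``/``min_cluster_floor`` for the
    minimum-cluster-size rule, ``random_state`` for the embedding seed.

    Attributes (after fit): ``embedding_`` (n, 2), ``labels_`` with NOISE=-1,
    ``min_cluster_size_``.
    """

    def __init__(
        self,
        n_neighbors: int = 30,
        min_dist: float = 0.05,
        min_cluster_fraction: float = 5e-5,
        min_cluster_floor: int = 20,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.min_cluster_fraction = min_cluster_fraction
        self.min_cluster_floor = min_cluster_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.min_cluster_size_ = min_cluster_size(
            X.shape[0], self.min_cluster_fraction, self.min_cluster_floor
        )
        self.embedding_ = embed(
            X, n_neighbors=self.n_neighbors, min_dist=self.min_dist, seed=self.random_state
        )
        self.labels_ = cluster(self.embedding_, self.min_cluster_size_)
        return self
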