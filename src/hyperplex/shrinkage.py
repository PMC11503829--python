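"""Lognormal-shrinkage preprocessing.

Hyperplexed marker intensities are continuous and weakly separated: optical
crossbleed between neighboring cells smears what would be on/off expression
into overlapping lognormal modes.  This module implements the remedy used by
marker-agnostic phenotyping pipelines: for each marker, fit a Gaussian
mixture to the log-transformed intensities, hard-assign every cell to its
most probable component, and contract it toward the component center,

    x' = c_k + lambda * (x - c_k),      lambda in (0, 1],

which sharpens the modes ("enhances fragmentation") before the markers are
z-standardized and combined in the embedding.  Within a component the map is
affine, so pairwise distances scale exactly by lambda and the ordering of
values is preserved.

The number of components per marker is selected by BIC (K = 1..max_components,
ties broken toward the smaller K).  Intensities are logged as log(v + eps)
with eps = 1 by default, since segmented mean intensities include zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .io import CellTable, RunConfig, ValidationError

__all__ = [
    "MarkerMixture",
    "PreprocessedMatrix",
    "DegenerateInputError",
    "LognormalShrinkage",
    "fit_mixture",
    "merge_unseparated",
    "shrink",
    "preprocess",
]


class DegenerateInputError(ValueError):
    """Raised when a marker carries no usable signal (e.g. constant column)."""


@dataclass
class MarkerMixture:
    """A per-marker Gaussian mixture on the log scale, components sorted by center."""

    weights: np.ndarray
    centers: np.ndarray  # component means, log scale, ascending
    sds: np.ndarray
    shrink_centers: np.ndarray  # contraction targets (mean or component median)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.centers = np.asarray(self.centers, float)
        self.sds = np.asarray(self.sds, float)
        self.shrink_centers = np.asarray(self.shrink_centers, float)
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1) > 1e-8:
            raise ValidationError("mixture weights must be positive and sum to 1")
        if np.any(self.sds <= 0) or not np.all(np.isfinite(self.centers)):
            raise ValidationError("mixture SDs must be > 0 and centers finite")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for log-scale values x."""
        x = np.asarray(x, float)[:, None]
        log_dens = (
            -0.5 * ((x - self.centers) / self.sds) ** 2
            - np.log(self.sds)
            + np.log(self.weights)
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        return dens / dens.sum(axis=1, keepdims=True)

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Hard component assignment (argmax posterior responsibility)."""
        return np.argmax(self.responsibilities(x), axis=1)

    def to_dict(self) -> dict:
        return {k: v.tolist() for k, v in asdict(self).items()}


def fit_mixture(
    values: np.ndarray,
    max_components: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> MarkerMixture:
    """Fit a Gaussian mixture to log(values + pseudocount) for one marker.

    K is chosen by BIC over 1..max_components; ties favor the smaller K.
    Components are returned sorted by center.  Raises
    :class:`DegenerateInputError` for constant input.
    """
    return _fit_mixture_log(
        np.log(np.asarray(values, float) + pseudocount), max_components, seed
    )


def merge_unseparated(mix: MarkerMixture, threshold: float = 4.0) -> MarkerMixture:
    """Merge adjacent components that do not form distinct modes.

    BIC happily spends extra Gaussians on a smooth, skewed density; contracting
    such overlapping components apart would cut a continuous population at
    arbitrary boundaries.  Adjacent components (sorted by center) are merged,
    moment-matched, while their center gap is below ``threshold`` pooled
    within-component SDs — well above the ~2-SD gap at which an equal mixture
    of two Gaussians first becomes bimodal, so only clearly separated modes
    are kept as shrinkage targets.  ``threshold=0`` disables merging.
    """
    if threshold <= 0 or mix.n_components == 1:
        return mix
    w = list(mix.weights)
    c = list(mix.centers)
    v = list(mix.sds**2)
    merged = True
    while merged and len(w) > 1:
        merged = False
        for i in range(len(w) - 1):
            pooled = np.sqrt((w[i] * v[i] + w[i + 1] * v[i + 1]) / (w[i] + w[i + 1]))
            if c[i + 1] - c[i] < threshold * pooled:
                wt = w[i] + w[i + 1]
                cm = (w[i] * c[i] + w[i + 1] * c[i + 1]) / wt
                vm = (
                    w[i] * (v[i] + c[i] ** 2) + w[i + 1] * (v[i + 1] + c[i + 1] ** 2)
                ) / wt - cm**2
                w[i : i + 2] = [wt]
                c[i : i + 2] = [cm]
                v[i : i + 2] = [vm]
                merged = True
                break
    centers = np.array(c)
    return MarkerMixture(
        weights=np.array(w) / np.sum(w),
        centers=centers,
        sds=np.sqrt(v),
        shrink_centers=centers.copy(),
    )


def _fit_mixture_log(logv: np.ndarray, max_components: int, seed: int) -> MarkerMixture:
    logv = np.asarray(logv, float)
    logv = logv[np.isfinite(logv)]
    if len(logv) < 10:
        raise ValidationError("need at least 10 finite values to fit a mixture")
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    if np.ptp(logv) == 0:
        raise DegenerateInputError("constant marker: no mixture to fit")

    X = logv[:, None]
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=2, reg_covar=1e-6)
        try:
            gm.fit(X)
        except ValueError:
            continue
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:  # strict improvement; ties keep smaller K
            best_bic = bic
            best = gm
    if best is None:
        raise DegenerateInputError("mixture fit failed for all component counts")
    order = np.argsort(best.means_.ravel())
    centers = best.means_.ravel()[order]
    return MarkerMixture(
        weights=best.weights_[order],
        centers=centers,
        sds=np.sqrt(best.covariances_.ravel()[order]),
        shrink_centers=centers.copy(),
    )


def shrink(values: np.ndarray, fit: MarkerMixture, contraction: float) -> np.ndarray:
    """Contract log-scale values toward their component centers.

    Each value is hard-assigned to the component with the largest posterior
    responsibility and mapped to ``c + contraction * (x - c)``.  With
    contraction=1 this is the identity; as contraction -> 0 every value
    collapses onto its component center.
    """
    if not (0 < contraction <= 1):
        raise ValidationError("contraction must be in (0, 1]")
    x = np.asarray(values, float)
    k = fit.assign(x)
    c = fit.shrink_centers[k]
    return c + contraction * (x - c)


@dataclass
class PreprocessedMatrix:
    """Shrunk, standardized marker matrix plus the model that produced it."""

    values: np.ndarray  # (n_cells, n_markers), each non-constant column ~ N(0, 1)
    marker_names: list[str]
    model: "LognormalShrinkage"
    mean_: np.ndarray  # per-marker standardization mean (post-shrink, log scale)
    sd_: np.ndarray
    constant_mask: np.ndarray  # markers excluded from shrinkage, carried as zeros

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


class LognormalShrinkage(TransformerMixin, BaseEstimator):
    """Per-marker lognormal-mixture shrinkage + standardization transformer.

    Parameters
    ----------
    contraction : float in (0, 1], default 0.7
        Shrinkage factor lambda applied within each mixture component.
    max_components : int, default 5
        Largest per-marker mixture size tried; K selected by BIC.
    pseudocount : float, default 1.0
        eps added before the log transform (intensities include zeros).
    target : {"mean", "median"}, default "mean"
        Contraction target: the fitted component mean, or the empirical
        median of the training points assigned to the component.
    merge_threshold : float, default 3.0
        Components closer than this many pooled SDs are merged before
        shrinking (no distinct mode to contract toward); 0 disables.
    random_state : int, default 0

    Attributes
    ----------
    mixtures_ : list of MarkerMixture or None
        Per-marker fit; None for constant (flagged) markers.
    constant_mask_ : ndarray of bool
    mean_, sd_ : ndarray
        Standardization statistics of the shrunk training data.
    """

    def __init__(
        self,
        contraction: float = 0.7,
        max_components: int = 5,
        pseudocount: float = 1.0,
        target: str = "mean",
        merge_threshold: float = 4.0,
        random_state: int = 0,
    ):
        self.contraction = contraction
        self.max_components = max_components
        self.pseudocount = pseudocount
        self.target = target
        self.merge_threshold = merge_threshold
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_cells, n_markers)")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValidationError("intensities must be finite and non-negative")
        if not (0 < self.contraction <= 1):
            raise ValidationError("contraction must be in (0, 1]")
        if self.target not in ("mean", "median"):
            raise ValidationError("target must be 'mean' or 'median'")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        logX = np.log(X + self.pseudocount)
        n, m = X.shape
        self.mixtures_: list[MarkerMixture | None] = []
        self.constant_mask_ = np.zeros(m, dtype=bool)
        shrunk = np.empty_like(logX)
        for j in range(m):
            col = logX[:, j]
            try:
                mix = _fit_mixture_log(col, self.max_components, self.random_state)
                mix = merge_unseparated(mix, self.merge_threshold)
            except DegenerateInputError:
                self.mixtures_.append(None)
                self.constant_mask_[j] = True
                shrunk[:, j] = 0.0
                continue
            if self.target == "median":
                k = mix.assign(col)
                med = mix.centers.copy()
                for comp in range(mix.n_components):
                    sel = k == comp
                    if sel.any():
                        med[comp] = np.median(col[sel])
                mix.shrink_centers = med
            self.mixtures_.append(mix)
            shrunk[:, j] = shrink(col, mix, self.contraction)
        self.mean_ = shrunk.mean(axis=0)
        sd = shrunk.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        self.mean_[self.constant_mask_] = 0.0
        self.sd_[self.constant_mask_] = 1.0
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mixtures_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} markers, model was fitted with {self.n_features_in_}"
            )
        logX = np.log(X + self.pseudocount)
        out = np.empty_like(logX)
        for j, mix in enumerate(self.mixtures_):
            if mix is None:
                out[:, j] = 0.0
            else:
                out[:, j] = (shrink(logX[:, j], mix, self.contraction) - self.mean_[j]) / self.sd_[j]
        return out

    def to_dict(self) -> dict:
        """JSON-serializable model summary for run provenance."""
        check_is_fitted(self, "mixtures_")
        return {
            "contraction": self.contraction,
            "pseudocount": self.pseudocount,
            "target": self.target,
            "markers": [m.to_dict() if m is not None else None for m in self.mixtures_],
            "standardize_mean": self.mean_.tolist(),
            "standardize_sd": self.sd_.tolist(),
        }


def preprocess(table: CellTable, config: RunConfig | None = None) -> PreprocessedMatrix:
    """Full preprocessing of a cell table: mixture fit, shrinkage, standardization.

    Constant markers are flagged and carried as all-zero columns.
    Deterministic for a fixed config seed.
    """
    config = config or RunConfig()
    model = LognormalShrinkage(
        contraction=config.contraction,
        max_components=config.max_components,
        pseudocount=config.pseudocount,
        target=config.shrink_target,
        merge_threshold=config.merge_threshold,
        random_state=config.seed,
    )
    values = model.fit_transform(table.markers)
    return PreprocessedMatrix(
        values=values,
        marker_names=list(table.marker_names),
        model=model,
        mean_=model.mean_,
        sd_=model.sd_,
        constant_mask=model.constant_mask_,
    )
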