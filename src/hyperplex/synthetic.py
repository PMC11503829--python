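"""Synthetic CODEX-style single-cell tables and quantization test images.

The cell-table generator emulates the statistical structure the downstream
analysis assumes about hyperplexed spatial proteomics:

* per-cell-type marker intensities are lognormal — each type t has a
  log-mean mu[t, m] and log-SD sigma[t, m] per marker m, so log-intensities
  are Gaussian within a type;
* *crossbleed*: a fraction beta of each cell's observed signal is replaced by
  the mean own-signal of its k nearest spatial neighbors, reproducing the
  optical contamination that makes marker distributions continuous rather
  than dichotomous;
* additive half-normal background noise keeps intensities non-negative;
* an optional rare population expresses one designated marker at very low
  signal-to-noise (overlapping supports), distinguishable from the rest only
  by its joint profile.

Everything is deterministic given (spec, seed).  The image generator produces
the 8-bit test images used by the quantization utilities: a full gray ramp, a
posterization panel, and a faint-dendrite scene with pixel-level ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .io import CellTable, ValidationError

__all__ = [
    "CellType",
    "PanelSpec",
    "SyntheticTruth",
    "generate_cells",
    "generate_lowsnr_scenario",
    "generate_test_images",
    "well_separated_panel",
    "codex_like_panel",
]


@dataclass
class CellType:
    """One generative cell population: name, prevalence and lognormal program."""

    name: str
    prevalence: float
    log_means: np.ndarray  # per-marker mu on the log scale
    log_sds: np.ndarray  # per-marker sigma (> 0)


@dataclass
class PanelSpec:
    """Generative description of a marker panel and tissue field.

    Defaults emulate a ~28-antibody panel plus a nuclear counterstain.
    ``crossbleed`` is the mixing weight beta in [0, 1); ``k_neighbors`` the
    number of spatial neighbors contributing contamination (6 approximates the
    contact number of a planar cell packing).  ``background_sd`` is the scale
    of the additive half-normal background on the raw intensity scale.
    """

    marker_names: list[str]
    cell_types: list[CellType]
    n_cells: int = 5000
    field_size: tuple[float, float] = (1000.0, 1000.0)
    crossbleed: float = 0.1
    background_sd: float = 0.05
    k_neighbors: int = 6
    lowsnr_marker: int | None = None
    lowsnr_type: int | None = None
    counterstain: str | None = None

    def __post_init__(self) -> None:
        m = len(self.marker_names)
        if m < 1:
            raise ValidationError("need at least one marker")
        prev = np.array([t.prevalence for t in self.cell_types], dtype=float)
        if len(prev) < 1 or np.any(prev <= 0):
            raise ValidationError("prevalences must be positive")
        if abs(prev.sum() - 1.0) > 1e-8:
            raise ValidationError(f"prevalences must sum to 1, got {prev.sum():.6f}")
        if not (0 <= self.crossbleed < 1):
            raise ValidationError("crossbleed must be in [0, 1)")
        if self.background_sd < 0:
            raise ValidationError("background_sd must be >= 0")
        for t in self.cell_types:
            t.log_means = np.asarray(t.log_means, dtype=float)
            t.log_sds = np.asarray(t.log_sds, dtype=float)
            if t.log_means.shape != (m,) or t.log_sds.shape != (m,):
                raise ValidationError(
                    f"cell type {t.name!r}: program length must equal n_markers={m}"
                )
            if np.any(t.log_sds <= 0):
                raise ValidationError(f"cell type {t.name!r}: log_sds must be > 0")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated table: per-cell type labels and provenance."""

    type_labels: np.ndarray  # integer index into spec.cell_types
    type_names: list[str]
    spec: PanelSpec
    seed: int

    def label_of(self, name: str) -> int:
        return self.type_names.index(name)


def _exact_counts(prevalences: np.ndarray, n: int, pin: dict[int, int] | None = None) -> np.ndarray:
    """Largest-remainder apportionment of n cells to types; pinned counts exact."""
    pin = pin or {}
    counts = np.zeros(len(prevalences), dtype=int)
    for i, c in pin.items():
        counts[i] = c
    free = [i for i in range(len(prevalences)) if i not in pin]
    n_free = n - counts.sum()
    p = prevalences[free] / prevalences[free].sum()
    raw = p * n_free
    base = np.floor(raw).astype(int)
    rem = n_free - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    counts[free] = base
    return counts


def generate_cells(
    spec: PanelSpec, seed: int, exact_counts: bool = False
) -> tuple[CellTable, SyntheticTruth]:
    """Sample a synthetic cell table from a panel specification.

    Positions are uniform in the field.  Each cell's own signal for marker m
    is lognormal(mu[t, m], sigma[t, m]); the observed value is

        (1 - beta) * own + beta * mean(own of k nearest neighbors) + |N(0, background_sd)|

    Crossbleed mixes the neighbors' pre-noise own signal (one-pass model).
    Deterministic for fixed (spec, seed).  With ``exact_counts`` the per-type
    cell counts follow largest-remainder apportionment of the prevalences
    instead of multinomial sampling.
    """
    n, m = spec.n_cells, spec.n_markers
    k_types = len(spec.cell_types)
    if n < k_types:
        raise ValidationError(f"n_cells={n} smaller than number of cell types={k_types}")
    rng = np.random.default_rng(seed)

    prev = np.array([t.prevalence for t in spec.cell_types])
    if exact_counts:
        counts = _exact_counts(prev, n)
        labels = np.repeat(np.arange(k_types), counts)
        rng.shuffle(labels)
    else:
        labels = rng.choice(k_types, size=n, p=prev)

    w, h = spec.field_size
    x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)

    mus = np.stack([t.log_means for t in spec.cell_types])[labels]  # (n, m)
    sds = np.stack([t.log_sds for t in spec.cell_types])[labels]
    own = np.exp(rng.normal(mus, sds))

    beta = spec.crossbleed
    if beta > 0 and n > 1:
        k = min(spec.k_neighbors, n - 1)
        tree = cKDTree(np.column_stack([x, y]))
        _, idx = tree.query(np.column_stack([x, y]), k=k + 1)
        neigh = idx[:, 1:]  # drop self
        observed = (1 - beta) * own + beta * own[neigh].mean(axis=1)
    else:
        observed = own.copy()
    if spec.background_sd > 0:
        observed = observed + np.abs(rng.normal(0.0, spec.background_sd, size=(n, m)))

    table = CellTable(
        cell_id=np.arange(n),
        x=x,
        y=y,
        markers=observed,
        marker_names=list(spec.marker_names),
    )
    truth = SyntheticTruth(
        type_labels=labels,
        type_names=[t.name for t in spec.cell_types],
        spec=spec,
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Preset panels
# ---------------------------------------------------------------------------

def well_separated_panel(
    n_cells: int = 5000,
    n_markers: int = 20,
    prevalences: tuple[float, ...] = (0.4, 0.3, 0.15, 0.1, 0.05),
    mu_on: float = 2.0,
    sigma: float = 0.4,
    crossbleed: float = 0.05,
    background_sd: float = 0.05,
) -> PanelSpec:
    """Panel of well-separated types: each type expresses an exclusive marker block.

    With the defaults, on/off log-means differ by 5 sigma, comfortably above
    the 2-sigma separation needed for clean recovery benchmarks.
    """
    k = len(prevalences)
    if n_markers < k:
        raise ValidationError("need at least one marker per type")
    names = [f"M{i:02d}" for i in range(n_markers)]
    block = n_markers // k
    types = []
    for t, p in enumerate(prevalences):
        mu = np.zeros(n_markers)
        lo = t * block
        hi = n_markers if t == k - 1 else (t + 1) * block
        mu[lo:hi] = mu_on
        types.append(CellType(f"type_{t}", p, mu, np.full(n_markers, sigma)))
    return PanelSpec(
        marker_names=names,
        cell_types=types,
        n_cells=n_cells,
        crossbleed=crossbleed,
        background_sd=background_sd,
    )


def codex_like_panel(n_cells: int = 5000, crossbleed: float = 0.1) -> PanelSpec:
    """A 28-marker + counterstain panel with 8 populations of mixed abundance.

    Marker programs are fixed (seeded construction) so the panel is a stable
    reference scenario rather than a new draw per call.
    """
    n_markers = 29
    names = [f"Ab{i:02d}" for i in range(28)] + ["DAPI"]
    prevalences = (0.30, 0.20, 0.15, 0.10, 0.08, 0.07, 0.06, 0.04)
    rng = np.random.default_rng(20230428)  # panel identity, not a per-run seed
    types = []
    for t, p in enumerate(prevalences):
        mu = np.zeros(n_markers)
        on = rng.choice(28, size=4, replace=False)
        mu[on] = rng.uniform(1.5, 2.5, size=4)
        mu[28] = 1.5  # counterstain expressed by every cell
        sd = np.full(n_markers, 0.5)
        sd[28] = 0.25
        types.append(CellType(f"pop_{t}", p, mu, sd))
    return PanelSpec(
        marker_names=names,
        cell_types=types,
        n_cells=n_cells,
        crossbleed=crossbleed,
        counterstain="DAPI",
    )


def generate_lowsnr_scenario(
    n_cells: int = 20000,
    rare_fraction: float = 0.05,
    shift: float = 0.5,
    seed: int = 0,
    crossbleed: float = 0.05,
) -> tuple[CellTable, SyntheticTruth]:
    """Preset panel with a rare population expressing one marker at low SNR.

    Ten markers, five types.  Four common types each express an exclusive
    pair of structural markers; the rare type expresses none of them, so it is
    distinct only through its joint (mostly negative) profile.  Exactly one
    marker — the designated weak channel — differs between the rare type and
    everyone else, by ``shift`` on the log scale against a log-SD of 0.7, so
    supports overlap heavily (theoretical single-marker AUC ~0.69 at
    shift=0.5; no single marker separates rare from rest with AUC >= 0.75).
    The rare-cell count is exactly round(rare_fraction * n_cells).
    """
    if not (0 < rare_fraction <= 0.2):
        raise ValidationError("rare_fraction must be in (0, 0.2]")
    if shift < 0:
        raise ValidationError("shift must be >= 0")
    lowsnr_sd = 0.7
    auc = norm.cdf(shift / (np.sqrt(2) * lowsnr_sd))
    if auc >= 0.95:
        warnings.warn(
            f"shift={shift} gives single-marker AUC {auc:.3f} >= 0.95; "
            "the scenario is no longer low-SNR",
            stacklevel=2,
        )

    n_markers = 10
    names = [f"M{i:02d}" for i in range(8)] + ["DAPI", "CKlow"]
    common_prev = np.array([0.40, 0.25, 0.20, 0.15]) * (1 - rare_fraction)
    prevalences = list(common_prev) + [rare_fraction]

    types = []
    for t, p in enumerate(prevalences):
        mu = np.zeros(n_markers)
        sd = np.full(n_markers, 0.5)
        mu[8] = 1.5  # counterstain
        sd[8] = 0.25
        sd[9] = lowsnr_sd
        if t < 4:
            mu[2 * t] = 2.0
            mu[2 * t + 1] = 2.0
            name = f"common_{t}"
        else:
            mu[9] = shift
            name = "rare"
        types.append(CellType(name, float(p), mu, sd))

    spec = PanelSpec(
        marker_names=names,
        cell_types=types,
        n_cells=n_cells,
        crossbleed=crossbleed,
        background_sd=0.05,
        lowsnr_marker=9,
        lowsnr_type=4,
        counterstain="DAPI",
    )
    n_rare = int(round(rare_fraction * n_cells))
    rng = np.random.default_rng(seed)
    counts = _exact_counts(np.array(prevalences), n_cells, pin={4: n_rare})
    labels = np.repeat(np.arange(5), counts)
    rng.shuffle(labels)
    table, truth = _generate_from_labels(spec, labels, rng)
    truth.seed = seed
    return table, truth


def _generate_from_labels(
    spec: PanelSpec, labels: np.ndarray, rng: np.random.Generator
) -> tuple[CellTable, SyntheticTruth]:
    n, m = len(labels), spec.n_markers
    w, h = spec.field_size
    x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)
    mus = np.stack([t.log_means for t in spec.cell_types])[labels]
    sds = np.stack([t.log_sds for t in spec.cell_types])[labels]
    own = np.exp(rng.normal(mus, sds))
    beta = spec.crossbleed
    if beta > 0 and n > 1:
        k = min(spec.k_neighbors, n - 1)
        tree = cKDTree(np.column_stack([x, y]))
        _, idx = tree.query(np.column_stack([x, y]), k=k + 1)
        observed = (1 - beta) * own + beta * own[idx[:, 1:]].mean(axis=1)
    else:
        observed = own.copy()
    if spec.background_sd > 0:
        observed = observed + np.abs(rng.normal(0.0, spec.background_sd, size=(n, m)))
    table = CellTable(np.arange(n), x, y, observed, list(spec.marker_names))
    truth = SyntheticTruth(labels, [t.name for t in spec.cell_types], spec, -1)
    return table, truth


# ---------------------------------------------------------------------------
# Test images
# ---------------------------------------------------------------------------

def generate_test_images(kind: str, params: dict | None = None, seed: int = 0):
    """Generate 8-bit test images for the quantization utilities.

    kind="ramp"
        Horizontal gradient containing all 256 gray values.
        params: width (>= 256, default 256), height (default 32).
    kind="posterize_panel"
        dict mapping bit depth in {8, 7, 6, 5, 4} to the posterized ramp.
    kind="dendrite"
        Faint bright curvilinear structure (peak amplitude ``amp``) plus a
        bright cell body, over Gaussian background noise (mean ``bg``, SD
        ``sd``); returns (image, mask) where mask marks true dendrite pixels.
        The bright soma reproduces the realistic situation in which a global
        threshold locks onto strong signal and misses faint structure.
        params: amp (default 10), bg (20), sd (5), height (105), width (165),
        soma_amp (160).
    """
    p = dict(params or {})
    if kind == "ramp":
        width = int(p.get("width", 256))
        height = int(p.get("height", 32))
        if width < 256 or width * height < 256:
            raise ValidationError("ramp needs width >= 256 to contain all 256 values")
        row = (np.arange(width) * 256 // width).clip(0, 255).astype(np.uint8)
        return np.tile(row, (height, 1))
    if kind == "posterize_panel":
        from .imageops import posterize

        ramp = generate_test_images("ramp", p, seed)
        return {b: posterize(ramp, b) for b in (8, 7, 6, 5, 4)}
    if kind == "dendrite":
        amp = float(p.get("amp", 10.0))
        if amp <= 0:
            raise ValidationError("dendrite amplitude must be > 0")
        bg = float(p.get("bg", 20.0))
        sd = float(p.get("sd", 5.0))
        height = int(p.get("height", 105))
        width = int(p.get("width", 165))
        soma_amp = float(p.get("soma_amp", 160.0))
        rng = np.random.default_rng(seed)

        img = rng.normal(bg, sd, (height, width))
        # dendrite center line: smooth random walk across the full width
        yc = height / 2 + np.cumsum(rng.normal(0, 1.0, width))
        yc = yc - yc.mean() + height / 2
        yc = np.clip(yc, 2, height - 3)
        pts = np.column_stack([yc, np.arange(width)])
        yy, xx = np.mgrid[0:height, 0:width]
        d, _ = cKDTree(pts).query(np.column_stack([yy.ravel(), xx.ravel()]))
        d = d.reshape(height, width)
        img += amp * np.exp(-(d**2) / (2 * 0.8**2))
        mask = d < 1.5

        if soma_amp > 0:  # bright cell body at the dendrite's origin
            cy, cx = yc[-8], width - 8
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img += soma_amp * np.exp(-r2 / (2 * 4.0**2))
            mask &= r2 > 8.0**2  # soma footprint is not dendrite ground truth

        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        return img, mask
    raise ValidationError(f"unknown test image kind {kind!r}")
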