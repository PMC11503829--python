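"""Image-quantization and quantification utilities for 8-bit micrographs.

These are the classical eye-guided analysis operations the pipeline is
contrasted with: bit-depth posterization, gray-level counting, Otsu
thresholding, stained-area quantification normalized to a reference (nuclear)
mask, rectangular line profiles, logarithmic rendering, and brightfield
stain unmixing by optical-density color deconvolution.

Conventions: grayscale images are 2-D uint8 arrays (0-255), RGB images are
(H, W, 3); origin top-left, row-major.
"""

from __future__ import annotations

import numpy as np

from .io import ValidationError

__all__ = [
    "DegenerateImageError",
    "posterize",
    "count_levels",
    "otsu_threshold",
    "otsu_split",
    "mixture_foreground",
    "area_fraction",
    "line_profile",
    "log_render",
    "surface_export",
    "color_deconvolve",
    "STAIN_PRESETS",
]


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on the given image (e.g. constant)."""


def _check_image(image: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(image)
    if img.ndim not in (2, 3) or (img.ndim == 3 and img.shape[2] != 3):
        raise ValidationError(f"{name} must be 2-D grayscale or (H, W, 3) RGB")
    if img.size == 0:
        raise ValidationError(f"{name} must have at least one pixel")
    if img.dtype != np.uint8:
        arr = np.asarray(img, float)
        if arr.min() < 0 or arr.max() > 255:
            raise ValidationError(f"{name} values must lie in [0, 255]")
        img = np.rint(arr).astype(np.uint8)
    return img


def posterize(image: np.ndarray, bits: int) -> np.ndarray:
    """Reduce per-channel bit depth to ``bits`` (L = 2**bits output levels).

    Each value v maps to level i = floor(v * L / 256) (clamped to L - 1) and
    is rendered back to 8-bit as round(i * 255 / (L - 1)), so 0 -> 0 and
    255 -> 255 at every bit depth.  bits=8 returns the image unchanged.
    """
    if not (1 <= int(bits) <= 8) or int(bits) != bits:
        raise ValidationError("bits must be an integer in [1, 8]")
    img = _check_image(image)
    if bits == 8:
        return img.copy()
    L = 2 ** int(bits)
    idx = np.minimum(img.astype(np.int32) * L // 256, L - 1)
    lut_vals = np.rint(np.arange(L) * 255.0 / (L - 1)).astype(np.uint8)
    return lut_vals[idx]


def count_levels(image: np.ndarray) -> int:
    """Number of distinct pixel values present in the image (all channels pooled)."""
    return int(len(np.unique(_check_image(image))))


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold: smallest t in [0, 255] maximizing between-class variance.

    The image is split into {<= t, > t}; between-class variance
    w0 * w1 * (mu0 - mu1)^2 is evaluated for every t and the smallest
    maximizer returned (deterministic tie-break).  Constant images have no
    two-class partition and raise :class:`DegenerateImageError`.
    """
    img = _check_image(image)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: no threshold exists")
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def area_fraction(stain_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """Stained area normalized to a reference area: sum(stain) / sum(reference).

    Typical use: stained pixels over total nuclear (counterstain) pixels.
    The ratio can exceed 1.  An empty reference mask is an error.
    """
    stain = np.asarray(stain_mask).astype(bool)
    ref = np.asarray(reference_mask).astype(bool)
    if stain.shape != ref.shape:
        raise ValidationError("stain and reference masks must have equal shape")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValidationError("reference mask has no positive pixels")
    return float(stain.sum()) / n_ref


def line_profile(image: np.ndarray, rectangle: tuple[int, int, int, int]) -> np.ndarray:
    """Mean-intensity profile along the longer axis of an axis-aligned rectangle.

    ``rectangle`` is (x, y, width, height) with (x, y) the top-left corner in
    pixel coordinates.  For a wide rectangle the result is the per-column
    mean over its rows (length = width); for a tall one, the per-row mean
    (length = height).
    """
    img = _check_image(image)
    if img.ndim != 2:
        raise ValidationError("line_profile expects a grayscale image")
    x, y, w, h = (int(v) for v in rectangle)
    if w < 1 or h < 1:
        raise ValidationError("rectangle width and height must be >= 1")
    if x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
        raise ValidationError("rectangle out of image bounds")
    region = img[y : y + h, x : x + w].astype(float)
    return region.mean(axis=0) if w >= h else region.mean(axis=1)


def log_render(image: np.ndarray) -> np.ndarray:
    """Logarithmic 8-bit rendering: v' = round(255 * log(1 + v) / log(256)).

    Monotone non-decreasing, with 0 -> 0 and 255 -> 255; expands the low end
    of the intensity scale where faint structure hides.
    """
    img = _check_image(image)
    lut = np.rint(255.0 * np.log1p(np.arange(256)) / np.log(256.0)).astype(np.uint8)
    return lut[img]


def surface_export(image: np.ndarray):
    """Lossless (x, y, intensity) height-map table for external 3-D plotting.

    Rows are emitted in row-major order: y (row) outer, x (column) inner.
    """
    import pandas as pd

    img = _check_image(image)
    if img.ndim != 2:
        raise ValidationError("surface_export expects a grayscale image")
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "intensity": img.ravel().astype(int)}
    )


def otsu_split(values: np.ndarray) -> np.ndarray:
    """Otsu-style dichotomization of continuous non-negative values.

    Values are linearly quantized to 256 bins over their range and thresholded
    with :func:`otsu_threshold`; returns the boolean "positive" (above
    threshold) mask.  This is the single-marker gating strategy a
    thresholding-based analysis applies to one intensity channel.
    """
    v = np.asarray(values, float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValidationError("values must be finite")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateImageError("constant values: no threshold exists")
    q = np.clip((v - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    t = otsu_threshold(q.reshape(1, -1))
    return (q > t).reshape(np.asarray(values).shape)


def mixture_foreground(image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-component mixture classification of pixel log-intensities.

    Fits a 2-component Gaussian mixture to log(1 + v) over all pixels and
    returns the mask of pixels assigned to the brighter component.  Unlike a
    global threshold, the component boundary adapts to the full intensity
    distribution, which preserves faint structure lying between background
    and strong signal.
    """
    from sklearn.mixture import GaussianMixture

    img = _check_image(image)
    lv = np.log1p(img.astype(float)).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(lv)
    bright = int(np.argmax(gm.means_.ravel()))
    return (gm.predict(lv) == bright).reshape(img.shape[:2] if img.ndim == 2 else img.shape)


#: Standard brightfield stain optical-density vectors (R, G, B), unit length.
STAIN_PRESETS = {
    "hematoxylin": np.array([0.650, 0.704, 0.286]),
    "dab": np.array([0.269, 0.568, 0.777]),
    "eosin": np.array([0.072, 0.990, 0.105]),
}
STAIN_PRESETS = {k: v / np.linalg.norm(v) for k, v in STAIN_PRESETS.items()}


def color_deconvolve(image: np.ndarray, stain_vectors: np.ndarray) -> list[np.ndarray]:
    """Unmix a brightfield RGB image into per-stain optical-density images.

    Transmitted intensities are converted to optical density per channel,
    OD_c = -log10((v_c + 1) / 256), and the pixel OD vector is solved against
    the stain matrix.  With two stain vectors the third is completed as their
    normalized cross product.  Negative densities are clamped to 0.  Returns
    one density image per supplied stain, in order.

    ``image`` may be uint8 or float in [0, 255]; float input is unmixed
    without 8-bit rounding.
    """
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError("color_deconvolve expects an (H, W, 3) RGB image")
    if img.min() < 0 or img.max() > 255:
        raise ValidationError("image values must lie in [0, 255]")
    S = np.atleast_2d(np.asarray(stain_vectors, float))
    if S.shape[0] not in (2, 3) or S.shape[1] != 3:
        raise ValidationError("stain_vectors must be 2 or 3 RGB optical-density vectors")
    if np.any(S < 0):
        raise ValidationError("stain vectors must be non-negative")
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValidationError("stain vectors must be non-zero")
    S = S / norms[:, None]
    n_stains = S.shape[0]
    if n_stains == 2:
        third = np.cross(S[0], S[1])
        if np.linalg.norm(third) < 1e-8:
            raise ValidationError("stain vectors are collinear")
        S = np.vstack([S, third / np.linalg.norm(third)])
    if np.linalg.matrix_rank(S, tol=1e-8) < 3:
        raise ValidationError("stain vectors are collinear")

    od = -np.log10((img + 1.0) / 256.0)  # (H, W, 3)
    dens = od.reshape(-1, 3) @ np.linalg.inv(S)
    dens = np.clip(dens, 0.0, None).reshape(img.shape[0], img.shape[1], 3)
    return [dens[:, :, i] for i in range(n_stains)]
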