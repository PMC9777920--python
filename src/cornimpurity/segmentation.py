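"""Otsu binarization and the binary-morphology toolkit.

The foreground/background split (corn pile + impurities vs the dark
gaps between kernels) uses Otsu's maximum between-class-variance
threshold on the BT.601 luminance histogram. The morphology primitives
here — open, close, dilate, hole filling, majority (median) filtering,
connected components and area filtering — are the building blocks from
which each impurity class assembles its refinement pipeline.

Connectivity is 8 throughout: debris fragments that touch diagonally
should count as one object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, dilation, disk, opening

from .errors import DegenerateImageError, ParameterError
from .raster_io import validate_mask, validate_rgb

__all__ = [
    "ComponentSet",
    "luminance",
    "otsu_threshold",
    "binarize",
    "morph_open",
    "morph_close",
    "morph_dilate",
    "fill_holes",
    "median_filter",
    "label_components",
    "area_filter",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class ComponentSet:
    """Connected components of a mask: label raster (0 = background,
    k = component id, ids contiguous 1..N) and per-component pixel counts
    (``sizes[k - 1]`` is the size of component k)."""

    labels: np.ndarray
    sizes: np.ndarray
    connectivity: int = 8


def luminance(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RgbImage, rounded to uint8 gray levels."""
    validate_rgb(image)
    y = image @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold for a 256-bin gray-level histogram.

    Returns the level t maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` of the split {<= t} / {> t}; foreground
    is the bright side (``gray > t``). Ties are broken toward the
    smallest maximizing t, so the result is deterministic.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,) or (hist < 0).any():
        raise ParameterError("hist must be 256 non-negative counts")
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("histogram has fewer than two gray levels")
    total = hist.sum()
    levels = np.arange(256)
    w0 = np.cumsum(hist)[:-1]  # mass at levels <= t, t = 0..254
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    m1 = (hist * levels).sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
    variance = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(variance))  # argmax returns the first maximizer


def binarize(image: np.ndarray) -> np.ndarray:
    """Otsu foreground mask of an RgbImage (corn + impurities = bright side)."""
    gray = luminance(image)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = otsu_threshold(hist)
    return gray > t


def _check_radius(radius: int) -> None:
    if radius < 1:
        raise ParameterError(f"structuring-element radius must be >= 1, got {radius}")


def morph_open(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion then dilation with a disk: removes specks and thin
    protrusions (e.g. kernel radicle tips) without growing what remains."""
    _check_radius(radius)
    return opening(validate_mask(mask), disk(radius))


def morph_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation then erosion with a disk: bridges cracks and closes gaps."""
    _check_radius(radius)
    return closing(validate_mask(mask), disk(radius))


def morph_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation with a disk structuring element."""
    _check_radius(radius)
    return dilation(validate_mask(mask), disk(radius))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Turn background components not connected to the border into
    foreground (fills the 'loopholes' inside detected impurities)."""
    return ndimage.binary_fill_holes(validate_mask(mask))


def median_filter(mask: np.ndarray, size: int) -> np.ndarray:
    """Majority vote in a size×size window (odd size, reflected borders):
    removes isolated broken points and smooths ragged edges."""
    if size < 3 or size % 2 == 0:
        raise ParameterError(f"median window must be odd and >= 3, got {size}")
    filtered = ndimage.median_filter(
        validate_mask(mask).astype(np.uint8), size=size, mode="reflect"
    )
    return filtered.astype(bool)


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """8- (default) or 4-connected components with per-component sizes."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else None
    labels, n = ndimage.label(validate_mask(mask), structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ComponentSet(labels=labels, sizes=sizes, connectivity=connectivity)


def area_filter(mask: np.ndarray, threshold: int, mode: str) -> np.ndarray:
    """Keep connected components by area: ``keep_ge`` retains components
    of size >= threshold, ``keep_lt`` those of size < threshold.

    This encodes the class size priors: bract fragments occupy at least
    4500 px at the working resolution, crushed stones fewer than 400 px.
    """
    if threshold < 1:
        raise ParameterError(f"area threshold must be >= 1, got {threshold}")
    if mode not in ("keep_ge", "keep_lt"):
        raise ParameterError(f"mode must be keep_ge or keep_lt, got {mode!r}")
    comps = label_components(mask)
    if comps.sizes.size == 0:
        return np.zeros_like(mask)
    keep = comps.sizes >= threshold if mode == "keep_ge" else comps.sizes < threshold
    lut = np.concatenate(([False], keep))
    return lut[comps.labels]
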