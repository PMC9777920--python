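"""Raster input/output and the shared pixel conventions.

Every raster in this package is a numpy array with the origin at the
top-left corner, row-major order and 0-based indices; sizes are always
stated as ``(height, width)``.

Three array kinds circulate between modules:

``RgbImage``
    ``(H, W, 3) uint8`` array, channel order R, G, B. The pipeline input.
``BinaryMask``
    ``(H, W) bool`` array annotating an image of the same shape.
``LabelMap``
    ``(H, W) uint8`` array with the per-pixel class assignment. Codes are
    fixed as 0 = background/corn, 1 = broken bract, 2 = broken corncob,
    3 = crushed stone.

Masks and label maps are persisted as single-channel PNG only (lossless,
so classification output round-trips bit-exactly); JPEG is accepted for
input photographs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

__all__ = [
    "BACKGROUND",
    "BRACT",
    "CORNCOB",
    "STONE",
    "CLASS_CODES",
    "CLASS_NAMES",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_manifest",
    "read_manifest",
    "validate_rgb",
    "validate_mask",
    "validate_labels",
]

BACKGROUND = 0
BRACT = 1
CORNCOB = 2
STONE = 3

#: class name -> label code (background is the corn bed, not an impurity)
CLASS_CODES = {"bract": BRACT, "corncob": CORNCOB, "stone": STONE}
#: label code -> class name
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

_MAX_LABEL = STONE


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check that *image* is an 8-bit H×W×3 RGB raster and return it."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(
            f"expected an (H, W, 3) RGB raster, got shape {image.shape}"
        )
    if image.dtype != np.uint8:
        raise FormatError(f"expected uint8 pixels, got {image.dtype}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise FormatError("image must be at least 1x1")
    return image


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Check that *mask* is a boolean H×W raster (optionally of *shape*)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise FormatError(
            f"expected an (H, W) bool mask, got shape {mask.shape}, dtype {mask.dtype}"
        )
    if shape is not None and mask.shape != tuple(shape):
        raise FormatError(f"mask shape {mask.shape} does not match image shape {shape}")
    return mask


def validate_labels(labels: np.ndarray) -> np.ndarray:
    """Check that *labels* is an H×W uint8 raster using only codes 0-3."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise FormatError(f"expected an (H, W) label map, got shape {labels.shape}")
    if labels.dtype != np.uint8:
        raise FormatError(f"expected uint8 labels, got {labels.dtype}")
    if labels.size and labels.max() > _MAX_LABEL:
        bad = int(labels.max())
        raise FormatError(f"label code {bad} out of range 0..{_MAX_LABEL}")
    return labels


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit colour photograph (JPEG or PNG) as an RgbImage.

    An alpha channel, if present, is silently dropped. Grayscale payloads
    are rejected: the classifier needs colour.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure on e.g. a text file
        raise FormatError(f"{path} does not decode as an image: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected a colour image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit pixels, got {arr.dtype}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RgbImage as PNG or JPEG (by extension)."""
    iio.imwrite(Path(path), validate_rgb(image))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a BinaryMask (as 0/255) or LabelMap (codes 0-3) as a
    single-channel PNG.

    PNG is mandatory: classification output must round-trip bit-exactly.
    """
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise FormatError(f"masks must be written as PNG, got {path.suffix!r}")
    mask = np.asarray(mask)
    if mask.dtype == bool:
        payload = np.where(mask, np.uint8(255), np.uint8(0))
    else:
        payload = validate_labels(mask)
    iio.imwrite(path, payload)


def read_mask(path: str | Path, as_labels: bool = False) -> np.ndarray:
    """Read a single-channel PNG written by :func:`write_mask`.

    With ``as_labels`` the payload must use only the codes 0-3; otherwise
    any nonzero pixel is foreground.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: masks must be single-channel, got shape {arr.shape}")
    if as_labels:
        return validate_labels(arr.astype(np.uint8, casting="same_kind"))
    return arr > 0


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a result manifest as JSON (counts, scores, impurity content)."""
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
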