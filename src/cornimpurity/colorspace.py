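"""Colour-space conversion and per-region channel statistics.

Impurity classes are told apart by colour. Three spaces are supported —
HSV, NTSC (YIQ) and YCbCr — but only HSV drives the classifier: the
chromatic NTSC/YCbCr channels of the impurity classes overlap too much
to separate them, and they are kept here purely for the diagnostic
statistics that motivate that choice. In every space the luminance-like
channel (V, Y) is computed but flagged as excluded from classification,
so that illumination changes do not leak into class decisions.

Conventions:

* HSV follows the hexcone model with h, s, v all in [0, 1]; hue is the
  fraction of the full hue circle, **not** degrees, because the class
  thresholds are calibrated on that scale. Achromatic pixels (R = G = B)
  have s = 0 and, by convention, h = 0.
* NTSC is the YIQ linear transform of RGB scaled to [0, 1]; i and q keep
  their natural signed ranges.
* YCbCr uses the ITU-R BT.601 studio-range transform with all three
  channels rescaled to [0, 1] (i.e. divided by 255).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .errors import ParameterError
from .raster_io import validate_mask, validate_rgb

__all__ = [
    "SPACES",
    "ChannelStats",
    "convert_colorspace",
    "rgb_to_hsv",
    "channel_statistics",
    "stats_to_frame",
]

#: space -> (channel names, luminance channel index)
SPACES: dict[str, tuple[tuple[str, str, str], int]] = {
    "HSV": (("h", "s", "v"), 2),
    "NTSC": (("y", "i", "q"), 0),
    "YCbCr": (("y", "cb", "cr"), 0),
}

# value domain of each chromatic channel, used for fixed histogram binning
# (fixed edges make histograms over disjoint regions additive)
_DOMAINS = {
    ("HSV", "h"): (0.0, 1.0),
    ("HSV", "s"): (0.0, 1.0),
    ("NTSC", "i"): (-0.5957, 0.5957),
    ("NTSC", "q"): (-0.5226, 0.5226),
    ("YCbCr", "cb"): (0.0, 1.0),
    ("YCbCr", "cr"): (0.0, 1.0),
}

_N_BINS = 64


@dataclass
class ChannelStats:
    """Distribution summary of one chromatic channel over a pixel region."""

    space: str
    channel: str
    min: float
    max: float
    counts: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def convert_colorspace(image: np.ndarray, space: str) -> np.ndarray:
    """Convert an RgbImage to a float H×W×3 raster in the requested space.

    Returns channels in the order listed in :data:`SPACES`. The
    luminance-like channel is present in the output but is not used by
    the classifier.
    """
    validate_rgb(image)
    if space not in SPACES:
        raise ParameterError(f"unknown colour space {space!r}; choose from {sorted(SPACES)}")
    rgb = image.astype(np.float64) / 255.0
    if space == "HSV":
        return skcolor.rgb2hsv(rgb)
    if space == "NTSC":
        return skcolor.rgb2yiq(rgb)
    # YCbCr: skimage returns studio-range values on the 0-255 scale
    return skcolor.rgb2ycbcr(rgb.astype(np.float32)).astype(np.float64) / 255.0


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """HSV conversion shortcut; h, s, v all in [0, 1]."""
    return convert_colorspace(image, "HSV")


def channel_statistics(
    image: np.ndarray, region: np.ndarray, space: str = "HSV"
) -> list[ChannelStats]:
    """Distribution of the two chromatic channels over *region* pixels.

    This is the calibration step behind the class thresholds: crop a
    region known to contain one impurity class, look at where its h and s
    values (or i/q, Cb/Cr) fall, and place the class band around them.
    """
    validate_rgb(image)
    validate_mask(region, image.shape[:2])
    if not region.any():
        raise ValueError("region is empty; statistics undefined")
    converted = convert_colorspace(image, space)  # validates the space name
    names, lum = SPACES[space]
    out = []
    for idx, name in enumerate(names):
        if idx == lum:
            continue  # illumination-related channel excluded
        values = converted[:, :, idx][region]
        lo, hi = _DOMAINS[(space, name)]
        counts, edges = np.histogram(values, bins=_N_BINS, range=(lo, hi))
        out.append(
            ChannelStats(
                space=space,
                channel=name,
                min=float(values.min()),
                max=float(values.max()),
                counts=counts,
                bin_edges=edges,
            )
        )
    return out


def stats_to_frame(stats: list[ChannelStats]) -> pd.DataFrame:
    """Flatten ChannelStats into a tidy table (one row per histogram bin),
    suitable for CSV export."""
    rows = []
    for st in stats:
        for left, right, count in zip(st.bin_edges[:-1], st.bin_edges[1:], st.counts):
            rows.append(
                {
                    "space": st.space,
                    "channel": st.channel,
                    "min": st.min,
                    "max": st.max,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows)
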