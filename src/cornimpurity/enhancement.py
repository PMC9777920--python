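"""Multi-scale retinex with colour restoration (MSRCR).

Images captured inside a grain dryer suffer from uneven illumination
(a dark vignette toward the edges away from the light source) and dust
haze. Both push dark-corner kernels below a global binarization
threshold. Retinex enhancement removes the slowly-varying illumination
component before thresholding:

* single-scale retinex (SSR) of a channel I at scale sigma is
  ``log(I + eps) - log(G_sigma * I + eps)`` where ``G_sigma *`` denotes
  convolution with a normalized Gaussian surround — the log-ratio of a
  pixel to its neighbourhood average, which cancels any multiplicative
  illumination field that is smooth at scale sigma;
* MSR is a weighted sum of SSR over several scales (small scales keep
  edges, large scales keep tonal balance);
* the colour-restoration factor ``C_i = beta * (log(alpha*I_i + eps) -
  log(I_R + I_G + I_B + eps))`` re-weights each channel by its share of
  the pixel's total intensity, counteracting the desaturation that pure
  MSR causes;
* the product ``C_i * MSR_i`` is mapped to [0, 255] by a linear stretch
  between two percentiles of its own distribution (self-calibrating,
  unlike fixed gain/offset constants).

The whole chain is invariant, up to epsilon effects, under scaling every
input channel by a common positive constant — which is exactly the
illumination change it is designed to discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .raster_io import validate_rgb

__all__ = ["MsrcrParams", "single_scale_retinex", "msrcr_float", "msrcr"]


@dataclass(frozen=True)
class MsrcrParams:
    """MSRCR tuning knobs.

    Defaults follow the classic three-scale formulation: surround scales
    15 / 80 / 250 px with equal weights, colour-restoration alpha = 125
    and beta = 46. ``epsilon`` only guards the logarithms against zero
    pixels and is kept tiny so the log-ratio stays scale-invariant.
    Output normalization stretches between the 1st and 99th percentile.
    """

    scales: tuple[float, ...] = (15.0, 80.0, 250.0)
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    alpha: float = 125.0
    beta: float = 46.0
    clip_low: float = 1.0
    clip_high: float = 99.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.weights):
            raise ParameterError("scales and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ParameterError("weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ParameterError("weights must sum to 1")
        if any(s <= 0 for s in self.scales):
            raise ParameterError("scales must be positive")
        if list(self.scales) != sorted(set(self.scales)):
            raise ParameterError("scales must be strictly increasing")
        if not (0 <= self.clip_low < self.clip_high <= 100):
            raise ParameterError("require 0 <= clip_low < clip_high <= 100")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


def single_scale_retinex(channel: np.ndarray, sigma: float, epsilon: float = 1e-9) -> np.ndarray:
    """SSR of one non-negative float channel at surround scale *sigma*.

    Boundary handling is reflective, so the surround average never mixes
    in an artificial dark frame at the image border (a border artifact
    would defeat the point of fixing the dark-edge vignette).
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size and channel.min() < 0:
        raise ParameterError("channel values must be >= 0")
    surround = ndimage.gaussian_filter(channel, sigma=sigma, mode="reflect")
    return np.log(channel + epsilon) - np.log(surround + epsilon)


def _stretch(channel: np.ndarray, clip_low: float, clip_high: float) -> np.ndarray:
    """Linear stretch of a float field to [0, 255] between two of its own
    percentiles; a constant field maps to flat 128."""
    lo, hi = np.percentile(channel, [clip_low, clip_high])
    if hi - lo < 1e-300:
        return np.full_like(channel, 128.0)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0) * 255.0


def msrcr_float(rgb: np.ndarray, params: MsrcrParams | None = None) -> np.ndarray:
    """MSRCR on a float H×W×3 RGB raster (any non-negative scale).

    Returns the enhanced image as float64 in [0, 255], before 8-bit
    quantization. This is the form in which the illumination-scale
    invariance holds exactly (up to epsilon effects).
    """
    params = params or MsrcrParams()
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    eps = params.epsilon
    total = rgb.sum(axis=2)
    out = np.empty_like(rgb)
    for c in range(3):
        channel = rgb[:, :, c]
        msr = np.zeros_like(channel)
        for w, sigma in zip(params.weights, params.scales):
            msr += w * single_scale_retinex(channel, sigma, eps)
        restore = params.beta * (np.log(params.alpha * channel + eps) - np.log(total + eps))
        out[:, :, c] = _stretch(restore * msr, params.clip_low, params.clip_high)
    return out


def msrcr(image: np.ndarray, params: MsrcrParams | None = None) -> np.ndarray:
    """MSRCR on an 8-bit RgbImage, returning an 8-bit RgbImage."""
    validate_rgb(image)
    enhanced = msrcr_float(image.astype(np.float64), params)
    return np.clip(np.rint(enhanced), 0, 255).astype(np.uint8)
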