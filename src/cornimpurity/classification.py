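"""Per-class impurity recognition: HSV bands, coarse extraction, and
class-specific morphological refinement.

Each impurity class owns a closed hue/saturation band (hue on the [0, 1]
scale), calibrated on manually cropped impurity regions:

=========  ============  ============  ===========================
class      h range       s range       refinement
=========  ============  ============  ===========================
bract      [0.48, 0.60]  [0.15, 0.25]  open, fill holes, area >= 4500
corncob    [0.80, 1.00]  [0.06, 0.70]  close, fill holes, median
stone      [0.55, 0.65]  [0.28, 1.00]  dilate, AND binary, area < 400
=========  ============  ============  ===========================

The band mask alone fires on kernel radicle tips, shadow edges and
kernel-to-kernel boundaries, so each class first ANDs its band with the
Otsu foreground ("coarse extraction") and then applies morphology suited
to its geometry: bracts are large papery sheets full of pinholes; broken
corncobs are compact rectangles with cracks; crushed stones are small
blobs whose band mask is often incomplete and needs to be re-grown into
the binary mask before the small-area rule isolates them.

Although the bract and stone hue ranges overlap ([0.55, 0.60]), their
saturation ranges are disjoint, so no pixel can satisfy both bands.
Remaining overlaps between refined masks (created by morphology) are
resolved by class priority, default stone > corncob > bract: stones have
the tightest band and smallest area, so mis-assigning them is costliest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .colorspace import rgb_to_hsv
from .enhancement import MsrcrParams, msrcr
from .errors import ParameterError
from .raster_io import CLASS_CODES, validate_mask, validate_rgb
from .segmentation import (
    area_filter,
    binarize,
    fill_holes,
    median_filter,
    morph_close,
    morph_dilate,
    morph_open,
)

__all__ = [
    "ClassSpec",
    "ClassifierConfig",
    "default_specs",
    "hsv_band_mask",
    "coarse_extract",
    "refine_bracts",
    "refine_corncobs",
    "refine_stones",
    "PipelineArtifacts",
    "classify_detailed",
    "classify_image",
]


@dataclass(frozen=True)
class ClassSpec:
    """One impurity class: colour band, morphology plan, area rule.

    ``h_range`` and ``s_range`` are closed intervals in [0, 1] (both ends
    inclusive). ``area_rule`` is ``(threshold_px, "keep_ge" | "keep_lt")``
    or ``None``. The morphology parameters are interpreted by the class's
    refine function (see :attr:`refine_plan`).
    """

    name: str
    h_range: tuple[float, float]
    s_range: tuple[float, float]
    open_radius: int = 3
    close_radius: int = 5
    dilate_radius: int = 3
    median_size: int = 5
    area_rule: tuple[int, str] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.h_range, self.s_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ParameterError(f"invalid band [{lo}, {hi}] for {self.name!r}")
        if self.name not in CLASS_CODES:
            raise ParameterError(f"unknown class {self.name!r}")

    @property
    def refine_plan(self) -> tuple[str, ...]:
        """Human-readable morphology step sequence for this class."""
        plans = {
            "bract": (f"open(r={self.open_radius})", "fill_holes", f"area {self.area_rule}"),
            "corncob": (f"close(r={self.close_radius})", "fill_holes", f"median({self.median_size})"),
            "stone": (f"dilate(r={self.dilate_radius})", "and binary", f"area {self.area_rule}"),
        }
        return plans[self.name]


def default_specs() -> tuple[ClassSpec, ClassSpec, ClassSpec]:
    """The three impurity classes with their calibrated bands and rules."""
    return (
        ClassSpec("bract", (0.48, 0.60), (0.15, 0.25), area_rule=(4500, "keep_ge")),
        ClassSpec("corncob", (0.80, 1.00), (0.06, 0.70)),
        ClassSpec("stone", (0.55, 0.65), (0.28, 1.00), area_rule=(400, "keep_lt")),
    )


@dataclass(frozen=True)
class ClassifierConfig:
    """Full classifier configuration.

    ``source`` selects the image from which HSV is extracted. The class
    bands are calibrated on unenhanced photographs, so the default is
    ``original``; the Otsu foreground mask, by contrast, is always taken
    from the MSRCR-enhanced image when ``enhance`` is on, since that is
    where the enhancement pays off. ``priority`` lists classes from
    highest to lowest precedence for overlap resolution.
    """

    specs: tuple[ClassSpec, ...] = field(default_factory=default_specs)
    priority: tuple[str, ...] = ("stone", "corncob", "bract")
    source: str = "original"
    enhance: bool = True
    msrcr: MsrcrParams = field(default_factory=MsrcrParams)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(self.specs) != 3 or len(set(names)) != 3:
            raise ParameterError("config needs exactly three distinct class specs")
        if sorted(self.priority) != sorted(names):
            raise ParameterError("priority must be a permutation of the class names")
        if self.source not in ("original", "enhanced"):
            raise ParameterError("source must be 'original' or 'enhanced'")

    def spec(self, name: str) -> ClassSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_enhancement(self, enabled: bool) -> "ClassifierConfig":
        return replace(self, enhance=enabled)


def hsv_band_mask(hsv: np.ndarray, spec: ClassSpec) -> np.ndarray:
    """Pixels whose (h, s) fall inside the class band, both ends inclusive."""
    h, s = hsv[:, :, 0], hsv[:, :, 1]
    return (
        (h >= spec.h_range[0])
        & (h <= spec.h_range[1])
        & (s >= spec.s_range[0])
        & (s <= spec.s_range[1])
    )


def coarse_extract(band: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """AND of a class band mask with the Otsu foreground: the class's
    first-stage candidate pixels."""
    validate_mask(band)
    validate_mask(binary, band.shape)
    return band & binary


def refine_bracts(
    coarse: np.ndarray, open_radius: int = 3, area_threshold: int = 4500
) -> np.ndarray:
    """Bract refinement: open (drops radicle specks, smooths the sheet
    boundary), fill pinholes, then keep only components >= 4500 px."""
    refined = morph_open(coarse, open_radius)
    refined = fill_holes(refined)
    return area_filter(refined, area_threshold, "keep_ge")


def refine_corncobs(
    coarse: np.ndarray, close_radius: int = 5, median_size: int = 5
) -> np.ndarray:
    """Corncob refinement: close (bridges surface cracks), fill holes,
    then a majority filter to drop broken points and tidy the edges."""
    if not coarse.any():
        return validate_mask(coarse).copy()
    refined = morph_close(coarse, close_radius)
    refined = fill_holes(refined)
    return median_filter(refined, median_size)


def refine_stones(
    coarse: np.ndarray,
    binary: np.ndarray,
    dilate_radius: int = 3,
    area_threshold: int = 400,
) -> np.ndarray:
    """Stone refinement: dilate the (often incomplete) band mask, clip it
    back to the Otsu foreground to restore the stone's true extent, then
    keep only components < 400 px."""
    refined = morph_dilate(coarse, dilate_radius)
    refined = coarse_extract(refined, binary)
    return area_filter(refined, area_threshold, "keep_lt")


def _refine(name: str, coarse: np.ndarray, binary: np.ndarray, spec: ClassSpec) -> np.ndarray:
    if name == "bract":
        thr = spec.area_rule[0] if spec.area_rule else 4500
        return refine_bracts(coarse, spec.open_radius, thr)
    if name == "corncob":
        return refine_corncobs(coarse, spec.close_radius, spec.median_size)
    thr = spec.area_rule[0] if spec.area_rule else 400
    return refine_stones(coarse, binary, spec.dilate_radius, thr)


@dataclass
class PipelineArtifacts:
    """Intermediate and final products of one classification run."""

    labels: np.ndarray    # LabelMap, codes 0-3
    binary: np.ndarray    # Otsu foreground used for the AND steps
    enhanced: np.ndarray  # MSRCR image (the input itself if enhancement off)


def classify_detailed(
    image: np.ndarray, config: ClassifierConfig | None = None
) -> PipelineArtifacts:
    """Run the full recognition chain on one photograph.

    Produces a LabelMap (0 background/corn, 1 bract, 2 corncob, 3 stone)
    together with the intermediate rasters the quantification stage
    needs. Lower-priority classes are painted first, so a pixel claimed
    by several refined masks ends up with the highest-priority label.
    """
    validate_rgb(image)
    config = config or ClassifierConfig()
    enhanced = msrcr(image, config.msrcr) if config.enhance else image
    binary = binarize(enhanced)
    hsv = rgb_to_hsv(enhanced if config.source == "enhanced" else image)

    labels = np.zeros(image.shape[:2], dtype=np.uint8)
    for name in reversed(config.priority):
        spec = config.spec(name)
        coarse = coarse_extract(hsv_band_mask(hsv, spec), binary)
        refined = _refine(name, coarse, binary, spec)
        labels[refined] = CLASS_CODES[name]
    return PipelineArtifacts(labels=labels, binary=binary, enhanced=enhanced)


def classify_image(
    image: np.ndarray, config: ClassifierConfig | None = None
) -> np.ndarray:
    """LabelMap of one photograph (see :func:`classify_detailed`)."""
    return classify_detailed(image, config).labels
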