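"""Deterministic synthetic corn-pile scenes with pixel-level ground truth.

No image dataset accompanies the impurity-detection problem, so this
module renders scenes that reproduce the statistical structure the
classifier relies on, plus the degradations the enhancement stage is
meant to fix:

* a dense bed of overlapping elliptical corn kernels in the yellow-orange
  hue band, a fraction of which carry a pale low-saturation radicle tip
  at one end (the tips fall inside the bract colour band and are the
  classic false-positive source the bract area rule must reject);
* impurity objects painted on top of the bed, each with per-pixel HSV
  sampled strictly inside its class band (margin 0.01 by default, so
  8-bit quantization cannot push a truth pixel out of band): bracts as
  large irregular blobs (area >= 4500 px), broken corncobs as rotated
  rectangles, crushed stones as small blobs (area < 400 px) resting in a
  dark crevice ring, the way small debris settles between kernels;
* degradations applied only after the ground truth is frozen — a
  multiplicative illumination ramp darkening the top-left (the vignette
  seen away from the light source), achromatic gray dust specks, and
  additive Gaussian noise. Degradations never change labels.

Everything is driven by one ``numpy`` Generator seeded from
``SceneConfig.seed``: the same config yields bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from skimage import color as skcolor
from skimage.morphology import dilation, disk

from .errors import ParameterError
from .evaluation import ContentModel, impurity_content
from .raster_io import BRACT, CORNCOB, STONE

__all__ = [
    "SceneConfig",
    "SceneBundle",
    "generate_scene",
    "degrade",
    "PRESETS",
    "preset_config",
]

Band = tuple[float, float]


@dataclass(frozen=True)
class SceneConfig:
    """Scene recipe. All HSV bands sit strictly inside the corresponding
    classifier bands so that ground truth is recoverable by construction;
    kernel and background colours sit outside every class band."""

    seed: int = 0
    height: int = 480
    width: int = 600

    # corn bed
    n_kernels: int = 900
    kernel_h: Band = (0.08, 0.14)
    kernel_s: Band = (0.50, 0.90)
    kernel_v: Band = (0.60, 0.95)
    kernel_major: tuple[int, int] = (16, 22)   # semi-axes, px
    kernel_minor: tuple[int, int] = (11, 16)
    radicle_fraction: float = 0.35
    radicle_h: Band = (0.49, 0.58)  # inside the bract band: interference
    radicle_s: Band = (0.16, 0.24)
    radicle_v: Band = (0.55, 0.75)

    # background between kernels: dark, nearly achromatic, hue away from
    # every class band
    background_h: Band = (0.20, 0.45)
    background_s: Band = (0.00, 0.03)
    background_v: Band = (0.03, 0.10)

    # impurities
    n_bracts: int = 1
    bract_h: Band = (0.49, 0.59)
    bract_s: Band = (0.16, 0.24)
    bract_v: Band = (0.55, 0.80)
    bract_area: tuple[int, int] = (6000, 9000)

    n_corncobs: int = 1
    corncob_h: Band = (0.82, 0.98)
    corncob_s: Band = (0.10, 0.60)
    corncob_v: Band = (0.50, 0.85)
    corncob_long: tuple[int, int] = (60, 100)  # rectangle sides, px
    corncob_short: tuple[int, int] = (35, 55)

    n_stones: int = 3
    stone_h: Band = (0.56, 0.64)
    stone_s: Band = (0.30, 0.90)
    stone_v: Band = (0.40, 0.70)
    stone_area: tuple[int, int] = (80, 200)
    stone_shadow: int = 4  # crevice ring width, px

    # degradations (applied after truth is frozen)
    vignette_strength: float = 0.0
    dust_density: float = 0.0
    noise_sigma: float = 0.0

    content_model: ContentModel = field(default_factory=ContentModel)

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ParameterError("canvas must be at least 64x64")
        if min(self.vignette_strength, self.dust_density, self.noise_sigma) < 0:
            raise ParameterError("degradation parameters must be >= 0")
        # rough feasibility: impurity bounding boxes must fit the canvas
        need = (
            self.n_bracts * (2 * _BRACT_WINDOW) ** 2 / 4
            + self.n_corncobs * self.corncob_long[1] ** 2
            + self.n_stones * (4 * self.stone_shadow + 30) ** 2
        )
        if need > 0.5 * self.height * self.width:
            raise ParameterError("impurity areas infeasible for canvas size")


#: half-size of the local window in which a bract blob is grown
_BRACT_WINDOW = 80


@dataclass
class SceneBundle:
    """A rendered scene: image, per-pixel truth labels, and a manifest
    with per-object records and the ground-truth impurity content."""

    image: np.ndarray   # (H, W, 3) uint8
    truth: np.ndarray   # (H, W) uint8 label map
    corn: np.ndarray    # (H, W) bool: kernel coverage minus impurities/crevices
    manifest: dict[str, Any]
    config: SceneConfig

    @property
    def foreground(self) -> np.ndarray:
        """Ground-truth bright foreground: corn plus impurities."""
        return self.corn | (self.truth > 0)


# --------------------------------------------------------------------------
# painting helpers (all operate on separate float H, S, V planes)


def _sample(rng: np.random.Generator, band: Band, n: int) -> np.ndarray:
    return rng.uniform(band[0], band[1], size=n)


def _paint(planes, mask, rows, cols, rng, h: Band, s: Band, v: Band) -> None:
    """Paint per-pixel HSV jitter inside the given bands."""
    hp, sp, vp = planes
    n = rows.size
    hp[rows, cols] = _sample(rng, h, n)
    sp[rows, cols] = _sample(rng, s, n)
    vp[rows, cols] = _sample(rng, v, n)
    mask[rows, cols] = True


def _ellipse_coords(r0, c0, a, b, theta, shape):
    """Pixel coordinates of a rotated ellipse clipped to the canvas."""
    rad = int(np.ceil(max(a, b))) + 1
    rr = np.arange(max(0, int(r0) - rad), min(shape[0], int(r0) + rad + 1))
    cc = np.arange(max(0, int(c0) - rad), min(shape[1], int(c0) + rad + 1))
    if rr.size == 0 or cc.size == 0:
        return np.array([], int), np.array([], int)
    dy = rr[:, None] - r0
    dx = cc[None, :] - c0
    u = dx * np.cos(theta) + dy * np.sin(theta)
    w = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (w / b) ** 2 <= 1.0
    iy, ix = np.nonzero(inside)
    return rr[iy], cc[ix]


def _blob_mask(rng: np.random.Generator, target_area: int, window: int) -> np.ndarray:
    """Irregular connected blob: a random walk of overlapping stamped
    disks, grown until the area reaches the target. Each step is shorter
    than the previous disk radius, so the union stays 8-connected."""
    size = 2 * window
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[:size, :size]
    margin = 28.0
    py = px = float(window)
    r_prev = rng.uniform(22, 30)
    mask |= (yy - py) ** 2 + (xx - px) ** 2 <= r_prev**2
    while mask.sum() < target_area:
        r = rng.uniform(14, 26)
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(0.4, 0.9) * r_prev
        py = float(np.clip(py + step * np.sin(ang), margin, size - margin))
        px = float(np.clip(px + step * np.cos(ang), margin, size - margin))
        mask |= (yy - py) ** 2 + (xx - px) ** 2 <= r**2
        r_prev = r
    return mask


def _small_blob(rng: np.random.Generator, target_area: int) -> np.ndarray:
    """Small stone-shaped blob of roughly the target area."""
    r0 = max(3.0, np.sqrt(target_area / np.pi) * rng.uniform(0.75, 0.9))
    size = int(4 * r0) + 8
    yy, xx = np.mgrid[:size, :size]
    cy = cx = size / 2
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r0**2
    for _ in range(rng.integers(1, 3)):
        r = r0 * rng.uniform(0.5, 0.8)
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.4, 0.9) * r0
        mask |= (yy - cy - off * np.sin(ang)) ** 2 + (xx - cx - off * np.cos(ang)) ** 2 <= r**2
    return mask


def _place_nonoverlapping(rng, shape, half_h, half_w, occupied, margin=10, tries=200):
    """Find a center whose (half_h, half_w) box avoids previously placed
    impurity boxes; raises if the canvas is too crowded."""
    H, W = shape
    for _ in range(tries):
        r = rng.uniform(half_h + 2, H - half_h - 2)
        c = rng.uniform(half_w + 2, W - half_w - 2)
        box = (r - half_h - margin, r + half_h + margin, c - half_w - margin, c + half_w + margin)
        if all(box[1] < o[0] or box[0] > o[1] or box[3] < o[2] or box[2] > o[3] for o in occupied):
            occupied.append(box)
            return r, c
    raise ParameterError("could not place impurity: canvas too crowded")


def _object_record(name, mask, planes):
    hp, sp, vp = planes
    ys, xs = np.nonzero(mask)
    return {
        "class": name,
        "centroid": [float(ys.mean()), float(xs.mean())],
        "area": int(mask.sum()),
        "mean_hsv": [float(hp[mask].mean()), float(sp[mask].mean()), float(vp[mask].mean())],
    }


# --------------------------------------------------------------------------


def generate_scene(config: SceneConfig | None = None) -> SceneBundle:
    """Render one scene: corn bed, impurities, truth, then degradations."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    shape = (H, W)

    hp = np.empty(shape)
    sp = np.empty(shape)
    vp = np.empty(shape)
    planes = (hp, sp, vp)

    # background
    hp[:] = rng.uniform(*config.background_h, size=shape)
    sp[:] = rng.uniform(*config.background_s, size=shape)
    vp[:] = rng.uniform(*config.background_v, size=shape)

    # corn bed
    corn = np.zeros(shape, dtype=bool)
    for _ in range(config.n_kernels):
        a = rng.uniform(*config.kernel_major)
        b = rng.uniform(*config.kernel_minor)
        theta = rng.uniform(0, np.pi)
        r0 = rng.uniform(0, H)
        c0 = rng.uniform(0, W)
        rows, cols = _ellipse_coords(r0, c0, a, b, theta, shape)
        if rows.size == 0:
            continue
        _paint(planes, corn, rows, cols, rng, config.kernel_h, config.kernel_s, config.kernel_v)
        if rng.uniform() < config.radicle_fraction:
            # pale radicle tip at one end of the major axis
            tr = r0 + 0.8 * a * np.sin(theta) * rng.choice([-1, 1])
            tc = c0 + 0.8 * a * np.cos(theta)
            rows, cols = _ellipse_coords(tr, tc, a * 0.3, b * 0.35, theta, shape)
            if rows.size:
                _paint(planes, corn, rows, cols, rng,
                       config.radicle_h, config.radicle_s, config.radicle_v)

    # impurities (never overlapping each other; painted over the bed)
    truth = np.zeros(shape, dtype=np.uint8)
    occupied: list[tuple[float, float, float, float]] = []
    objects: list[dict[str, Any]] = []

    for _ in range(config.n_bracts):
        target = int(rng.integers(*config.bract_area))
        local = _blob_mask(rng, target, _BRACT_WINDOW)
        r, c = _place_nonoverlapping(rng, shape, _BRACT_WINDOW, _BRACT_WINDOW, occupied)
        mask = np.zeros(shape, dtype=bool)
        top, left = int(r) - _BRACT_WINDOW, int(c) - _BRACT_WINDOW
        mask[top : top + local.shape[0], left : left + local.shape[1]] = local
        ys, xs = np.nonzero(mask)
        _paint(planes, mask, ys, xs, rng, config.bract_h, config.bract_s, config.bract_v)
        truth[mask] = BRACT
        objects.append(_object_record("bract", mask, planes))

    for _ in range(config.n_corncobs):
        length = rng.integers(*config.corncob_long)
        width = rng.integers(*config.corncob_short)
        theta = rng.uniform(0, np.pi)
        half = 0.5 * np.hypot(length, width)
        r, c = _place_nonoverlapping(rng, shape, half, half, occupied)
        yy, xx = np.mgrid[:H, :W]
        u = (xx - c) * np.cos(theta) + (yy - r) * np.sin(theta)
        w = -(xx - c) * np.sin(theta) + (yy - r) * np.cos(theta)
        mask = (np.abs(u) <= length / 2) & (np.abs(w) <= width / 2)
        ys, xs = np.nonzero(mask)
        _paint(planes, mask, ys, xs, rng, config.corncob_h, config.corncob_s, config.corncob_v)
        truth[mask] = CORNCOB
        objects.append(_object_record("corncob", mask, planes))

    for _ in range(config.n_stones):
        target = int(rng.integers(*config.stone_area))
        local = _small_blob(rng, target)
        half = local.shape[0] / 2 + config.stone_shadow
        r, c = _place_nonoverlapping(rng, shape, half, half, occupied)
        mask = np.zeros(shape, dtype=bool)
        top, left = int(r - local.shape[0] / 2), int(c - local.shape[1] / 2)
        mask[top : top + local.shape[0], left : left + local.shape[1]] = local
        # dark crevice ring: small stones settle between kernels
        ring = dilation(mask, disk(config.stone_shadow)) & ~mask
        ys, xs = np.nonzero(ring)
        _paint(planes, ring, ys, xs, rng,
               config.background_h, config.background_s, config.background_v)
        corn[ring] = False
        ys, xs = np.nonzero(mask)
        _paint(planes, mask, ys, xs, rng, config.stone_h, config.stone_s, config.stone_v)
        truth[mask] = STONE
        objects.append(_object_record("stone", mask, planes))

    corn &= truth == 0

    hsv = np.stack([hp, sp, vp], axis=2)
    image = np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)

    # truth is frozen here; degradations only touch the image
    tz = int(np.count_nonzero(truth))
    tw = int(np.count_nonzero(corn))
    pz = impurity_content(tz, tw, config.content_model).pz if tz + tw else 0.0
    manifest = {
        "objects": objects,
        "counts": {"tz": tz, "tw": tw},
        "truth_pz": pz,
        "seed": config.seed,
    }

    image = degrade(
        image,
        config.vignette_strength,
        config.dust_density,
        config.noise_sigma,
        seed=int(rng.integers(2**31)),
    )
    return SceneBundle(image=image, truth=truth, corn=corn, manifest=manifest, config=config)


def degrade(
    image: np.ndarray,
    vignette_strength: float = 0.0,
    dust_density: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Apply acquisition degradations to an image (labels unaffected).

    Vignette: multiplicative linear ramp from full brightness at the
    bottom-right corner down to ``1 - strength`` at the top-left. Dust:
    achromatic gray specks (radius-1 disks) at the given per-pixel
    density. Noise: clipped additive Gaussian, sigma in 8-bit units.
    With all three parameters zero the input is returned unchanged.
    """
    if min(vignette_strength, dust_density, noise_sigma) < 0:
        raise ParameterError("degradation parameters must be >= 0")
    if vignette_strength == dust_density == noise_sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    H, W = image.shape[:2]
    out = image.astype(np.float64)
    if vignette_strength > 0:
        ny = (H - 1 - np.arange(H)) / max(H - 1, 1)
        nx = (W - 1 - np.arange(W)) / max(W - 1, 1)
        t = (ny[:, None] + nx[None, :]) / 2.0  # 1 at top-left, 0 at bottom-right
        out *= (1.0 - vignette_strength * t)[:, :, None]
    if dust_density > 0:
        n_specks = rng.binomial(H * W, dust_density)
        ys = rng.integers(0, H, n_specks)
        xs = rng.integers(0, W, n_specks)
        speck = np.zeros((H, W), dtype=bool)
        speck[ys, xs] = True
        speck = dilation(speck, disk(1))
        out[speck] = rng.uniform(100, 180, size=(int(speck.sum()), 1))
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


#: named degradation presets for the CLI
PRESETS: dict[str, dict[str, float]] = {
    "clean": dict(vignette_strength=0.0, dust_density=0.0, noise_sigma=0.0),
    "vignette": dict(vignette_strength=0.5, dust_density=0.01, noise_sigma=0.0),
    "hard": dict(vignette_strength=0.6, dust_density=0.02, noise_sigma=4.0),
}


def preset_config(seed: int, preset: str = "clean", **overrides) -> SceneConfig:
    """SceneConfig for a named degradation preset."""
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return replace(SceneConfig(seed=seed), **PRESETS[preset], **overrides)
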