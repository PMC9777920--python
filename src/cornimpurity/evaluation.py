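"""Pixel-level evaluation and the impurity-content estimator.

Recognition quality is scored per class at the pixel level against
manually annotated (or synthetic ground-truth) masks:

* precision  Pa = Tp / (Tp + Fp) × 100%
* recall     Ra = Tp / (Tp + Fn) × 100%
* F1         F1 = 2 Pa Ra / (Pa + Ra)   (harmonic mean, in %)

Impurity content converts classified pixel counts into a mass fraction
using per-pixel mass densities measured by weighing annotated samples:

    Pz = rho_z * Tz / (rho_z * Tz + rho_w * Tw) × 100%

with Tz the impurity pixels (union of the three refined class masks),
Tw the remaining corn foreground pixels, and default densities
rho_w = 7.31e-3 mg/pixel (corn) and rho_z = 1.05e-3 mg/pixel
(impurities). Only the ratio rho_z / rho_w affects Pz.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .raster_io import CLASS_CODES, validate_labels, validate_mask

__all__ = [
    "EvalCounts",
    "EvalResult",
    "ContentModel",
    "ContentResult",
    "ClassReport",
    "count_pixels",
    "f1_score",
    "precision_recall_f1",
    "impurity_content",
    "evaluate_labelmap",
    "report_to_frame",
]


@dataclass(frozen=True)
class EvalCounts:
    """Pixel confusion counts: Tp correctly identified, Fp incorrectly
    identified, Fn missed. Tp + Fn equals the ground-truth positives."""

    tp: int
    fp: int
    fn: int

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class EvalResult:
    """Precision, recall and F1, all as percentages in [0, 100]."""

    pa: float
    ra: float
    f1: float


@dataclass(frozen=True)
class ContentModel:
    """Per-pixel mass densities (mg/pixel) used to weight pixel counts."""

    rho_w: float = 7.31e-3  # corn kernels
    rho_z: float = 1.05e-3  # impurities

    def __post_init__(self) -> None:
        if self.rho_w <= 0 or self.rho_z <= 0:
            raise ParameterError("densities must be positive")


@dataclass(frozen=True)
class ContentResult:
    """Impurity pixel count, corn pixel count, and the content estimate."""

    tz: int
    tw: int
    pz: float


@dataclass(frozen=True)
class ClassReport:
    """Per-class evaluation row: counts, scores and whether the class
    occurs at all (in truth or prediction)."""

    name: str
    counts: EvalCounts
    result: EvalResult
    present: bool


def count_pixels(predicted: np.ndarray, truth: np.ndarray) -> EvalCounts:
    """Confusion counts of a predicted mask against a ground-truth mask."""
    validate_mask(predicted)
    validate_mask(truth, predicted.shape)
    tp = int(np.count_nonzero(predicted & truth))
    fp = int(np.count_nonzero(predicted & ~truth))
    fn = int(np.count_nonzero(~predicted & truth))
    return EvalCounts(tp, fp, fn)


def f1_score(pa: float, ra: float) -> float:
    """Harmonic mean of precision and recall percentages (0/0 -> 0)."""
    if pa + ra == 0:
        return 0.0
    return 2.0 * pa * ra / (pa + ra)


def precision_recall_f1(counts: EvalCounts) -> EvalResult:
    """Scores from confusion counts; every 0/0 is defined as 0."""
    pa = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    ra = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return EvalResult(pa=pa, ra=ra, f1=f1_score(pa, ra))


def impurity_content(tz: int, tw: int, model: ContentModel | None = None) -> ContentResult:
    """Mass-weighted impurity content from classified pixel counts."""
    model = model or ContentModel()
    if tz < 0 or tw < 0:
        raise ValueError("pixel counts must be non-negative")
    if tz + tw == 0:
        raise ValueError("no classified pixels: impurity content undefined")
    mass_z = model.rho_z * tz
    mass_w = model.rho_w * tw
    return ContentResult(tz=int(tz), tw=int(tw), pz=100.0 * mass_z / (mass_z + mass_w))


def evaluate_labelmap(predicted: np.ndarray, truth: np.ndarray) -> list[ClassReport]:
    """One-vs-rest evaluation of each impurity class plus a micro-average.

    The micro-average pools the three classes' pixel counts before
    computing scores. A class absent from both truth and prediction is
    reported with zero scores and ``present=False``.
    """
    validate_labels(predicted)
    validate_labels(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    reports: list[ClassReport] = []
    pooled = EvalCounts(0, 0, 0)
    for name, code in CLASS_CODES.items():
        counts = count_pixels(predicted == code, truth == code)
        pooled = pooled + counts
        present = (counts.tp + counts.fp + counts.fn) > 0
        reports.append(ClassReport(name, counts, precision_recall_f1(counts), present))
    reports.append(ClassReport("micro", pooled, precision_recall_f1(pooled), True))
    return reports


def report_to_frame(reports: list[ClassReport]) -> pd.DataFrame:
    """Evaluation rows as a table with Pa/Ra/F1 rounded to 2 decimals
    (full precision stays available on the dataclasses)."""
    rows = []
    for r in reports:
        row = {"class": r.name, **asdict(r.counts)}
        row.update({k: round(v, 2) for k, v in asdict(r.result).items()})
        row["present"] = r.present
        rows.append(row)
    return pd.DataFrame(rows)
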