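"""End-to-end orchestration: enhance → binarize → classify → quantify,
for single images and batches, with optional evaluation against truth
label maps.

Batch evaluation pools raw pixel counts over all images before computing
precision/recall/F1 (micro-average); a per-image macro-average is also
reported, since the two can differ when image difficulty varies.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .classification import classify_detailed
from .config import PipelineConfig
from .evaluation import (
    EvalCounts,
    count_pixels,
    impurity_content,
    precision_recall_f1,
)
from .raster_io import (
    CLASS_CODES,
    read_image,
    read_mask,
    write_image,
    write_manifest,
    write_mask,
)

__all__ = ["quantify_labels", "run_pipeline", "run_batch"]

logger = logging.getLogger("cornimpurity")


def quantify_labels(
    labels: np.ndarray, binary: np.ndarray, config: PipelineConfig
) -> dict[str, Any]:
    """Impurity content from a label map and the Otsu foreground.

    Tz is the union of the three impurity classes; Tw is the remaining
    foreground (corn). Returns counts, per-class pixel counts and the
    content percentage (2-decimal presentation, full precision kept).
    """
    impurity = labels > 0
    tz = int(np.count_nonzero(impurity))
    tw = int(np.count_nonzero(binary & ~impurity))
    content = impurity_content(tz, tw, config.content)
    return {
        "counts": {
            "tz": tz,
            "tw": tw,
            **{name: int(np.count_nonzero(labels == code)) for name, code in CLASS_CODES.items()},
        },
        "impurity_content_percent": round(content.pz, 2),
        "impurity_content_percent_full": content.pz,
    }


def run_pipeline(
    image_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Process one photograph; optionally write all stage outputs.

    When *out_dir* is given, writes ``enhanced.png``, ``binary.png``,
    ``labels.png`` and ``content.json`` there. Returns the manifest.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    image = read_image(image_path)
    art = classify_detailed(image, config.classifier)
    manifest = quantify_labels(art.labels, art.binary, config)
    manifest["image"] = str(image_path)
    elapsed = time.perf_counter() - t0
    logger.info(
        "%s: %s in %.2fs", image_path,
        {k: v for k, v in manifest["counts"].items()}, elapsed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image(art.enhanced, out / "enhanced.png")
        write_mask(art.binary, out / "binary.png")
        write_mask(art.labels, out / "labels.png")
        write_manifest(manifest, out / "content.json")
    return manifest


_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def run_batch(
    image_dir: str | Path,
    config: PipelineConfig | None = None,
    truth_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Process a directory of images; evaluate when truth maps exist.

    Truth label maps are matched by stem: ``<truth_dir>/<stem>.png``.
    Returns a per-image table and a summary with pooled (micro) and
    per-image-averaged (macro) scores per class.
    """
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    rows: list[dict[str, Any]] = []
    pooled: dict[str, EvalCounts] = {n: EvalCounts(0, 0, 0) for n in CLASS_CODES}
    per_image_f1: dict[str, list[float]] = {n: [] for n in CLASS_CODES}
    evaluated = 0

    for path in paths:
        image = read_image(path)
        art = classify_detailed(image, config.classifier)
        manifest = quantify_labels(art.labels, art.binary, config)
        row: dict[str, Any] = {
            "image": path.name,
            "pz": manifest["impurity_content_percent_full"],
            **manifest["counts"],
        }
        if truth_dir is not None:
            truth_path = Path(truth_dir) / f"{path.stem}.png"
            if not truth_path.exists():
                logger.warning("no truth map for %s; skipped from evaluation", path.name)
            else:
                truth = read_mask(truth_path, as_labels=True)
                evaluated += 1
                for name, code in CLASS_CODES.items():
                    counts = count_pixels(art.labels == code, truth == code)
                    pooled[name] = pooled[name] + counts
                    row[f"{name}_f1"] = precision_recall_f1(counts).f1
                    per_image_f1[name].append(row[f"{name}_f1"])
        rows.append(row)

    summary: dict[str, Any] = {"n_images": len(paths), "n_evaluated": evaluated}
    if evaluated:
        for name in CLASS_CODES:
            res = precision_recall_f1(pooled[name])
            summary[name] = {
                "pa": res.pa,
                "ra": res.ra,
                "f1": res.f1,
                "f1_macro": float(np.mean(per_image_f1[name])),
            }
    return pd.DataFrame(rows), summary
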