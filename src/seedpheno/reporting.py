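"""Per-image summaries, annotated images, reproducibility and extraction.

The batch entry point :func:`run_predict` mirrors how populations of
seed images are scored in practice: every image in a directory is
preprocessed, segmented, described and classified, and the results are
written as an annotated PNG per image, a long-form per-seed parameter
CSV, and a per-image summary spreadsheet (XLSX for users, plus a CSV
twin with identical values for pipelines).

Reproducibility of repeated imaging of the same population is scored as
1 - CV, where CV is the standard deviation of the per-image counts
divided by their mean; categories averaging 10 seeds or fewer per image
are flagged as excluded to avoid unstable ratios.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from openpyxl import Workbook
from PIL import Image, ImageDraw

from .annotations import SeedClass
from .classifier import ClassifiedSeed, ModelBundle, load_bundle, predict
from .features import DESCRIPTOR_NAMES
from .imaging import CalibratedImage, load_image, SUPPORTED_EXTENSIONS
from .pipeline import PipelineConfig, process_image
from .segmentation import SegmentMask

__all__ = [
    "ImageSummary",
    "ReproRecord",
    "CLASS_PALETTE",
    "summarize",
    "reproducibility",
    "annotate_image",
    "extract_fields",
    "run_predict",
]

log = logging.getLogger(__name__)

#: Fixed annotation palette: normal = green, partial = orange, full = red.
CLASS_PALETTE: dict[SeedClass, tuple[int, int, int]] = {
    SeedClass.NORMAL: (0, 180, 0),
    SeedClass.PARTIAL: (255, 150, 0),
    SeedClass.FULL: (220, 0, 0),
}


@dataclass(frozen=True)
class ImageSummary:
    """Per-image class counts, percentages and mean prediction confidence."""

    image_id: str
    total_seeds: int
    count_normal: int
    count_partial: int
    count_full: int
    pct_normal: float
    pct_partial: float
    pct_full: float
    mean_confidence: float
    processing_seconds: float
    empty: bool = False


@dataclass(frozen=True)
class ReproRecord:
    """Reproducibility (1 - CV) of one category's counts in one population."""

    population_id: str
    category: str  # total | normal | partial | full
    mean: float
    sd: float
    cv: float
    reproducibility: float
    included: bool


def summarize(
    classified: list[ClassifiedSeed], image_id: str, elapsed: float = 0.0
) -> ImageSummary:
    """Aggregate per-seed predictions into one summary row."""
    total = len(classified)
    counts = {c: 0 for c in SeedClass}
    for seed in classified:
        counts[seed.category] += 1
    if total == 0:
        log.warning("image %s: no seeds detected", image_id)
        pcts = (0.0, 0.0, 0.0)
        mean_conf = 0.0
    else:
        pcts = tuple(100.0 * counts[c] / total for c in SeedClass)
        mean_conf = float(np.mean([s.confidence for s in classified]))
    return ImageSummary(
        image_id=image_id,
        total_seeds=total,
        count_normal=counts[SeedClass.NORMAL],
        count_partial=counts[SeedClass.PARTIAL],
        count_full=counts[SeedClass.FULL],
        pct_normal=pcts[0],
        pct_partial=pcts[1],
        pct_full=pcts[2],
        mean_confidence=mean_conf,
        processing_seconds=float(elapsed),
        empty=total == 0,
    )


def reproducibility(counts_by_image: pd.DataFrame) -> list[ReproRecord]:
    """Per-population, per-category 1 - CV across repeated images.

    ``counts_by_image`` needs columns ``population_id``, ``image_id``,
    ``normal``, ``partial``, ``full``; a ``total`` column is derived.
    Populations with fewer than two images are skipped with a warning.
    """
    required = {"population_id", "image_id", "normal", "partial", "full"}
    missing = required - set(counts_by_image.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    df = counts_by_image.copy()
    df["total"] = df["normal"] + df["partial"] + df["full"]
    records: list[ReproRecord] = []
    for pop, group in df.groupby("population_id", sort=True):
        if len(group) < 2:
            log.warning("population %s has %d image(s); skipped", pop, len(group))
            continue
        for cat in ("total", "normal", "partial", "full"):
            vals = group[cat].to_numpy(dtype=np.float64)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            cv = sd / mean if mean > 0 else float("nan")
            records.append(
                ReproRecord(
                    population_id=str(pop),
                    category=cat,
                    mean=mean,
                    sd=sd,
                    cv=cv,
                    reproducibility=1.0 - cv if np.isfinite(cv) else float("nan"),
                    included=mean > 10,
                )
            )
    return records


def annotate_image(
    img: CalibratedImage,
    masks: list[SegmentMask],
    classified: list[ClassifiedSeed],
) -> np.ndarray:
    """Draw each seed's contour in its class colour plus its index.

    Pixels outside the drawn contours and index text are left untouched;
    with no seeds the output equals the input.
    """
    canvas = Image.fromarray(img.pixels.copy())
    if not masks:
        return np.asarray(canvas)
    draw = ImageDraw.Draw(canvas)
    by_index = {c.seed_index: c for c in classified}
    for m in masks:
        cls = by_index.get(m.seed_index)
        colour = CLASS_PALETTE[cls.category] if cls else (128, 128, 128)
        pts = [(float(x), float(y)) for x, y in m.contour]
        draw.line(pts + [pts[0]], fill=colour, width=2)
        x0, y0 = m.bbox[0], m.bbox[1]
        draw.text((x0, max(0, y0 - 10)), str(m.seed_index), fill=colour)
    return np.asarray(canvas)


def extract_fields(
    parameters_table: pd.DataFrame,
    fields: list[str],
    um_per_px: float | None = None,
) -> pd.DataFrame:
    """Narrow a per-seed parameter table to selected descriptors.

    ``area_mm2`` may be requested when the pixel calibration is known:
    ``area_mm2 = area_px * (um_per_px / 1000)^2``.
    """
    valid = set(DESCRIPTOR_NAMES) | {"area_mm2"}
    unknown = [f for f in fields if f not in valid]
    if unknown:
        raise ValueError(
            f"unknown field(s) {unknown}; valid names are the 38 canonical "
            f"descriptors plus 'area_mm2'"
        )
    out = {}
    for f in fields:
        if f == "area_mm2":
            if um_per_px is None:
                raise ValueError("area_mm2 requires a um_per_px calibration")
            out[f] = parameters_table["area_px"] * (um_per_px / 1000.0) ** 2
        else:
            out[f] = parameters_table[f]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Batch prediction
# ---------------------------------------------------------------------------

def _find_images(in_dir: str) -> list[str]:
    names = sorted(os.listdir(in_dir))
    return [
        os.path.join(in_dir, n)
        for n in names
        if os.path.splitext(n)[1].lower() in SUPPORTED_EXTENSIONS
    ]


def _summary_frame(summaries: list[ImageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": s.image_id,
                "total_seeds": s.total_seeds,
                "count_normal": s.count_normal,
                "count_partial": s.count_partial,
                "count_full": s.count_full,
                "pct_normal": s.pct_normal,
                "pct_partial": s.pct_partial,
                "pct_full": s.pct_full,
                "mean_confidence": s.mean_confidence,
                "processing_seconds": s.processing_seconds,
            }
            for s in summaries
        ]
    )


def _write_summary_xlsx(df: pd.DataFrame, path: str) -> None:
    wb = Workbook()
    ws = wb.active
    ws.title = "seed_summary"
    ws.append(list(df.columns))
    for row in df.itertuples(index=False):
        ws.append(list(row))
    wb.save(path)


def run_predict(
    in_dir: str | os.PathLike,
    model_path: str | os.PathLike | ModelBundle,
    cfg: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> int:
    """Score every image in a directory with a trained model.

    Writes ``out/predicted_images/<id>.png``, ``out/seed_parameters.csv``
    (one row per seed: ids, provenance, the 38 descriptors, predicted
    class, probabilities and confidence), and ``out/seed_summary.xlsx``
    plus a value-identical ``seed_summary.csv``.  Per-image failures are
    logged and skipped; the exit status is 0 only if every image
    processed cleanly.
    """
    cfg = cfg or PipelineConfig()
    in_dir = os.fspath(in_dir)
    out_dir = os.fspath(out_dir) if out_dir is not None else os.path.join(in_dir, "out")
    images = _find_images(in_dir)
    if not images:
        raise FileNotFoundError(f"no readable images in {in_dir}")
    bundle = model_path if isinstance(model_path, ModelBundle) else load_bundle(model_path)
    pred_dir = os.path.join(out_dir, "predicted_images")
    os.makedirs(pred_dir, exist_ok=True)

    param_rows: list[dict] = []
    summaries: list[ImageSummary] = []
    status = 0
    for path in images:
        t0 = time.monotonic()
        try:
            img = load_image(path, um_per_px=cfg.um_per_px)
            pre, masks, feats = process_image(img, cfg)
            classified = predict(bundle, feats)
            by_index = {c.seed_index: c for c in classified}
            mask_by_index = {m.seed_index: m for m in masks}
            for f in feats:
                c = by_index[f.seed_index]
                row = {
                    "image_id": f.image_id,
                    "seed_index": f.seed_index,
                    "provenance": mask_by_index[f.seed_index].provenance,
                }
                row.update(f.as_dict())
                if cfg.um_per_px is not None:
                    row["area_mm2"] = f["area_px"] * (cfg.um_per_px / 1000.0) ** 2
                row.update(
                    {
                        "predicted_class": c.category.label,
                        "p_normal": c.probabilities[0],
                        "p_partial": c.probabilities[1],
                        "p_full": c.probabilities[2],
                        "confidence": c.confidence,
                    }
                )
                param_rows.append(row)
            annotated = annotate_image(img, masks, classified)
            Image.fromarray(annotated).save(
                os.path.join(pred_dir, f"{img.source_id}.png")
            )
            summaries.append(
                summarize(classified, img.source_id, time.monotonic() - t0)
            )
        except Exception:
            log.exception("failed to process image %s; skipped", path)
            status = 1
    pd.DataFrame(param_rows).to_csv(
        os.path.join(out_dir, "seed_parameters.csv"), index=False
    )
    summary_df = _summary_frame(summaries)
    summary_df.to_csv(os.path.join(out_dir, "seed_summary.csv"), index=False)
    _write_summary_xlsx(summary_df, os.path.join(out_dir, "seed_summary.xlsx"))
    return status
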