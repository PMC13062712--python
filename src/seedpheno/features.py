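"""Per-seed descriptor extraction: 21 colour, 9 shape, 5 texture, 3 position.

Every segmented seed is summarised as an ordered record of 38 values
(:data:`DESCRIPTOR_NAMES`).  Colour statistics are computed on
background-normalized pixels so they are comparable across lighting
conditions; shape descriptors include the overlap ratio — the
intersection-over-union between the seed mask and the ellipse fitted to
it — which is close to 1 for plump regular seeds and drops for
collapsed, shrivelled ones; texture is summarised by five standard
grey-level co-occurrence (Haralick-type) properties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from skimage import color as skcolor
from skimage import feature as skfeature
from skimage import measure as skmeasure

from .imaging import PreprocessedImage
from .segmentation import SegmentMask

__all__ = [
    "DESCRIPTOR_NAMES",
    "DESCRIPTOR_GROUPS",
    "SeedDescriptors",
    "FittedEllipse",
    "fit_ellipse",
    "rasterize_ellipse",
    "overlap_ratio",
    "glcm_features",
    "compute_descriptors",
]

log = logging.getLogger(__name__)

#: Canonical, ordered descriptor names; this exact order is the
#: ``seed_parameters.csv`` header and is serialized into model bundles.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    # --- colour (21) ---
    "mean_r", "std_r", "median_r",
    "mean_g", "std_g", "median_g",
    "mean_b", "std_b", "median_b",
    "mean_h", "std_h",
    "mean_s", "std_s",
    "mean_v", "std_v",
    "mean_grey", "std_grey", "median_grey",
    "mean_lab_l", "mean_lab_a", "mean_lab_b",
    # --- shape (9) ---
    "area_px", "perimeter_px", "eccentricity", "solidity", "overlap_ratio",
    "circularity", "aspect_ratio", "extent", "convexity",
    # --- texture (5) ---
    "glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity",
    "glcm_energy", "glcm_correlation",
    # --- position (3) ---
    "centroid_x", "centroid_y", "nn_distance",
)

DESCRIPTOR_GROUPS: dict[str, tuple[int, int]] = {
    "color": (0, 21),
    "shape": (21, 30),
    "texture": (30, 35),
    "position": (35, 38),
}

assert len(DESCRIPTOR_NAMES) == 38

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class SeedDescriptors:
    """The ordered 38-value descriptor record for one segmented seed."""

    image_id: str
    seed_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (38,):
            raise ValueError(f"expected 38 descriptor values, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("descriptor values must be finite")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return float(self.values[DESCRIPTOR_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DESCRIPTOR_NAMES, map(float, self.values)))


@dataclass(frozen=True)
class FittedEllipse:
    """Moment-matched ellipse: centre, semi-axes (px) and orientation.

    ``theta`` is the major-axis angle in radians, measured from the +x
    axis toward +y (image frame, y down), normalized to [0, pi).
    """

    cx: float
    cy: float
    major: float
    minor: float
    theta: float
    degenerate: bool = False


def fit_ellipse(mask: SegmentMask) -> FittedEllipse:
    """Fit the ellipse with the mask's centroid and second central moments.

    A uniform ellipse with semi-axes (a, b) has coordinate variances
    (a^2/4, b^2/4) along its principal axes, so semi-axes are recovered
    as twice the square roots of the covariance eigenvalues.
    """
    if mask.area_px < 5:
        raise ValueError("ellipse fit needs at least 5 pixels")
    ys, xs = np.nonzero(mask.local_mask)
    x = xs + mask.bbox[0]
    y = ys + mask.bbox[1]
    cx, cy = float(x.mean()), float(y.mean())
    dx, dy = x - cx, y - cy
    sxx = float(np.mean(dx * dx))
    syy = float(np.mean(dy * dy))
    sxy = float(np.mean(dx * dy))
    common = math.sqrt(((sxx - syy) / 2.0) ** 2 + sxy * sxy)
    lam1 = (sxx + syy) / 2.0 + common
    lam2 = (sxx + syy) / 2.0 - common
    major = 2.0 * math.sqrt(max(lam1, 0.0))
    minor = 2.0 * math.sqrt(max(lam2, 0.0))
    theta = 0.5 * math.atan2(2.0 * sxy, sxx - syy) % math.pi
    degenerate = False
    if minor < 0.5:
        minor = 0.5
        degenerate = True
        log.warning("degenerate mask at (%.1f, %.1f): minor axis clamped", cx, cy)
    return FittedEllipse(cx=cx, cy=cy, major=major, minor=minor, theta=theta,
                         degenerate=degenerate)


def rasterize_ellipse(ell: FittedEllipse, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean raster of pixel centres inside the ellipse, over a bbox."""
    x0, y0, x1, y1 = bbox
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - ell.cx
    dy = yy - ell.cy
    ct, st = math.cos(ell.theta), math.sin(ell.theta)
    u = (dx * ct + dy * st) / ell.major
    v = (-dx * st + dy * ct) / ell.minor
    return u * u + v * v <= 1.0


def overlap_ratio(mask: SegmentMask, ell: FittedEllipse | None = None) -> float:
    """IoU between the seed mask and its fitted ellipse, in [0, 1]."""
    if ell is None:
        ell = fit_ellipse(mask)
    r = math.ceil(ell.major) + 2
    x0 = min(mask.bbox[0], int(math.floor(ell.cx - r)))
    y0 = min(mask.bbox[1], int(math.floor(ell.cy - r)))
    x1 = max(mask.bbox[2], int(math.ceil(ell.cx + r)) + 1)
    y1 = max(mask.bbox[3], int(math.ceil(ell.cy + r)) + 1)
    ell_r = rasterize_ellipse(ell, (x0, y0, x1, y1))
    m = np.zeros_like(ell_r)
    m[mask.bbox[1] - y0 : mask.bbox[3] - y0,
      mask.bbox[0] - x0 : mask.bbox[2] - x0] = mask.local_mask
    inter = int(np.logical_and(m, ell_r).sum())
    union = int(np.logical_or(m, ell_r).sum())
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Texture
# ---------------------------------------------------------------------------

def glcm_matrices(grey_crop: np.ndarray, local_mask: np.ndarray,
                  levels: int = GLCM_LEVELS) -> list[np.ndarray]:
    """Masked, symmetrized, normalized co-occurrence matrix per angle.

    Grey values under the mask are quantized to ``levels`` bins by fixed
    binning (256/levels wide); pixels outside the mask are assigned a
    sentinel level so that only pairs with *both* pixels inside the mask
    are counted, at distance 1 for angles 0/45/90/135 degrees.  Angles
    with no valid pair yield an empty (all-zero) matrix.
    """
    q = (grey_crop.astype(np.int64) * levels // 256).astype(np.uint8)
    q = np.where(local_mask, q, levels)  # sentinel for out-of-mask
    raw = skfeature.graycomatrix(
        q, distances=[1], angles=list(GLCM_ANGLES),
        levels=levels + 1, symmetric=False, normed=False,
    )
    mats = []
    for a in range(len(GLCM_ANGLES)):
        p = raw[:levels, :levels, 0, a].astype(np.float64)
        p = p + p.T
        total = p.sum()
        mats.append(p / total if total > 0 else p)
    return mats


def _glcm_props(p: np.ndarray) -> tuple[float, float, float, float, float]:
    levels = p.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    diff = (i - j).astype(np.float64)
    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    energy = float(np.sqrt((p**2).sum()))
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0  # zero-variance convention
    else:
        cov = float((p * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / math.sqrt(var_i * var_j)
    return contrast, dissimilarity, homogeneity, energy, correlation


def glcm_features(grey_crop: np.ndarray, mask: SegmentMask) -> np.ndarray:
    """Contrast, dissimilarity, homogeneity, energy, correlation (angle-averaged)."""
    if mask.area_px < 16:
        raise ValueError("texture features need a mask of at least 16 px")
    mats = [m for m in glcm_matrices(grey_crop, mask.local_mask) if m.sum() > 0]
    if not mats:
        log.warning("no in-mask pixel pairs; constant-texture convention used")
        return np.array([0.0, 0.0, 1.0, 1.0, 0.0])
    props = np.array([_glcm_props(p) for p in mats])
    return props.mean(axis=0)


# ---------------------------------------------------------------------------
# Full record
# ---------------------------------------------------------------------------

def _colour_stats(rgb_crop: np.ndarray, local_mask: np.ndarray,
                  grey_crop: np.ndarray) -> list[float]:
    px = rgb_crop[local_mask].astype(np.float64)  # (n, 3)
    out: list[float] = []
    for ch in range(3):
        v = px[:, ch]
        out += [float(v.mean()), float(v.std()), float(np.median(v))]
    hsv = skcolor.rgb2hsv(rgb_crop.astype(np.float64) / 255.0)[local_mask]
    for ch in range(3):
        v = hsv[:, ch]
        out += [float(v.mean()), float(v.std())]
    g = grey_crop[local_mask].astype(np.float64)
    out += [float(g.mean()), float(g.std()), float(np.median(g))]
    lab = skcolor.rgb2lab(rgb_crop.astype(np.float64) / 255.0)[local_mask]
    out += [float(lab[:, 0].mean()), float(lab[:, 1].mean()), float(lab[:, 2].mean())]
    return out


def _shape_stats(mask: SegmentMask) -> list[float]:
    props = skmeasure.regionprops(mask.local_mask.astype(np.uint8))[0]
    area = float(mask.area_px)
    perimeter = float(props.perimeter)
    ell = fit_ellipse(mask)
    ov = overlap_ratio(mask, ell)
    circ = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 1.0
    circ = min(circ, 1.1)  # discretization slack cap for tiny round masks
    aspect = ell.major / ell.minor
    hull_perimeter = float(
        skmeasure.regionprops(props.image_convex.astype(np.uint8))[0].perimeter
    )
    convexity = hull_perimeter / perimeter if perimeter > 0 else 1.0
    return [
        area, perimeter, float(props.eccentricity), float(props.solidity),
        ov, circ, aspect, float(props.extent), convexity,
    ]


def _single_record(pre: PreprocessedImage, mask: SegmentMask) -> np.ndarray | None:
    x0, y0, x1, y1 = mask.bbox
    h, w = pre.grey.shape
    if x0 >= w or y0 >= h or x1 <= 0 or y1 <= 0 or mask.area_px == 0:
        log.warning("mask %d empty after boundary clip; skipped", mask.seed_index)
        return None
    rgb_crop = pre.normalized_rgb[y0:y1, x0:x1]
    grey_crop = pre.grey[y0:y1, x0:x1]
    colour = _colour_stats(rgb_crop, mask.local_mask, grey_crop)
    shape = _shape_stats(mask)
    texture = list(glcm_features(grey_crop, mask))
    cx, cy = mask.centroid
    return np.array(colour + shape + texture + [cx, cy, 0.0], dtype=np.float64)


def compute_descriptors(
    pre: PreprocessedImage,
    masks: list[SegmentMask],
    n_jobs: int = 1,
) -> list[SeedDescriptors]:
    """One 38-value record per mask, in seed-index order.

    Nearest-neighbour distance is computed between final mask centroids;
    with a single seed it is set to the image diagonal (flagged in the
    log).  ``n_jobs`` parallelizes per-seed extraction over threads;
    parallel and serial runs produce identical values.
    """
    masks = sorted(masks, key=lambda m: m.seed_index)
    if n_jobs == 1:
        rows = [_single_record(pre, m) for m in masks]
    else:
        rows = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_single_record)(pre, m) for m in masks
        )
    kept = [(m, r) for m, r in zip(masks, rows) if r is not None]
    if not kept:
        return []
    cents = np.array([[r[35], r[36]] for _, r in kept])
    nn_idx = DESCRIPTOR_NAMES.index("nn_distance")
    if len(kept) == 1:
        diag = math.hypot(pre.height, pre.width)
        log.warning("single seed in %s: nn_distance set to image diagonal",
                    pre.source.source_id)
        kept[0][1][nn_idx] = diag
    else:
        d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(d2.min(axis=1))
        for (_, r), d in zip(kept, nn):
            r[nn_idx] = float(d)
    return [
        SeedDescriptors(image_id=pre.source.source_id, seed_index=m.seed_index,
                        values=r)
        for m, r in kept
    ]
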