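"""Hybrid instance segmentation of seed scenes.

Dispersed seeds on white paper are separated by global Otsu thresholding
plus Canny edge subtraction; foreground components that look like fused
clusters (too large, or too concave, relative to a robust per-image
reference seed area) are routed to a dense-region backend that splits
them into individual seeds.  Two backends honour the same contract: a
marker-controlled watershed on the distance transform, and an adapter
for promptable automatic mask generation (Segment Anything), selected
by configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg

from .imaging import PreprocessedImage

__all__ = [
    "SegmentMask",
    "RegionPartition",
    "DenseBackendConfig",
    "BackendUnavailableError",
    "otsu_threshold",
    "extract_foreground",
    "partition_regions",
    "split_cluster",
    "segment_image",
    "trace_contour",
]

log = logging.getLogger(__name__)

PROVENANCE_THRESHOLD = "threshold"
PROVENANCE_DENSE = "dense_backend"


class BackendUnavailableError(RuntimeError):
    """The selected dense backend cannot run (e.g. SAM weights absent)."""


@dataclass(frozen=True)
class DenseBackendConfig:
    """Configuration of the dense-region (cluster-splitting) backend."""

    backend: str = "watershed"
    points_per_side: int = 49
    pred_iou_thresh: float = 0.86
    nms_iou: float = 0.3

    def __post_init__(self) -> None:
        if self.backend not in ("watershed", "sam"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if not 0 < self.pred_iou_thresh < 1:
            raise ValueError("pred_iou_thresh must be in (0,1)")
        if not 0 < self.nms_iou < 1:
            raise ValueError("nms_iou must be in (0,1)")


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(histogram: np.ndarray) -> tuple[int, bool]:
    """Between-class-variance-maximizing split of a 256-bin histogram.

    The low class is ``bins <= t``; ties break toward the lowest ``t``.
    Returns ``(threshold, degenerate)`` where *degenerate* flags a
    single-valued histogram (threshold = that bin).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    total = hist.sum()
    if total == 0:
        raise ValueError("histogram is empty")
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0]), True

    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                       # weight of class <= t
    m0 = np.cumsum(hist * levels)              # unnormalized mean
    w1 = total - w0
    mu_total = m0[-1]
    # between-class variance w0*w1*(mu0-mu1)^2; guard empty classes
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    sigma_b[255] = -np.inf  # t=255 puts everything in one class
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    if not np.isfinite(sigma_b[best]):
        # all mass at the extremes with no valid split: lowest t wins
        best = 0
    return best, False


# ---------------------------------------------------------------------------
# Mask container and exact contour tracing
# ---------------------------------------------------------------------------

def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a filled 4-connected mask.

    Returns a closed polygon of (x, y) vertices lying on pixel corners
    (half-integer coordinates), oriented so that rasterizing it with
    "pixel centre inside polygon" reproduces the mask exactly.  The mask
    must be hole-free; diagonal pinch points are resolved by always
    taking the sharpest right turn, which keeps the interior on a
    consistent side.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no contour")
    pad = np.pad(mask, 1)
    rows, cols = np.nonzero(pad)
    # directed crack edges, clockwise in array view (interior on the right)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(r0: int, c0: int, r1: int, c1: int) -> None:
        edges.setdefault((r0, c0), []).append((r1, c1))

    up = ~pad[rows - 1, cols]
    down = ~pad[rows + 1, cols]
    left = ~pad[rows, cols - 1]
    right = ~pad[rows, cols + 1]
    # vertices in doubled coordinates: corner (r-1/2, c-1/2) -> (2r-1, 2c-1)
    for r, c, u, d, l, rt in zip(rows, cols, up, down, left, right):
        if u:
            add(2 * r - 1, 2 * c - 1, 2 * r - 1, 2 * c + 1)
        if rt:
            add(2 * r - 1, 2 * c + 1, 2 * r + 1, 2 * c + 1)
        if d:
            add(2 * r + 1, 2 * c + 1, 2 * r + 1, 2 * c - 1)
        if l:
            add(2 * r + 1, 2 * c - 1, 2 * r - 1, 2 * c - 1)

    start = min(edges)
    path = [start]
    prev_dir: tuple[int, int] | None = None
    current = start
    while True:
        candidates = edges[current]
        if len(candidates) == 1 or prev_dir is None:
            nxt = candidates[0]
        else:
            # sharpest right turn relative to the incoming direction
            def turn(cand: tuple[int, int]) -> int:
                d = (cand[0] - current[0], cand[1] - current[1])
                cross = prev_dir[0] * d[1] - prev_dir[1] * d[0]
                return -cross  # clockwise orientation: right turn has cross < 0
            nxt = min(candidates, key=turn)
        candidates.remove(nxt)
        if not candidates:
            del edges[current]
        prev_dir = (nxt[0] - current[0], nxt[1] - current[1])
        current = nxt
        if current == start:
            break
        path.append(current)
    # doubled padded coords -> image-frame (x, y)
    verts = np.asarray(path, dtype=np.float64)
    ys = (verts[:, 0] - 2) / 2.0
    xs = (verts[:, 1] - 2) / 2.0
    return np.column_stack([xs, ys])


@dataclass(frozen=True)
class SegmentMask:
    """One candidate seed instance.

    The binary mask is stored as a tight bounding box plus a local mask;
    ``bbox`` is half-open ``(x0, y0, x1, y1)`` in image coordinates
    (x = column, y = row, 0-based).
    """

    bbox: tuple[int, int, int, int]
    local_mask: np.ndarray
    contour: np.ndarray
    provenance: str
    quality: float = 1.0
    seed_index: int = -1

    @property
    def area_px(self) -> int:
        return int(self.local_mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid in image coordinates."""
        ys, xs = np.nonzero(self.local_mask)
        return (float(xs.mean()) + self.bbox[0], float(ys.mean()) + self.bbox[1])

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        x0, y0, x1, y1 = self.bbox
        out[y0:y1, x0:x1] = self.local_mask
        return out

    def iou(self, other: "SegmentMask") -> float:
        ax0, ay0, ax1, ay1 = self.bbox
        bx0, by0, bx1, by1 = other.bbox
        ix0, iy0 = max(ax0, bx0), max(ay0, by0)
        ix1, iy1 = min(ax1, bx1), min(ay1, by1)
        if ix0 >= ix1 or iy0 >= iy1:
            return 0.0
        a = self.local_mask[iy0 - ay0 : iy1 - ay0, ix0 - ax0 : ix1 - ax0]
        b = other.local_mask[iy0 - by0 : iy1 - by0, ix0 - bx0 : ix1 - bx0]
        inter = int(np.logical_and(a, b).sum())
        if inter == 0:
            return 0.0
        union = self.area_px + other.area_px - inter
        return inter / union


def mask_from_full(
    full: np.ndarray, provenance: str, quality: float = 1.0
) -> SegmentMask:
    """Build a SegmentMask from an image-frame boolean raster.

    Normalizes the raster to a single hole-free 4-connected component
    (largest piece kept) so that the traced contour is exact.
    """
    full = np.asarray(full, dtype=bool)
    labels, n = ndi.label(full, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        raise ValueError("cannot build a mask from an empty raster")
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        full = labels == (int(np.argmax(counts)) + 1)
    full = ndi.binary_fill_holes(full)
    ys, xs = np.nonzero(full)
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    local = full[y0:y1, x0:x1].copy()
    contour = trace_contour(local)
    contour = contour + np.array([x0, y0], dtype=np.float64)
    return SegmentMask(
        bbox=(x0, y0, x1, y1),
        local_mask=local,
        contour=contour,
        provenance=provenance,
        quality=float(quality),
    )


@dataclass
class RegionPartition:
    """Foreground components routed to the threshold or dense path."""

    singletons: list[SegmentMask]
    clusters: list[SegmentMask]
    reference_area: float


# ---------------------------------------------------------------------------
# Foreground extraction and routing
# ---------------------------------------------------------------------------

def extract_foreground(
    pre: PreprocessedImage,
    min_area: int = 100,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
) -> np.ndarray:
    """Binary seed foreground from the blurred luminance.

    Seeds are darker than the white paper, so foreground is the low
    class of an Otsu split of the blurred histogram.  Canny edge pixels
    are subtracted to break thin bridges between touching seeds; hole
    filling then restores edge cuts that do not reach the background,
    and a 3x3 opening removes slivers.  Components below ``min_area``
    pixels are dropped as debris.
    """
    hist = np.bincount(pre.blurred.ravel(), minlength=256)[:256]
    thr, degenerate = otsu_threshold(hist)
    if degenerate:
        log.warning("degenerate brightness histogram; empty foreground")
        return np.zeros(pre.blurred.shape, dtype=bool)
    fg = pre.blurred < thr
    # Canny runs on the grey with its own 1 px smoothing: the seam between
    # touching seeds is only ~1 px wide and survives less smoothing only
    edges = skfeature.canny(
        pre.grey.astype(np.float64) / 255.0,
        sigma=1.0,
        low_threshold=canny_low / 255.0,
        high_threshold=canny_high / 255.0,
    )
    raw = fg.copy()
    fg &= ~edges
    fg = ndi.binary_fill_holes(fg)
    fg = ndi.binary_opening(fg, structure=np.ones((3, 3), dtype=bool))
    labels, n = ndi.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
        # edge subtraction + opening shave ~1 px off every true boundary;
        # grow components back inside the raw threshold mask without letting
        # separated components re-merge (expansion stops at equidistance and
        # a contact band between different labels is kept clear)
        grown = skseg.expand_labels(labels, distance=1.5)
        grown[~raw] = 0
        inner = grown > 0
        contact = (
            skseg.find_boundaries(grown, mode="thick")
            & ~skseg.find_boundaries(inner, mode="thick")
            & inner
        )
        fg = inner & ~contact
    return fg


def _component_solidity(local: np.ndarray) -> float:
    props = skmeasure.regionprops(local.astype(np.uint8))
    return float(props[0].solidity) if props else 0.0


def partition_regions(
    foreground: np.ndarray,
    min_area: int = 100,
    cluster_area_factor: float = 1.6,
    cluster_solidity: float = 0.85,
) -> RegionPartition:
    """Split foreground components into singleton seeds and clusters.

    The reference seed area ``A_ref`` is the median area of compact
    components (solidity >= 0.90), falling back to the median of all
    components.  A component is routed to the dense backend iff its
    area exceeds ``cluster_area_factor * A_ref`` or its solidity falls
    below ``cluster_solidity``.
    """
    # 4-connectivity: seeds touching only diagonally are distinct components,
    # and every component survives mask normalization intact
    labels, n = ndi.label(
        foreground, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    comps: list[SegmentMask] = []
    solidities: list[float] = []
    for idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:  # pragma: no cover
            continue
        local = labels[sl] == idx
        area = int(local.sum())
        if area < min_area:
            log.debug("dropping %d px debris component", area)
            continue
        full = np.zeros(foreground.shape, dtype=bool)
        full[sl] = local
        comp = mask_from_full(full, PROVENANCE_THRESHOLD, quality=1.0)
        comps.append(comp)
        solidities.append(_component_solidity(comp.local_mask))
    if not comps:
        return RegionPartition(singletons=[], clusters=[], reference_area=0.0)
    areas = np.array([c.area_px for c in comps], dtype=np.float64)
    sol = np.array(solidities)
    compact = areas[sol >= 0.90]
    a_ref = float(np.median(compact) if compact.size else np.median(areas))
    singles, clusters = [], []
    for comp, s in zip(comps, sol):
        if comp.area_px > cluster_area_factor * a_ref or s < cluster_solidity:
            clusters.append(comp)
        else:
            singles.append(comp)
    return RegionPartition(singletons=singles, clusters=clusters, reference_area=a_ref)


# ---------------------------------------------------------------------------
# Dense backends
# ---------------------------------------------------------------------------

def _greedy_nms(masks: list[SegmentMask], iou_cap: float) -> list[SegmentMask]:
    """Keep masks greedily by descending quality, rejecting IoU > cap."""
    kept: list[SegmentMask] = []
    for m in sorted(masks, key=lambda m: (-m.quality, m.bbox)):
        if all(m.iou(k) <= iou_cap for k in kept):
            kept.append(m)
    return kept


def _finalize_cluster_masks(
    candidates: list[SegmentMask],
    cluster: SegmentMask,
    a_ref: float,
    cfg: DenseBackendConfig,
    shape: tuple[int, int],
) -> list[SegmentMask]:
    """Apply the shared backend contract to candidate masks."""
    cluster_full = cluster.full_mask(shape)
    ok: list[SegmentMask] = []
    for m in candidates:
        area = m.area_px
        if not (0.3 * a_ref <= area <= 1.6 * a_ref):
            continue
        inside = int(np.logical_and(m.full_mask(shape), cluster_full).sum())
        if inside < 0.9 * area:
            continue
        ok.append(m)
    ok = _greedy_nms(ok, cfg.nms_iou)
    if ok:
        union = np.zeros(shape, dtype=bool)
        for m in ok:
            union |= m.full_mask(shape)
        # cluster regions the accepted fragments do not explain (e.g. a pair
        # of seeds the distance transform cannot separate) are kept as
        # low-confidence masks rather than thrown away with the whole split
        leftover = cluster_full & ~union
        lab, n = ndi.label(
            leftover, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        for i in range(1, n + 1):
            piece = lab == i
            if piece.sum() >= 0.3 * a_ref:
                ok.append(mask_from_full(piece, PROVENANCE_DENSE, quality=0.2))
                union |= piece
        coverage = np.logical_and(union, cluster_full).sum() / cluster.area_px
        if coverage >= 0.8:
            return ok
    # unsplittable: return the whole cluster as one low-confidence seed
    return [
        SegmentMask(
            bbox=cluster.bbox,
            local_mask=cluster.local_mask,
            contour=cluster.contour,
            provenance=PROVENANCE_DENSE,
            quality=0.2,
        )
    ]


def _watershed_once(local: np.ndarray, min_sep: int) -> list[np.ndarray]:
    """Marker-controlled watershed of one region; returns local fragment masks."""
    padded = np.pad(local, 1)  # EDT must see background at the crop border
    dist = ndi.distance_transform_edt(padded)
    peaks = skfeature.peak_local_max(
        dist, min_distance=min_sep, labels=padded, exclude_border=False
    )
    markers = np.zeros_like(padded, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # pragma: no cover - EDT of nonempty mask has a max
        markers[np.unravel_index(np.argmax(dist), dist.shape)] = 1
    ws = skseg.watershed(-dist, markers=markers, mask=padded)[1:-1, 1:-1]
    return [ws == lab for lab in range(1, ws.max() + 1) if (ws == lab).any()]


def _split_cluster_watershed(
    cluster: SegmentMask, a_ref: float, cfg: DenseBackendConfig, shape: tuple[int, int]
) -> list[SegmentMask]:
    min_sep = max(1, int(round(0.8 * math.sqrt(a_ref / math.pi))))
    pending = [(cluster.local_mask, min_sep)]
    final_frags: list[np.ndarray] = []
    while pending:
        local, sep = pending.pop()
        frags = _watershed_once(local, sep)
        for frag in frags:
            area = int(frag.sum())
            # a fragment still holding >1 seed is re-split with closer markers
            if area > 1.6 * a_ref and sep > 2:
                pending.append((frag, max(2, sep // 2)))
            else:
                final_frags.append(frag)
    x0, y0 = cluster.bbox[0], cluster.bbox[1]
    fragments: list[SegmentMask] = []
    for frag in final_frags:
        full = np.zeros(shape, dtype=bool)
        full[y0 : y0 + frag.shape[0], x0 : x0 + frag.shape[1]] = frag
        m = mask_from_full(full, PROVENANCE_DENSE, quality=1.0)
        m = SegmentMask(
            bbox=m.bbox,
            local_mask=m.local_mask,
            contour=m.contour,
            provenance=PROVENANCE_DENSE,
            quality=_component_solidity(m.local_mask),
        )
        fragments.append(m)
    return _finalize_cluster_masks(fragments, cluster, a_ref, cfg, shape)


def _split_cluster_sam(
    pre: PreprocessedImage,
    cluster: SegmentMask,
    a_ref: float,
    cfg: DenseBackendConfig,
    shape: tuple[int, int],
    mask_generator=None,
) -> list[SegmentMask]:
    """Automatic mask generation over a padded crop of the cluster.

    ``mask_generator`` is an injected object with a ``generate(rgb)``
    method returning dicts with ``segmentation`` (bool array) and
    ``predicted_iou`` keys, as produced by SAM's automatic mask
    generator built with ``points_per_side`` and ``pred_iou_thresh``
    from ``cfg``.  Without an injected generator the SAM package and
    model weights must be available; otherwise this backend refuses to
    run rather than silently falling back.
    """
    if mask_generator is None:
        try:
            import segment_anything  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "SAM backend selected but the segment-anything package/weights "
                "are unavailable; use backend='watershed' or inject a mask "
                "generator"
            ) from exc
        raise BackendUnavailableError(
            "SAM backend requires an injected mask generator with loaded weights"
        )
    x0, y0, x1, y1 = cluster.bbox
    pad = 8
    cx0, cy0 = max(0, x0 - pad), max(0, y0 - pad)
    cx1, cy1 = min(shape[1], x1 + pad), min(shape[0], y1 + pad)
    crop = pre.normalized_rgb[cy0:cy1, cx0:cx1]
    raw = mask_generator.generate(crop)
    candidates: list[SegmentMask] = []
    for rec in raw:
        seg = np.asarray(rec["segmentation"], dtype=bool)
        if not seg.any():
            continue
        full = np.zeros(shape, dtype=bool)
        full[cy0:cy1, cx0:cx1] = seg
        m = mask_from_full(full, PROVENANCE_DENSE, quality=1.0)
        m = SegmentMask(
            bbox=m.bbox,
            local_mask=m.local_mask,
            contour=m.contour,
            provenance=PROVENANCE_DENSE,
            quality=float(rec.get("predicted_iou", 0.5)),
        )
        candidates.append(m)
    return _finalize_cluster_masks(candidates, cluster, a_ref, cfg, shape)


def split_cluster(
    pre: PreprocessedImage,
    cluster: SegmentMask,
    a_ref: float,
    cfg: DenseBackendConfig | None = None,
    mask_generator=None,
) -> list[SegmentMask]:
    """Split a fused cluster region into individual seed masks.

    Both backends honour the same contract: every returned mask lies at
    least 90% inside the cluster, has area within [0.3, 1.6] of the
    reference seed area, and survives greedy non-maximum suppression at
    the configured IoU cap; if the surviving masks cover less than 80%
    of the cluster, the whole cluster is returned as a single
    low-quality (0.2) mask instead.
    """
    cfg = cfg or DenseBackendConfig()
    shape = pre.blurred.shape
    if cfg.backend == "watershed":
        return _split_cluster_watershed(cluster, a_ref, cfg, shape)
    return _split_cluster_sam(pre, cluster, a_ref, cfg, shape, mask_generator)


def segment_image(
    pre: PreprocessedImage,
    cfg: DenseBackendConfig | None = None,
    min_area: int = 100,
    cluster_area_factor: float = 1.6,
    cluster_solidity: float = 0.85,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
    mask_generator=None,
) -> list[SegmentMask]:
    """Full hybrid segmentation: one mask per seed, deterministically indexed.

    Seed indices are assigned row-major by centroid (y, then x), so
    re-running on the same image reproduces identical indices and masks.
    """
    cfg = cfg or DenseBackendConfig()
    fg = extract_foreground(pre, min_area=min_area, canny_low=canny_low, canny_high=canny_high)
    part = partition_regions(
        fg,
        min_area=min_area,
        cluster_area_factor=cluster_area_factor,
        cluster_solidity=cluster_solidity,
    )
    masks = list(part.singletons)
    for cluster in part.clusters:
        masks.extend(
            split_cluster(pre, cluster, part.reference_area, cfg, mask_generator)
        )
    masks = _greedy_nms(masks, cfg.nms_iou)
    masks.sort(key=lambda m: (round(m.centroid[1], 3), round(m.centroid[0], 3)))
    return [
        SegmentMask(
            bbox=m.bbox,
            local_mask=m.local_mask,
            contour=m.contour,
            provenance=m.provenance,
            quality=m.quality,
            seed_index=i,
        )
        for i, m in enumerate(masks)
    ]
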