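"""Synthetic seed scenes with known instance masks and labels.

The generator emulates photographs of Arabidopsis seed populations
dispersed on white paper: plump light-brown ellipsoids (normal),
misshapen darker seeds (partially collapsed) and shrivelled dark-brown
irregular seeds (fully collapsed).  Seed outlines are ellipses whose
radius is modulated by random low-order sinusoids; the modulation
amplitude, size deficit and colour darkening increase with collapse
severity, reproducing the qualitative contrasts a human annotator uses.
Touching is produced by tangent placement (seeds may touch, never
stack), and lighting perturbations are global gain changes, so every
pipeline stage can be exercised against exact ground truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .annotations import LabelPoint, SeedClass
from .imaging import CalibratedImage

__all__ = [
    "PhenotypeParams",
    "SceneSpec",
    "SceneTruth",
    "PlacementError",
    "DEFAULT_PHENOTYPES",
    "render_seed",
    "generate_scene",
    "write_fixture_set",
]


class PlacementError(RuntimeError):
    """Raised when seeds cannot be placed under the scene's constraints."""


def _interpolate_params(p: "PhenotypeParams", target: "PhenotypeParams",
                        t: float) -> "PhenotypeParams":
    """Linear blend of rendering parameters, ``t`` of the way to ``target``."""
    mix = lambda a, b: a + t * (b - a)
    return PhenotypeParams(
        base_area_px=mix(p.base_area_px, target.base_area_px),
        area_jitter=mix(p.area_jitter, target.area_jitter),
        axis_ratio_range=(
            mix(p.axis_ratio_range[0], target.axis_ratio_range[0]),
            mix(p.axis_ratio_range[1], target.axis_ratio_range[1]),
        ),
        radial_noise_amp=mix(p.radial_noise_amp, target.radial_noise_amp),
        radial_noise_harmonics=int(round(
            mix(p.radial_noise_harmonics, target.radial_noise_harmonics)
        )),
        base_rgb=tuple(mix(a, b) for a, b in zip(p.base_rgb, target.base_rgb)),
        rgb_jitter=mix(p.rgb_jitter, target.rgb_jitter),
        speckle_sd=mix(p.speckle_sd, target.speckle_sd),
    )


@dataclass(frozen=True)
class PhenotypeParams:
    """Rendering parameters for one phenotype class.

    ``radial_noise_amp`` is the total boundary-modulation amplitude as a
    fraction of the local ellipse radius; ``base_area_px`` the expected
    mask area in pixels before jitter.
    """

    base_area_px: float
    area_jitter: float
    axis_ratio_range: tuple[float, float]
    radial_noise_amp: float
    radial_noise_harmonics: int
    base_rgb: tuple[float, float, float]
    rgb_jitter: float
    speckle_sd: float
    #: optional (milder, severer) endpoint parameter sets: each seed draws a
    #: severity in [-severity_span, +severity_span] and interpolates its
    #: parameters toward the corresponding endpoint, producing a phenotype
    #: continuum centred on this class's own values
    severity_endpoints: tuple["PhenotypeParams", "PhenotypeParams"] | None = None
    severity_span: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.radial_noise_amp < 1:
            raise ValueError("radial_noise_amp must be in [0, 1)")
        if self.radial_noise_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if not 0 <= self.severity_span <= 1:
            raise ValueError("severity_span must be in [0, 1]")


_NORMAL_PARAMS = PhenotypeParams(
    base_area_px=700.0, area_jitter=0.12, axis_ratio_range=(1.3, 1.7),
    radial_noise_amp=0.04, radial_noise_harmonics=3,
    base_rgb=(181.0, 141.0, 96.0), rgb_jitter=10.0, speckle_sd=6.0,
)
_FULL_PARAMS = PhenotypeParams(
    base_area_px=455.0, area_jitter=0.16, axis_ratio_range=(1.2, 2.1),
    radial_noise_amp=0.35, radial_noise_harmonics=6,
    base_rgb=(84.0, 58.0, 38.0), rgb_jitter=10.0, speckle_sd=10.0,
)

#: Default phenotype contrasts, relative to a 700 px reference seed.
#: Normal seeds are smooth light-brown ellipses; fully collapsed seeds
#: are markedly smaller, dark brown and shrivelled.  Partially collapsed
#: seeds form a severity continuum centred on their own (intermediate)
#: parameter set and stretching toward both neighbours — they genuinely
#: share characteristics with normal and fully collapsed seeds, which is
#: what makes them the hardest category to call.
DEFAULT_PHENOTYPES: dict[SeedClass, PhenotypeParams] = {
    SeedClass.NORMAL: _NORMAL_PARAMS,
    SeedClass.PARTIAL: PhenotypeParams(
        base_area_px=630.0, area_jitter=0.14, axis_ratio_range=(1.3, 1.9),
        radial_noise_amp=0.15, radial_noise_harmonics=4,
        base_rgb=(135.0, 102.0, 70.0), rgb_jitter=12.0, speckle_sd=8.0,
        severity_endpoints=(_NORMAL_PARAMS, _FULL_PARAMS),
    ),
    SeedClass.FULL: _FULL_PARAMS,
}

#: Class mix matching a typical triploid-block seed population
#: (roughly one third per category, partials slightly rarer).
DEFAULT_CLASS_MIX = (0.364, 0.285, 0.351)

LIGHTING_GAIN = {"normal": 1.0, "dark": 0.7, "bright": 1.2}


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene; fully deterministic given rng_seed."""

    n_seeds: int = 150
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX
    cluster_fraction: float = 0.2
    max_cluster_size: int = 6
    image_size: tuple[int, int] = (1024, 1360)
    lighting: str = "normal"
    rng_seed: int = 0
    phenotypes: dict[SeedClass, PhenotypeParams] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.lighting not in LIGHTING_GAIN:
            raise ValueError(f"unknown lighting {self.lighting!r}")


@dataclass
class SceneTruth:
    """A rendered scene plus exact instance-level ground truth."""

    image: CalibratedImage
    instance_masks: list[np.ndarray]  # full-frame boolean rasters
    classes: list[SeedClass]
    label_points: list[LabelPoint]
    spec: SceneSpec


# ---------------------------------------------------------------------------
# Single-seed rendering
# ---------------------------------------------------------------------------

def render_seed(
    cls: SeedClass,
    params: PhenotypeParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one seed: ``(local_mask, local_rgb)``.

    The outline is an ellipse whose radius is modulated by
    ``radial_noise_harmonics`` random sinusoids with total amplitude at
    most ``radial_noise_amp``; the fill is the phenotype base colour
    with a per-seed offset plus per-pixel Gaussian speckle.
    """
    params = params or DEFAULT_PHENOTYPES[cls]
    rng = rng or np.random.default_rng()
    if params.severity_endpoints is not None:
        s = rng.uniform(-params.severity_span, params.severity_span)
        target = params.severity_endpoints[0 if s < 0 else 1]
        params = _interpolate_params(params, target, abs(s))
    area = params.base_area_px * float(
        np.clip(1.0 + params.area_jitter * rng.standard_normal(), 0.5, 1.6)
    )
    q = rng.uniform(*params.axis_ratio_range)  # major/minor axis ratio
    b = math.sqrt(area / (math.pi * q))
    a = q * b
    phi = rng.uniform(0, math.pi)
    nh = params.radial_noise_harmonics
    weights = rng.dirichlet(np.ones(nh)) * params.radial_noise_amp \
        * rng.uniform(0.7, 1.0)
    phases = rng.uniform(0, 2 * math.pi, size=nh)

    half = int(math.ceil(a * (1.0 + params.radial_noise_amp) + 2))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ct, st = math.cos(phi), math.sin(phi)
    u = (xx * ct + yy * st) / a
    v = (-xx * st + yy * ct) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    scale = np.ones_like(rho)
    for k in range(nh):
        scale += weights[k] * np.sin((k + 1) * theta + phases[k])
    mask = rho <= np.maximum(scale, 0.1)
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    mask = mask[y0:y1, x0:x1]

    base = np.asarray(params.base_rgb) + rng.normal(0, params.rgb_jitter, size=3)
    patch = np.empty(mask.shape + (3,), dtype=np.float64)
    patch[:] = base
    patch += rng.normal(0, params.speckle_sd, size=patch.shape)
    patch = np.clip(patch, 0, 255)
    return mask, patch


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def _support(mask: np.ndarray, centre: np.ndarray, u: np.ndarray) -> float:
    """Support function of the mask's pixel set along unit direction u."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]) - centre
    return float((pts @ u).max())


def _local_centre(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean(), ys.mean()])


def _can_place(mask: np.ndarray, top: int, left: int, occupancy: np.ndarray,
               clearance: int) -> bool:
    h, w = mask.shape
    H, W = occupancy.shape
    if top < 2 or left < 2 or top + h > H - 2 or left + w > W - 2:
        return False
    t0, l0 = max(0, top - clearance), max(0, left - clearance)
    t1, l1 = min(H, top + h + clearance), min(W, left + w + clearance)
    window = occupancy[t0:t1, l0:l1]
    if not window.any():
        return True
    grown = ndi.binary_dilation(mask, iterations=clearance) if clearance else mask
    # paste the grown mask into the window's frame and test intersection
    canvas = np.zeros_like(window)
    gt = (top - clearance) - t0
    gl = (left - clearance) - l0
    src = grown[max(0, -gt) :, max(0, -gl) :]
    src = src[: window.shape[0] - max(0, gt), : window.shape[1] - max(0, gl)]
    canvas[max(0, gt) : max(0, gt) + src.shape[0],
           max(0, gl) : max(0, gl) + src.shape[1]] = src
    return not np.logical_and(canvas, window).any()


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render a full scene per its spec, with exact instance ground truth.

    Clustered seeds are placed as touching chains (tangent boundaries,
    zero pixel overlap); dispersed seeds keep at least 3 px clearance.
    The background is near-white paper; 'dark'/'bright' lighting applies
    a global gain of 0.7 / 1.2 (clipped) to the final image.
    """
    H, W = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)
    classes = [SeedClass(int(c)) for c in
               rng.choice(3, size=spec.n_seeds, p=np.asarray(spec.class_mix))]
    rendered = [render_seed(c, spec.phenotypes[c], rng) for c in classes]
    total_area = sum(m.sum() for m, _ in rendered)
    if total_area > 0.3 * H * W:
        raise PlacementError(
            f"total seed area {total_area} exceeds 30% of the image"
        )

    n_clustered = int(round(spec.cluster_fraction * spec.n_seeds))
    order = list(rng.permutation(spec.n_seeds))
    cluster_groups: list[list[int]] = []
    i = 0
    while i < n_clustered:
        size = int(rng.integers(2, spec.max_cluster_size + 1))
        size = min(size, n_clustered - i)
        if size < 2:
            break
        cluster_groups.append(order[i : i + size])
        i += size
    singles = order[i:]

    occupancy = np.zeros((H, W), dtype=bool)
    placements: dict[int, tuple[int, int]] = {}  # seed -> (top, left)

    def paste(idx: int, top: int, left: int) -> None:
        mask = rendered[idx][0]
        occupancy[top : top + mask.shape[0], left : left + mask.shape[1]] |= mask
        placements[idx] = (top, left)

    def random_spot(mask: np.ndarray) -> tuple[int, int]:
        h, w = mask.shape
        return (int(rng.integers(2, H - h - 2)), int(rng.integers(2, W - w - 2)))

    max_tries = 400
    for group in cluster_groups:
        for attempt in range(max_tries):
            trial_occ = occupancy.copy()
            trial_pl: dict[int, tuple[int, int]] = {}
            first = group[0]
            m0 = rendered[first][0]
            top, left = random_spot(m0)
            if not _can_place(m0, top, left, trial_occ, clearance=3):
                continue
            trial_occ[top : top + m0.shape[0], left : left + m0.shape[1]] |= m0
            trial_pl[first] = (top, left)
            ok = True
            prev = first
            for idx in group[1:]:
                placed = False
                for _ in range(40):
                    ang = rng.uniform(0, 2 * math.pi)
                    u = np.array([math.cos(ang), math.sin(ang)])
                    pm = rendered[prev][0]
                    nm = rendered[idx][0]
                    pc = _local_centre(pm)
                    nc = _local_centre(nm)
                    ptop, pleft = trial_pl[prev]
                    prev_centre = np.array([pleft, ptop]) + pc
                    d = _support(pm, pc, u) + _support(nm, nc, -u) + 1.0
                    # tightest placement first: pixel-tangency, zero overlap
                    best = None
                    for dd in (d - 1.0, d - 0.5, d, d + 0.5, d + 1.0):
                        centre = prev_centre + dd * u
                        t = int(round(centre[1] - nc[1]))
                        l = int(round(centre[0] - nc[0]))
                        if not _can_place(nm, t, l, trial_occ, clearance=0):
                            continue
                        best = (t, l)
                        break
                    if best is None:
                        continue
                    t, l = best
                    trial_occ[t : t + nm.shape[0], l : l + nm.shape[1]] |= nm
                    trial_pl[idx] = (t, l)
                    prev = idx
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                for idx, (t, l) in trial_pl.items():
                    paste(idx, t, l)
                break
        else:
            raise PlacementError("could not place a seed cluster; scene too crowded")

    for idx in singles:
        mask = rendered[idx][0]
        for attempt in range(max_tries):
            top, left = random_spot(mask)
            if _can_place(mask, top, left, occupancy, clearance=3):
                paste(idx, top, left)
                break
        else:
            raise PlacementError("could not place a dispersed seed; scene too crowded")

    # composite: near-white paper, then seed patches
    img = np.clip(rng.normal(252.0, 1.5, size=(H, W, 1)), 245, 255)
    img = np.repeat(img, 3, axis=2)
    instance_masks: list[np.ndarray] = []
    for idx in range(spec.n_seeds):
        mask, patch = rendered[idx]
        top, left = placements[idx]
        region = img[top : top + mask.shape[0], left : left + mask.shape[1]]
        region[mask] = patch[mask]
        full = np.zeros((H, W), dtype=bool)
        full[top : top + mask.shape[0], left : left + mask.shape[1]] = mask
        instance_masks.append(full)

    gain = LIGHTING_GAIN[spec.lighting]
    img = np.clip(img * gain, 0, 255).round().astype(np.uint8)
    cal = CalibratedImage(pixels=img, source_id=f"scene_{spec.rng_seed:05d}")

    label_points = []
    for mask, cls in zip(instance_masks, classes):
        ys, xs = np.nonzero(mask)
        label_points.append(
            LabelPoint(x=float(xs.mean()), y=float(ys.mean()), category=cls)
        )
    return SceneTruth(
        image=cal,
        instance_masks=instance_masks,
        classes=classes,
        label_points=label_points,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Fixture sets on disk
# ---------------------------------------------------------------------------

def write_fixture_set(specs: list[SceneSpec], out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write one (TIFF image, label TXT, truth archive) triple per spec.

    Label files use the multipoint dialect read by
    :func:`seedpheno.annotations.parse_label_file`.  Returns (and writes
    as ``manifest.csv``) a manifest with file names and per-class counts.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for spec in specs:
        truth = generate_scene(spec)
        sid = truth.image.source_id
        img_path = os.path.join(out_dir, f"{sid}.tif")
        tifffile.imwrite(img_path, truth.image.pixels)
        txt_path = os.path.join(out_dir, f"{sid}.txt")
        with open(txt_path, "w", encoding="utf-8") as fh:
            fh.write("X\tY\tCounter\n")
            for pt in truth.label_points:
                fh.write(f"{pt.x:.2f}\t{pt.y:.2f}\t{int(pt.category)}\n")
        truth_path = os.path.join(out_dir, f"{sid}_truth.npz")
        np.savez_compressed(
            truth_path,
            masks=np.stack(truth.instance_masks).astype(np.uint8),
            classes=np.array([int(c) for c in truth.classes]),
        )
        counts = {c: truth.classes.count(c) for c in SeedClass}
        rows.append({
            "image_id": sid,
            "image_file": os.path.basename(img_path),
            "label_file": os.path.basename(txt_path),
            "truth_file": os.path.basename(truth_path),
            "n_seeds": spec.n_seeds,
            "rng_seed": spec.rng_seed,
            "lighting": spec.lighting,
            "count_normal": counts[SeedClass.NORMAL],
            "count_partial": counts[SeedClass.PARTIAL],
            "count_full": counts[SeedClass.FULL],
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
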