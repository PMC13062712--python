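"""High-level orchestration: configuration and image -> descriptors runs."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import yaml

from .annotations import SeedClass, match_labels
from .features import SeedDescriptors, compute_descriptors
from .imaging import CalibratedImage, PreprocessedImage, preprocess
from .segmentation import DenseBackendConfig, SegmentMask, segment_image
from .synthetic import SceneSpec, SceneTruth, generate_scene

__all__ = ["PipelineConfig", "process_image", "make_training_examples"]


@dataclass(frozen=True)
class PipelineConfig:
    """All user-tunable knobs of the segmentation/feature pipeline.

    sigma
        Gaussian blur standard deviation in pixels; scale with zoom.
    min_area
        Components below this pixel area are dropped as debris (logged).
    cluster_area_factor, cluster_solidity
        A foreground component is routed to the dense backend iff its
        area exceeds ``cluster_area_factor`` times the reference seed
        area or its solidity falls below ``cluster_solidity``.
    backend, points_per_side, pred_iou_thresh, nms_iou
        Dense-backend selection and parameters.
    canny_low, canny_high
        Canny hysteresis thresholds (8-bit intensity units) used for
        edge subtraction during foreground extraction.
    um_per_px
        Optional physical pixel size; enables mm^2 areas in reports.
    """

    sigma: float = 2.0
    min_area: int = 100
    cluster_area_factor: float = 1.6
    cluster_solidity: float = 0.85
    backend: str = "watershed"
    points_per_side: int = 49
    pred_iou_thresh: float = 0.86
    nms_iou: float = 0.3
    canny_low: float = 50.0
    canny_high: float = 150.0
    um_per_px: float | None = None

    def dense_config(self) -> DenseBackendConfig:
        return DenseBackendConfig(
            backend=self.backend,
            points_per_side=self.points_per_side,
            pred_iou_thresh=self.pred_iou_thresh,
            nms_iou=self.nms_iou,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(os.fspath(path), encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def process_image(
    img: CalibratedImage,
    cfg: PipelineConfig | None = None,
    mask_generator=None,
) -> tuple[PreprocessedImage, list[SegmentMask], list[SeedDescriptors]]:
    """Preprocess, segment and extract descriptors for one image."""
    cfg = cfg or PipelineConfig()
    pre = preprocess(img, sigma=cfg.sigma)
    masks = segment_image(
        pre,
        cfg.dense_config(),
        min_area=cfg.min_area,
        cluster_area_factor=cfg.cluster_area_factor,
        cluster_solidity=cfg.cluster_solidity,
        canny_low=cfg.canny_low,
        canny_high=cfg.canny_high,
        mask_generator=mask_generator,
    )
    feats = compute_descriptors(pre, masks)
    return pre, masks, feats


def make_training_examples(
    n_seeds: int,
    rng_seed: int = 42,
    scene_spec: SceneSpec | None = None,
    cfg: PipelineConfig | None = None,
    seeds_per_scene: int = 150,
) -> list[tuple[SeedDescriptors, SeedClass]]:
    """Labeled training examples produced by the *real* pipeline.

    Scenes are generated, segmented, described, and the ground-truth
    label points are matched to the detected masks exactly as a user's
    manual annotations would be — so the examples inherit any
    segmentation imperfection, mirroring real training data.
    """
    base = scene_spec or SceneSpec(n_seeds=seeds_per_scene)
    examples: list[tuple[SeedDescriptors, SeedClass]] = []
    scene_idx = 0
    while len(examples) < n_seeds:
        spec = replace(base, rng_seed=rng_seed + scene_idx)
        truth = generate_scene(spec)
        pre, masks, feats = process_image(truth.image, cfg)
        report = match_labels(masks, truth.label_points)
        by_index = {f.seed_index: f for f in feats}
        for seed_index, category in report.matched:
            if seed_index in by_index:
                examples.append((by_index[seed_index], category))
        scene_idx += 1
        if scene_idx > 200:  # pragma: no cover - defensive bound
            raise RuntimeError("failed to accumulate enough training examples")
    return examples[:n_seeds]
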