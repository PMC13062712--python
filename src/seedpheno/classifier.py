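"""Random-forest classification of seeds into normal / partial / full.

The classifier consumes the ordered 38-descriptor record per seed and
predicts the three-category abortion phenotype by majority vote over an
ensemble of decision trees.  The final forest uses 100 trees, depth cap
7, minimum split 5, bootstrap resampling and out-of-bag scoring; a grid
search over a small bracket of these hyperparameters can be run on a
stratified 70/30 split.  Trained models are persisted as versioned
bundles that embed the descriptor order, so a stale model fails loudly
instead of mis-predicting.
"""

from __future__ import annotations

import datetime
import itertools
import os
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from . import __version__ as _pkg_version
from .annotations import SeedClass
from .features import DESCRIPTOR_NAMES, SeedDescriptors

__all__ = [
    "ForestConfig",
    "ModelBundle",
    "EvalReport",
    "ClassifiedSeed",
    "StratificationError",
    "ModelCompatibilityError",
    "BundleLoadError",
    "default_grid",
    "train",
    "predict",
    "downsample_curve",
    "save_bundle",
    "load_bundle",
]

BUNDLE_FORMAT_VERSION = 1
CLASS_ORDER = (SeedClass.NORMAL, SeedClass.PARTIAL, SeedClass.FULL)


class StratificationError(ValueError):
    """A class has too few examples for a stratified split."""


class ModelCompatibilityError(ValueError):
    """Feature table header does not match the bundle's descriptor order."""


class BundleLoadError(RuntimeError):
    """Bundle file is corrupt or has an unknown format version."""


def default_grid() -> dict[str, list]:
    """Hyperparameter bracket searched by default when a grid is requested."""
    return {
        "n_estimators": [100, 200, 500],
        "max_depth": [5, 7, 10, None],
        "min_samples_split": [2, 5, 10],
    }


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters and evaluation-split settings.

    ``grid=None`` (the default) fits the stated final parameters
    directly; pass :func:`default_grid` (or any mapping of parameter
    name to candidate list) to select them by grid search on the
    held-out split instead.
    """

    n_estimators: int = 100
    max_depth: int | None = 7
    min_samples_split: int = 5
    bootstrap: bool = True
    oob_score: bool = True
    test_size: float = 0.30
    stratify: bool = True
    random_state: int = 42
    grid: dict[str, list] | None = None


@dataclass
class EvalReport:
    """Held-out evaluation of a trained forest."""

    accuracy: float
    confusion: np.ndarray  # 3x3, rows = true, cols = predicted
    per_class_precision_recall: dict[str, tuple[float, float]]
    feature_importance: np.ndarray  # 38 values summing to 1
    oob_score: float
    best_params: dict


@dataclass
class ModelBundle:
    """Trained forest plus the metadata needed to apply it safely."""

    forest: RandomForestClassifier
    descriptor_order: tuple[str, ...]
    class_order: tuple[SeedClass, ...]
    training_meta: dict


@dataclass(frozen=True)
class ClassifiedSeed:
    """Prediction for one seed: category, class probabilities, confidence."""

    seed_index: int
    category: SeedClass
    probabilities: tuple[float, float, float]
    confidence: float


def _examples_to_xy(
    examples: list[tuple[SeedDescriptors, SeedClass]]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([d.values for d, _ in examples])
    y = np.array([int(c) for _, c in examples])
    return X, y


def _make_forest(params: dict, cfg: ForestConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_split=params["min_samples_split"],
        bootstrap=cfg.bootstrap,
        oob_score=cfg.oob_score and cfg.bootstrap,
        random_state=cfg.random_state,
        n_jobs=1,
    )


def _proba_matrix(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Vote fractions as an (n, 3) matrix in fixed class order."""
    raw = forest.predict_proba(X)
    out = np.zeros((raw.shape[0], 3))
    for col, cls in enumerate(forest.classes_):
        out[:, int(cls)] = raw[:, col]
    return out


def train(
    examples: list[tuple[SeedDescriptors, SeedClass]],
    cfg: ForestConfig | None = None,
) -> tuple[ModelBundle, EvalReport]:
    """Fit (and optionally grid-search) the forest on labeled descriptors.

    The data are split once into stratified train/test parts at
    ``cfg.test_size`` with ``cfg.random_state``.  With a grid, each
    candidate is fitted on the training part and scored by accuracy on
    the held-out part (ties break toward the earlier grid point in
    documented order); the winner is refit on the training part and the
    evaluation report is computed on the held-out part.
    """
    cfg = cfg or ForestConfig()
    if len(examples) < 30:
        raise ValueError(f"need at least 30 examples, got {len(examples)}")
    X, y = _examples_to_xy(examples)
    present, counts = np.unique(y, return_counts=True)
    if present.size < 2:
        raise StratificationError(
            f"only class {SeedClass(int(present[0])).label!r} present; "
            "need at least 2 classes"
        )
    for cls, cnt in zip(present, counts):
        if cnt < 2:
            raise StratificationError(
                f"class {SeedClass(int(cls)).label!r} has {cnt} example(s); "
                "at least 2 required for a stratified split"
            )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y,
        test_size=cfg.test_size,
        stratify=y if cfg.stratify else None,
        random_state=cfg.random_state,
    )

    if cfg.grid:
        keys = list(cfg.grid)
        best_params, best_score = None, -1.0
        for combo in itertools.product(*(cfg.grid[k] for k in keys)):
            params = {
                "n_estimators": cfg.n_estimators,
                "max_depth": cfg.max_depth,
                "min_samples_split": cfg.min_samples_split,
            }
            params.update(dict(zip(keys, combo)))
            forest = _make_forest(params, cfg).fit(X_tr, y_tr)
            score = accuracy_score(y_te, forest.predict(X_te))
            if score > best_score:  # strict: ties keep the earlier point
                best_params, best_score = params, score
    else:
        best_params = {
            "n_estimators": cfg.n_estimators,
            "max_depth": cfg.max_depth,
            "min_samples_split": cfg.min_samples_split,
        }

    forest = _make_forest(best_params, cfg).fit(X_tr, y_tr)
    y_pred = forest.predict(X_te)
    conf = confusion_matrix(y_te, y_pred, labels=[0, 1, 2])
    prec, rec, _, _ = precision_recall_fscore_support(
        y_te, y_pred, labels=[0, 1, 2], zero_division=0.0
    )
    report = EvalReport(
        accuracy=float(accuracy_score(y_te, y_pred)),
        confusion=conf,
        per_class_precision_recall={
            cls.label: (float(p), float(r))
            for cls, p, r in zip(CLASS_ORDER, prec, rec)
        },
        feature_importance=np.asarray(forest.feature_importances_),
        oob_score=float(getattr(forest, "oob_score_", float("nan"))),
        best_params=dict(best_params),
    )
    meta = {
        "n_examples": len(examples),
        "class_counts": {SeedClass(int(c)).label: int(n)
                         for c, n in zip(present, counts)},
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in asdict(cfg).items()},
        "best_params": dict(best_params),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "artifact_version": _pkg_version,
        "format_version": BUNDLE_FORMAT_VERSION,
    }
    bundle = ModelBundle(
        forest=forest,
        descriptor_order=tuple(DESCRIPTOR_NAMES),
        class_order=CLASS_ORDER,
        training_meta=meta,
    )
    return bundle, report


def _check_header(bundle: ModelBundle, header: tuple[str, ...]) -> None:
    if tuple(header) != tuple(bundle.descriptor_order):
        missing = [n for n in bundle.descriptor_order if n not in header]
        extra = [n for n in header if n not in bundle.descriptor_order]
        reordered = not missing and not extra
        raise ModelCompatibilityError(
            "feature header does not match the model's descriptor order: "
            + (f"missing {missing}, unexpected {extra}"
               if not reordered else "columns are reordered")
        )


def predict(
    bundle: ModelBundle, feats: list[SeedDescriptors]
) -> list[ClassifiedSeed]:
    """Classify descriptor records; deterministic given the bundle."""
    if not feats:
        return []
    _check_header(bundle, tuple(DESCRIPTOR_NAMES))
    X = np.array([d.values for d in feats])
    proba = _proba_matrix(bundle.forest, X)
    out = []
    for d, p in zip(feats, proba):
        cat = SeedClass(int(np.argmax(p)))  # argmax ties -> lower class code
        out.append(
            ClassifiedSeed(
                seed_index=d.seed_index,
                category=cat,
                probabilities=(float(p[0]), float(p[1]), float(p[2])),
                confidence=float(p.max()),
            )
        )
    return out


def predict_table(bundle: ModelBundle, table: pd.DataFrame) -> list[ClassifiedSeed]:
    """Classify a feature table; its columns must equal the bundle's order."""
    _check_header(bundle, tuple(table.columns))
    feats = [
        SeedDescriptors(image_id="", seed_index=i, values=row)
        for i, row in enumerate(table.to_numpy(dtype=np.float64))
    ]
    return predict(bundle, feats)


# ---------------------------------------------------------------------------
# Training-set-size (down-sampling) analysis
# ---------------------------------------------------------------------------

def downsample_curve(
    pool: list[tuple[SeedDescriptors, SeedClass]],
    validation: list[tuple[SeedDescriptors, SeedClass]],
    sizes: list[int],
    iterations: int = 30,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, int | None]:
    """Accuracy as a function of training-set size.

    For each size and iteration a class-stratified random subset of the
    pool is drawn (seed = base_seed + iteration), a forest with the
    final default parameters is fitted (no grid search), and accuracy is
    measured on the full pool and on the independent validation set.
    The plateau is the smallest size whose mean validation accuracy
    differs from the next larger size's mean by less than 0.001.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X_pool, y_pool = _examples_to_xy(pool)
    X_val, y_val = _examples_to_xy(validation)
    sizes = sorted(sizes)
    for s in sizes:
        if s > len(pool):
            raise ValueError(f"training-set size {s} exceeds pool size {len(pool)}")
    rows = []
    for size in sizes:
        for it in range(iterations):
            seed = base_seed + it
            if size == len(pool):
                X_sub, y_sub = X_pool, y_pool
            else:
                X_sub, _, y_sub, _ = train_test_split(
                    X_pool, y_pool, train_size=size, stratify=y_pool,
                    random_state=seed,
                )
            cfg = ForestConfig(random_state=seed)
            forest = _make_forest(
                {"n_estimators": cfg.n_estimators, "max_depth": cfg.max_depth,
                 "min_samples_split": cfg.min_samples_split}, cfg
            ).fit(X_sub, y_sub)
            rows.append({
                "size": size,
                "iteration": it,
                "acc_on_pool": float(accuracy_score(y_pool, forest.predict(X_pool))),
                "acc_on_validation": float(accuracy_score(y_val, forest.predict(X_val))),
            })
    table = pd.DataFrame(rows)
    means = table.groupby("size")["acc_on_validation"].mean()
    plateau = None
    for smaller, larger in zip(sizes[:-1], sizes[1:]):
        if abs(means[larger] - means[smaller]) < 0.001:
            plateau = smaller
            break
    return table, plateau


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path: str | os.PathLike) -> None:
    """Serialize a model bundle (joblib archive with format version)."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "forest": bundle.forest,
        "descriptor_order": tuple(bundle.descriptor_order),
        "class_order": tuple(int(c) for c in bundle.class_order),
        "training_meta": bundle.training_meta,
    }
    joblib.dump(payload, os.fspath(path))


def load_bundle(path: str | os.PathLike) -> ModelBundle:
    """Load a bundle; corrupt files and unknown versions fail loudly."""
    try:
        payload = joblib.load(os.fspath(path))
    except Exception as exc:
        raise BundleLoadError(f"cannot load model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise BundleLoadError(f"{path} is not a model bundle")
    version = payload["format_version"]
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleLoadError(
            f"{path} has bundle format version {version}; "
            f"this build reads version {BUNDLE_FORMAT_VERSION}"
        )
    return ModelBundle(
        forest=payload["forest"],
        descriptor_order=tuple(payload["descriptor_order"]),
        class_order=tuple(SeedClass(c) for c in payload["class_order"]),
        training_meta=payload["training_meta"],
    )
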