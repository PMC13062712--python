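"""Parsing of ImageJ multipoint label files and label-to-mask matching.

Manual annotation uses ImageJ's multipoint tool with one counter per
phenotype category (0 = normal, 1 = partially collapsed, 2 = fully
collapsed); an export macro writes one plain-text file per image with
point coordinates and counter values.  Points are matched to segmented
masks by containment, and every annotation that cannot be used (point
in no mask, or a mask receiving conflicting categories) is accounted
for explicitly rather than silently dropped.
"""

from __future__ import annotations

import enum
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np

from .imaging import CalibratedImage
from .segmentation import SegmentMask

__all__ = [
    "SeedClass",
    "LabelPoint",
    "MatchReport",
    "LabelParseError",
    "parse_label_file",
    "match_labels",
]

log = logging.getLogger(__name__)


class SeedClass(enum.IntEnum):
    """Three-category seed-abortion phenotype, integer codes fixed."""

    NORMAL = 0
    PARTIAL = 1
    FULL = 2

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]


_CLASS_LABELS = {
    SeedClass.NORMAL: "normal",
    SeedClass.PARTIAL: "partial",
    SeedClass.FULL: "full",
}


class LabelParseError(ValueError):
    """A label file row could not be interpreted."""


@dataclass(frozen=True)
class LabelPoint:
    """A manual annotation point in image coordinates (0-based, x right, y down)."""

    x: float
    y: float
    category: SeedClass


@dataclass
class MatchReport:
    """Accounting of label points against segmented masks.

    Invariant: every input point is either behind a match, listed as
    unmatched, or inside an excluded (conflicting) mask.
    """

    matched: list[tuple[int, SeedClass]] = field(default_factory=list)
    unmatched_points: list[LabelPoint] = field(default_factory=list)
    excluded_masks: list[tuple[int, str]] = field(default_factory=list)


_SPLIT_RE = re.compile(r"[\t,;]+|\s{1,}")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_label_file(path: str | os.PathLike,
                     img: CalibratedImage) -> list[LabelPoint]:
    """Read a multipoint label file: rows of x, y, counter.

    Tab-, comma-, semicolon- or whitespace-separated; a single header
    row is detected by a non-numeric first field and skipped.  Points
    outside the image bounds are dropped with a warning; counter values
    outside {0, 1, 2} are an error.
    """
    path = os.fspath(path)
    points: list[LabelPoint] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        tokens = [t for t in _SPLIT_RE.split(line) if t]
        if lineno == 1 and tokens and not _is_number(tokens[0]):
            continue  # header row
        if len(tokens) < 3:
            raise LabelParseError(
                f"{path}:{lineno}: expected at least x, y, counter columns, "
                f"got {line!r}"
            )
        try:
            x, y = float(tokens[0]), float(tokens[1])
            counter = float(tokens[2])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
        if counter not in (0.0, 1.0, 2.0):
            raise LabelParseError(
                f"{path}:{lineno}: unknown counter value {tokens[2]!r} "
                "(expected 0, 1 or 2)"
            )
        if not (0 <= x < img.width and 0 <= y < img.height):
            log.warning("%s:%d: point (%.1f, %.1f) outside image bounds; dropped",
                        path, lineno, x, y)
            continue
        points.append(LabelPoint(x=x, y=y, category=SeedClass(int(counter))))
    return points


def match_labels(masks: list[SegmentMask],
                 points: list[LabelPoint]) -> MatchReport:
    """Assign each label point to the unique mask containing it.

    A mask with exactly one point — or several points all of one
    category, first kept — is matched with that category; a mask
    receiving conflicting categories is excluded from training; points
    inside no mask are reported as unmatched.  Boundary pixels count as
    inside.  Anomalies are reported, never raised.
    """
    report = MatchReport()
    per_mask: dict[int, list[LabelPoint]] = {}
    for pt in points:
        owner = None
        col, row = int(round(pt.x)), int(round(pt.y))
        for m in masks:
            x0, y0, x1, y1 = m.bbox
            if x0 <= col < x1 and y0 <= row < y1 and m.local_mask[row - y0, col - x0]:
                owner = m.seed_index
                break
        if owner is None:
            report.unmatched_points.append(pt)
        else:
            per_mask.setdefault(owner, []).append(pt)
    for idx in sorted(per_mask):
        cats = {p.category for p in per_mask[idx]}
        if len(cats) == 1:
            report.matched.append((idx, per_mask[idx][0].category))
        else:
            report.excluded_masks.append((idx, "multiple conflicting points"))
    return report
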