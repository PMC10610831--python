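"""Shared data types and file formats.

Detection boxes use the YOLO text convention: one object per line,
``class cx cy w h`` in coordinates normalized to the image size, with an
optional trailing confidence column for predictions.  Class indices 0-3 map
to the four shred varieties Y (tobacco silk), G (cut stem), P (expanded
tobacco silk) and Z (reconstituted tobacco shred).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

CLASS_NAMES: tuple[str, ...] = ("Y", "G", "P", "Z")
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class DetectionBox:
    """One labeled axis-aligned box in normalized image coordinates."""

    class_index: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.class_index < len(CLASS_NAMES):
            raise ValidationError(f"class index {self.class_index} out of range")
        for v in (self.cx, self.cy, self.w, self.h):
            if not np.isfinite(v):
                raise ValidationError("box coordinates must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError("box width/height must be positive")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_index]

    def to_xyxy(self, shape: tuple[int, int] | None = None) -> tuple[float, float, float, float]:
        """Corner coordinates; in pixels when an (H, W) shape is given."""
        sy, sx = (1.0, 1.0) if shape is None else (shape[0], shape[1])
        return (
            (self.cx - self.w / 2) * sx,
            (self.cy - self.h / 2) * sy,
            (self.cx + self.w / 2) * sx,
            (self.cy + self.h / 2) * sy,
        )

    @staticmethod
    def from_xyxy(
        class_index: int,
        x0: float,
        y0: float,
        x1: float,
        y1: float,
        shape: tuple[int, int] | None = None,
        confidence: float | None = None,
    ) -> "DetectionBox":
        sy, sx = (1.0, 1.0) if shape is None else (shape[0], shape[1])
        return DetectionBox(
            class_index=class_index,
            cx=(x0 + x1) / 2 / sx,
            cy=(y0 + y1) / 2 / sy,
            w=(x1 - x0) / sx,
            h=(y1 - y0) / sy,
            confidence=confidence,
        )

    def clipped(self) -> "DetectionBox | None":
        """Clip to the unit frame; None when nothing remains inside."""
        x0, y0, x1, y1 = self.to_xyxy()
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, 1.0), min(y1, 1.0)
        if x1 - x0 <= 1e-6 or y1 - y0 <= 1e-6:
            return None
        return DetectionBox.from_xyxy(self.class_index, x0, y0, x1, y1, confidence=self.confidence)

    def shifted(self, dx: float, dy: float) -> "DetectionBox":
        return replace(self, cx=self.cx + dx, cy=self.cy + dy)


def box_iou_xyxy(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two corner-coordinate boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValidationError("degenerate box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def read_yolo_labels(path: str | os.PathLike) -> list[DetectionBox]:
    boxes: list[DetectionBox] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (5, 6):
                raise ValidationError(f"malformed label line: {line!r}")
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else None
            boxes.append(DetectionBox(cls, cx, cy, w, h, conf))
    return boxes


def write_yolo_labels(path: str | os.PathLike, boxes: Iterable[DetectionBox]) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            line = f"{b.class_index} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
            if b.confidence is not None:
                line += f" {b.confidence:.6f}"
            fh.write(line + "\n")


def read_image(path: str | os.PathLike) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.asarray(img[..., :3], dtype=np.uint8)


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))
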