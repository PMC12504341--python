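"""Axis-aligned bounding boxes and the geometry shared across modules.

Coordinates are continuous pixels, origin at the image's top-left corner,
x rightward and y downward. Boxes are closed intervals
``[x_min, x_max] x [y_min, y_max]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundingBox", "iou", "box_to_measurement", "measurement_to_box", "iou_matrix"]


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite: {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def as_ltwh(self) -> tuple[float, float, float, float]:
        """(left, top, width, height) — the MOT file convention."""
        return (self.x_min, self.y_min, self.width, self.height)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, 1 iff identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(rows: list[BoundingBox], cols: list[BoundingBox]) -> np.ndarray:
    out = np.zeros((len(rows), len(cols)))
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            out[i, j] = iou(a, b)
    return out


def box_to_measurement(box: BoundingBox) -> np.ndarray:
    """Box -> Kalman measurement (cx, cy, a, h) with a = width/height."""
    h = box.height
    return np.array([(box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0,
                     box.width / h, h])


def measurement_to_box(z: np.ndarray) -> BoundingBox:
    """Inverse of :func:`box_to_measurement`."""
    cx, cy, a, h = float(z[0]), float(z[1]), float(z[2]), float(z[3])
    w = a * h
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)
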