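"""Axis-aligned bounding boxes and the rectangle distance used for blob clustering.

Coordinates are 0-based with x = column (rightward) and y = row (downward).
A box of width ``w`` starting at ``x0`` covers the pixel columns
``x0 .. x0 + w - 1``, i.e. the continuous interval ``[x0, x0 + w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BoundingBox", "rectangle_distance", "mask_bbox"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("bounding box must be at least 1x1")

    @property
    def x1(self) -> int:
        """One past the rightmost covered column."""
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        """One past the bottom covered row."""
        return self.y0 + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.width / 2.0, self.y0 + self.height / 2.0)

    def corners(self) -> np.ndarray:
        """The four continuous corner points, shape (4, 2) as (x, y)."""
        return np.array(
            [
                (self.x0, self.y0),
                (self.x1, self.y0),
                (self.x0, self.y1),
                (self.x1, self.y1),
            ],
            dtype=float,
        )

    def distance_to_point(self, x: float, y: float) -> float:
        """Euclidean distance from (x, y) to the nearest point of the box (0 inside)."""
        dx = max(self.x0 - x, 0.0, x - self.x1)
        dy = max(self.y0 - y, 0.0, y - self.y1)
        return math.hypot(dx, dy)


def rectangle_distance(b1: BoundingBox, b2: BoundingBox) -> float:
    """Minimum Euclidean distance between two axis-aligned rectangles.

    This is the blob-to-blob distance used to group nearby foreground
    fragments into one candidate person: the gap between the closest pair of
    points on the two rectangle boundaries, and 0 whenever the rectangles
    overlap or touch.
    """
    dx = max(b1.x0 - b2.x1, b2.x0 - b1.x1, 0)
    dy = max(b1.y0 - b2.y1, b2.y0 - b1.y1, 0)
    return math.hypot(dx, dy)


def mask_bbox(mask: np.ndarray) -> BoundingBox:
    """Tight bounding box of the nonzero pixels of a binary mask."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no bounding box")
    x0, y0 = int(xs.min()), int(ys.min())
    return BoundingBox(x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)
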