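"""Axis-aligned bounding boxes, measurement-space conversions, and IoU.

Pixel convention: origin at the image's top-left corner, x increasing
rightward, y increasing downward.  Boxes are stored as continuous
``(x_left, y_top, width, height)`` — never snapped to integer pixels.

The Kalman filter observes a box through the 4-vector ``(u, v, s, r)``:
center column, center row, area in square pixels, and width/height aspect
ratio.  Both directions of that mapping live here, together with
intersection-over-union, the association cost used throughout the tracker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive width or height."""


class InvalidMeasurementError(ValueError):
    """Raised for measurements with non-positive area or aspect ratio."""


@dataclass(frozen=True)
class Box:
    """A detection or track rectangle in pixel coordinates.

    Parameters
    ----------
    x, y
        Top-left corner (column, row) in pixels.
    w, h
        Width and height in pixels; both must be strictly positive.
    confidence
        Optional detector score in [0, 1]; ``None`` for track boxes.
    """

    x: float
    y: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(
                f"box width and height must be positive, got w={self.w}, h={self.h}"
            )

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def x_right(self) -> float:
        return self.x + self.w

    @property
    def y_bottom(self) -> float:
        return self.y + self.h


@dataclass(frozen=True)
class Measurement:
    """Box expressed in the filter's observation space (u, v, s, r)."""

    u: float
    v: float
    s: float
    r: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.r > 0):
            raise InvalidMeasurementError(
                f"area and aspect ratio must be positive, got s={self.s}, r={self.r}"
            )


def box_to_measurement(b: Box) -> Measurement:
    """Convert a box to its (center-x, center-y, area, aspect) observation."""
    return Measurement(
        u=b.x + b.w / 2.0,
        v=b.y + b.h / 2.0,
        s=b.w * b.h,
        r=b.w / b.h,
    )


def measurement_to_box(m: Measurement, confidence: float | None = None) -> Box:
    """Invert :func:`box_to_measurement`.

    ``w = sqrt(s * r)`` and ``h = s / w`` recover width and height from area
    and aspect ratio; the round trip reproduces the box to floating tolerance.
    """
    if not (m.s > 0 and m.r > 0):
        raise InvalidMeasurementError(
            f"area and aspect ratio must be positive, got s={m.s}, r={m.r}"
        )
    w = math.sqrt(m.s * m.r)
    h = m.s / w
    return Box(x=m.u - w / 2.0, y=m.v - h / 2.0, w=w, h=h, confidence=confidence)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1].

    Symmetric; 0 for disjoint boxes, including boxes that merely share an
    edge (measure-zero overlap), and 1 only for identical boxes.
    """
    ix = min(a.x_right, b.x_right) - max(a.x, b.x)
    if ix <= 0.0:
        return 0.0
    iy = min(a.y_bottom, b.y_bottom) - max(a.y, b.y)
    if iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)
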