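"""Region-of-interest primitives shared by the stimulus decoder and the
fluorescence quantification.

Two ROI shapes are supported, mirroring what an experimenter draws in an
image viewer: ellipses (center + semi-axes) and arbitrary polygons.  A pixel
belongs to an ROI when its *center point* falls inside the shape; pixels whose
center lies exactly on a polygon edge are excluded (half-open convention), so
adjacent ROIs never double-count a pixel.

Coordinates are (x, y) with x = column, y = row, matching how drawing tools
report cursor positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import shapely


@dataclass(frozen=True)
class EllipseRoi:
    """Elliptical region: ``((x-cx)/rx)^2 + ((y-cy)/ry)^2 <= 1``."""

    center: Tuple[float, float]  # (x, y)
    radii: Tuple[float, float]  # (rx, ry)

    def __post_init__(self) -> None:
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValueError("ellipse radii must be positive")

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        h, w = shape
        cx, cy = self.center
        rx, ry = self.radii
        y, x = np.ogrid[:h, :w]
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0

    def bounds(self) -> Tuple[float, float, float, float]:
        cx, cy = self.center
        rx, ry = self.radii
        return (cx - rx, cy - ry, cx + rx, cy + ry)


@dataclass(frozen=True)
class PolygonRoi:
    """Polygonal region; vertices are (x, y) pairs, implicitly closed."""

    vertices: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        h, w = shape
        poly = shapely.Polygon(self.vertices)
        y, x = np.mgrid[:h, :w]
        # strict interior: boundary pixel-centers excluded
        return shapely.contains_xy(poly, x.ravel(), y.ravel()).reshape(h, w)

    def bounds(self) -> Tuple[float, float, float, float]:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (min(xs), min(ys), max(xs), max(ys))


Roi = Union[EllipseRoi, PolygonRoi]


def roi_union_mask(rois: Sequence[Roi], shape: Tuple[int, int]) -> np.ndarray:
    """Boolean union of several ROIs on an image grid."""
    if len(rois) == 0:
        raise ValueError("empty ROI list")
    out = np.zeros(shape, dtype=bool)
    for r in rois:
        out |= r.mask(shape)
    return out


def check_roi_in_bounds(roi: Roi, shape: Tuple[int, int]) -> None:
    """Raise if the ROI extends beyond the image."""
    x0, y0, x1, y1 = roi.bounds()
    h, w = shape
    if x0 < -0.5 or y0 < -0.5 or x1 > w - 0.5 or y1 > h - 0.5:
        raise ValueError(
            f"ROI bounds ({x0:.1f},{y0:.1f})-({x1:.1f},{y1:.1f}) exceed "
            f"image of size {w}x{h}"
        )
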