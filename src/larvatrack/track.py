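"""Single-object tracking over binary mask sequences.

Per frame, connected components of the mask are measured (area, centroid,
perimeter); components passing the size gates are candidates and the one
nearest the previously tracked centroid is linked to the track.  Frames with
no plausible candidate are marked invalid and their measurements left
missing — downstream code decides whether to interpolate.

Perimeter is the measurement of interest (it most reliably reflects larval
contraction), so its estimator matters: the boundary is traced as an
8-connected chain and its length computed with the corner-corrected weights
of Vossepoel & Smeulders (0.980 per axial step, 1.406 per diagonal step,
-0.091 per corner), which keeps the error on digitized disks of radius
10-50 under ~2 % — the plain 1/sqrt(2) chain length overestimates smooth
shapes by 5-6 %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TrackParams",
    "Component",
    "label_components",
    "measure_perimeter",
    "boundary_chain",
    "track_single",
]

logger = logging.getLogger(__name__)

# 8-connectivity structuring element: diagonal pixels belong to the same
# component (a contracted larva can be thin enough for this to matter).
_STRUCT8 = np.ones((3, 3), dtype=int)

# chain-code directions 0..7, clockwise from north, as (dy, dx)
_NEIGHBORS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)

# Vossepoel-Smeulders weights
_W_EVEN = 0.980
_W_ODD = 1.406
_W_CORNER = -0.091

#: Perimeter assigned to a single isolated pixel: the estimator's value for
#: the smallest closed chain of four axial steps with four corners.
SINGLE_PIXEL_PERIMETER = 4 * _W_EVEN + 4 * _W_CORNER


@dataclass(frozen=True)
class TrackParams:
    """Candidate gates: component area within [min_area, max_area] px^2 and
    per-frame centroid displacement at most max_jump px."""

    min_area: float = 100.0
    max_area: float = 1e5
    max_jump: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if self.max_jump <= 0:
            raise ValueError("max_jump must be positive")


@dataclass(frozen=True)
class Component:
    """One connected component of a binary mask."""

    label: int
    area: float  # px^2 (pixel count)
    centroid: Tuple[float, float]  # (x, y)
    perimeter: float  # px


def boundary_chain(mask: np.ndarray) -> np.ndarray:
    """8-connected chain code of a component's outer boundary (Moore
    tracing, clockwise, starting at the topmost-then-leftmost pixel).
    Returns an empty array for a single-pixel component."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty component")
    if ys.size == 1:
        return np.empty(0, dtype=np.intp)
    i = np.lexsort((xs, ys))[0]
    pad = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask
    start = (int(ys[i]) + 1, int(xs[i]) + 1)
    chain: List[int] = []
    cur = start
    search_start = 6  # first search direction: west (nothing lies north)
    limit = 8 * ys.size + 8
    while True:
        for k in range(8):
            d = (search_start + k) % 8
            dy, dx = _NEIGHBORS[d]
            ny, nx = cur[0] + dy, cur[1] + dx
            if pad[ny, nx]:
                chain.append(d)
                cur = (ny, nx)
                search_start = (d + 6) % 8  # backtrack direction + 2, clockwise
                break
        else:  # isolated pixel among scattered others
            return np.empty(0, dtype=np.intp)
        if cur == start and len(chain) >= 2:
            break
        if len(chain) > limit:  # pragma: no cover - defensive
            raise RuntimeError("boundary tracing did not close")
    return np.asarray(chain, dtype=np.intp)


def measure_perimeter(mask: np.ndarray) -> float:
    """Corner-corrected chain-code perimeter of a single component.

    For an axis-aligned w x h rectangle the chain has ``2(w+h) - 4`` axial
    steps and 4 corners, so the estimate is ``0.980*(2(w+h)-4) - 0.364``.
    A single pixel gets :data:`SINGLE_PIXEL_PERIMETER`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty component has no perimeter")
    chain = boundary_chain(mask)
    if chain.size == 0:
        return SINGLE_PIXEL_PERIMETER
    n_even = int(np.sum(chain % 2 == 0))
    n_odd = int(chain.size - n_even)
    n_corner = int(np.sum(chain != np.roll(chain, 1)))
    return _W_EVEN * n_even + _W_ODD * n_odd + _W_CORNER * n_corner


def label_components(mask: np.ndarray) -> List[Component]:
    """Measure the 8-connected components of a binary mask.

    Centroids are (x, y) pixel coordinates (mean of member pixel indices).
    An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    out: List[Component] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        sub = labels[sl] == lab
        ys, xs = np.nonzero(sub)
        area = float(ys.size)
        cy = float(ys.mean()) + sl[0].start
        cx = float(xs.mean()) + sl[1].start
        out.append(
            Component(
                label=lab,
                area=area,
                centroid=(cx, cy),
                perimeter=measure_perimeter(sub),
            )
        )
    return out


def track_single(
    masks: Sequence[np.ndarray],
    params: TrackParams = TrackParams(),
    fps: float = 10.0,
) -> pd.DataFrame:
    """Track one object through a sequence of binary masks.

    Columns: frame, time_s, area, perimeter, x, y, step_distance, valid.
    Invalid frames (no candidate within the gates, or the nearest candidate
    jumped implausibly far) carry NaN measurements.  ``max_jump`` is a
    per-frame allowance: after a gap of g invalid frames the gate widens to
    ``g * max_jump``.  The first valid frame seeds the track with the
    largest in-gate component and has step_distance 0.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = len(masks)
    area = np.full(n, np.nan)
    perim = np.full(n, np.nan)
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    step = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    prev_xy: Tuple[float, float] | None = None
    prev_frame = -1
    for t, mask in enumerate(masks):
        candidates = [
            c
            for c in label_components(mask)
            if params.min_area <= c.area <= params.max_area
        ]
        if not candidates:
            continue
        if prev_xy is None:
            chosen = max(candidates, key=lambda c: c.area)
            dist = 0.0
        else:
            dists = [
                float(np.hypot(c.centroid[0] - prev_xy[0], c.centroid[1] - prev_xy[1]))
                for c in candidates
            ]
            k = int(np.argmin(dists))
            chosen, dist = candidates[k], dists[k]
            gap = t - prev_frame
            if dist > params.max_jump * gap:
                continue
        area[t] = chosen.area
        perim[t] = chosen.perimeter
        xs[t], ys[t] = chosen.centroid
        step[t] = dist
        valid[t] = True
        prev_xy = chosen.centroid
        prev_frame = t

    if not valid.any():
        logger.warning("track_single: no frame produced a trackable object")
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / fps,
            "area": area,
            "perimeter": perim,
            "x": xs,
            "y": ys,
            "step_distance": step,
            "valid": valid,
        }
    )
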