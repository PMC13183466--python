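"""Mitochondrial-content quantification from two-channel fluorescence.

Motor-neuron terminals co-express a cytosolic marker (first channel) and a
mitochondrially targeted marker (second channel).  Mitochondrial content of
a terminal is the background-subtracted mean fluorescence of the
mitochondrial channel inside bouton ROIs divided by the same quantity in
the cytosolic channel — a ratio that cancels expression level and
illumination, so it is invariant to any gain applied equally to both
channels.

Workflow: average-project each z-stack to a single image, measure the mean
over the union of bouton ROIs minus the mean over adjacent background ROIs
in each channel, and divide.  Knockdown efficiency across groups of
terminals is reported as the percent reduction of the mean content relative
to a control group.

ROIs use pixel-center inclusion (see :mod:`larvatrack.roi`).  Aggregates of
either marker bias the ratio; avoiding them is the responsibility of ROI
placement, not of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .roi import EllipseRoi, PolygonRoi, Roi, check_roi_in_bounds, roi_union_mask

__all__ = [
    "RoiSet",
    "MitoContentResult",
    "project_average",
    "roi_background_subtracted_mean",
    "mitochondrial_content",
    "percent_reduction",
    "read_stack",
    "load_roi_set",
]


@dataclass(frozen=True)
class RoiSet:
    """Bouton ROIs plus background ROIs placed adjacent to the terminal."""

    bouton_rois: tuple
    background_rois: tuple

    def __post_init__(self) -> None:
        if len(self.bouton_rois) < 1 or len(self.background_rois) < 1:
            raise ValueError("need at least one bouton ROI and one background ROI")


@dataclass(frozen=True)
class MitoContentResult:
    """Background-subtracted channel means and their ratio for one
    terminal.  ``flagged`` marks a negative (sub-background) signal."""

    mito_signal: float
    cyto_signal: float
    content: float
    per_roi: pd.DataFrame = field(compare=False, repr=False, default=None)
    flagged: bool = False


def project_average(stack: Union[np.ndarray, Sequence[np.ndarray]]) -> np.ndarray:
    """Pixelwise mean across slices (average-intensity projection)."""
    if isinstance(stack, np.ndarray):
        if stack.ndim == 2:
            return stack.astype(float)
        if stack.ndim != 3:
            raise ValueError("expected a 2-D image or 3-D stack")
        return stack.mean(axis=0, dtype=float)
    slices = [np.asarray(s) for s in stack]
    if len(slices) == 0:
        raise ValueError("empty stack")
    if any(s.shape != slices[0].shape for s in slices):
        raise ValueError("stack slices have mismatched shapes")
    return np.mean(slices, axis=0, dtype=float)


def roi_background_subtracted_mean(
    image: np.ndarray,
    rois: RoiSet,
    mode: Literal["union", "per_roi"] = "union",
) -> float:
    """Mean over bouton ROIs minus mean over background ROIs.

    ``union`` pools all bouton pixels before averaging (default); ``per_roi``
    averages each bouton ROI separately and then averages those means.  A
    negative result (signal below background) is returned as-is — the
    caller decides whether that invalidates the terminal.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D image (project stacks first)")
    for r in (*rois.bouton_rois, *rois.background_rois):
        check_roi_in_bounds(r, image.shape)
    bg_mask = roi_union_mask(rois.background_rois, image.shape)
    if not bg_mask.any():
        raise ValueError("background ROI union covers no pixels")
    bg = float(image[bg_mask].mean())
    if mode == "union":
        fg_mask = roi_union_mask(rois.bouton_rois, image.shape)
        if not fg_mask.any():
            raise ValueError("bouton ROI union covers no pixels")
        fg = float(image[fg_mask].mean())
    elif mode == "per_roi":
        means = []
        for r in rois.bouton_rois:
            m = r.mask(image.shape)
            if not m.any():
                raise ValueError("a bouton ROI covers no pixels")
            means.append(float(image[m].mean()))
        fg = float(np.mean(means))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return fg - bg


def mitochondrial_content(
    cyto_image: np.ndarray,
    mito_image: np.ndarray,
    rois: RoiSet,
    mode: Literal["union", "per_roi"] = "union",
) -> MitoContentResult:
    """Content = background-subtracted mito mean / background-subtracted
    cyto mean.  The two channels must be registered (same shape); a
    non-positive cytosolic signal leaves the ratio undefined and raises."""
    cyto_image = np.asarray(cyto_image, dtype=float)
    mito_image = np.asarray(mito_image, dtype=float)
    if cyto_image.shape != mito_image.shape:
        raise ValueError("channel images are not registered (shapes differ)")
    cyto = roi_background_subtracted_mean(cyto_image, rois, mode=mode)
    mito = roi_background_subtracted_mean(mito_image, rois, mode=mode)
    if cyto <= 0:
        raise ValueError(
            f"cytosolic signal {cyto:.4g} is not positive; content undefined"
        )
    per_roi = pd.DataFrame(
        {
            "roi": range(len(rois.bouton_rois)),
            "cyto_mean": [
                float(cyto_image[r.mask(cyto_image.shape)].mean())
                for r in rois.bouton_rois
            ],
            "mito_mean": [
                float(mito_image[r.mask(mito_image.shape)].mean())
                for r in rois.bouton_rois
            ],
        }
    )
    return MitoContentResult(
        mito_signal=mito,
        cyto_signal=cyto,
        content=mito / cyto,
        per_roi=per_roi,
        flagged=mito < 0,
    )


def percent_reduction(
    test: Sequence[Union[MitoContentResult, float]],
    control: Sequence[Union[MitoContentResult, float]],
) -> float:
    """Percent reduction of mean content in a test group relative to a
    control group: ``100 * (1 - mean(test) / mean(control))``."""

    def contents(group) -> np.ndarray:
        vals = np.array(
            [g.content if isinstance(g, MitoContentResult) else float(g) for g in group]
        )
        if vals.size == 0:
            raise ValueError("empty group")
        return vals

    t = contents(test)
    c = contents(control)
    c_mean = float(c.mean())
    if c_mean <= 0:
        raise ValueError("control mean content must be positive")
    return 100.0 * (1.0 - float(t.mean()) / c_mean)


def read_stack(path: Union[str, Path]) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (slices, h, w) float stack."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret {path} as a grayscale stack")
    return arr.astype(float)


def load_roi_set(path: Union[str, Path]) -> RoiSet:
    """Read ROI definitions from JSON.

    Schema: ``{"bouton": [...], "background": [...]}`` where each entry is
    either ``{"type": "ellipse", "center": [x, y], "radii": [rx, ry]}`` or
    ``{"type": "polygon", "vertices": [[x, y], ...]}``.
    """
    import json

    with open(path) as fh:
        data = json.load(fh)

    def parse(entry) -> Roi:
        kind = entry.get("type")
        if kind == "ellipse":
            return EllipseRoi(
                center=tuple(entry["center"]), radii=tuple(entry["radii"])
            )
        if kind == "polygon":
            return PolygonRoi(vertices=tuple(tuple(v) for v in entry["vertices"]))
        raise ValueError(f"unknown ROI type {kind!r} in {path}")

    return RoiSet(
        bouton_rois=tuple(parse(e) for e in data.get("bouton", [])),
        background_rois=tuple(parse(e) for e in data.get("background", [])),
    )
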