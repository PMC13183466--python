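"""Frame preprocessing: the blur / background-subtraction / threshold chain
that turns a raw frame into a binary larva mask.

The chain reproduces a standard ImageJ recipe for isolating a dark larva on
a bright, unevenly illuminated agar plate:

1. Gaussian blur, radius 1 (sigma = radius; the radius-to-sigma convention
   is fixed here rather than inherited from any particular viewer version).
2. Rolling-ball background subtraction, radius 50 px.  The ball is rolled
   under the photometric inverse for dark-on-light scenes so the larva
   survives as a positive foreground residual.
3. Otsu threshold of the residual (or a fixed manual threshold).
4. Binarization; mask ``True`` = larva, whatever the display convention.

These defaults are a starting point: real recordings vary in illumination
and contrast, so every stage is exposed individually and the threshold can
be computed per frame (default) or frozen from a reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage import restoration, transform

__all__ = [
    "SegmentationParams",
    "gaussian_blur",
    "subtract_background",
    "otsu_threshold",
    "binarize",
    "segment_frame",
]

Polarity = Literal["dark_on_light", "light_on_dark"]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation chain. Defaults reproduce the
    blur-1 / ball-50 / Otsu recipe for a dark larva on a light background."""

    blur_radius: float = 1.0
    rolling_ball_radius: float = 50.0
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float = 0.0
    object_polarity: Polarity = "dark_on_light"

    def __post_init__(self) -> None:
        if self.blur_radius < 0:
            raise ValueError("blur_radius must be >= 0")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.object_polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError(f"unknown polarity {self.object_polarity!r}")


def gaussian_blur(frame: np.ndarray, radius: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with sigma = radius.

    Radius 0 returns the input unchanged (as float).  Borders use reflection
    so constant images stay constant and the kernel integrates to one.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if radius == 0:
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma=radius, mode="reflect")


def _white_level(frame: np.ndarray, original_dtype: np.dtype) -> float:
    if np.issubdtype(original_dtype, np.integer):
        return float(np.iinfo(original_dtype).max)
    return float(frame.max())


def _shrink_factor(ball_radius: float) -> int:
    # Large balls roll on a downsampled image; the background is smooth at
    # that scale so the speed-up costs little accuracy.
    if ball_radius < 16:
        return 1
    if ball_radius < 32:
        return 2
    if ball_radius < 100:
        return 4
    return 8


def subtract_background(
    frame: np.ndarray,
    ball_radius: float = 50.0,
    polarity: Polarity = "dark_on_light",
    exact: bool = False,
) -> np.ndarray:
    """Rolling-ball background subtraction.

    A ball of the given radius is rolled under the intensity surface; the
    surface it traces is the background estimate (a grayscale opening with a
    ball-shaped structuring element), which is subtracted so that objects
    smaller than the ball survive as a non-negative residual.  For
    ``dark_on_light`` the frame is photometrically inverted first, so the
    dark object becomes the positive foreground of the residual.

    For ``ball_radius >= 16`` the ball is rolled on a proportionally
    downsampled copy and the background is resampled back (``exact=True``
    disables this).  Output is float, clipped to non-negative, and never
    exceeds the input's dynamic range.
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    if ball_radius >= min(arr.shape):
        raise ValueError(
            f"ball_radius {ball_radius} does not fit inside frame {arr.shape}"
        )
    work = arr.astype(float)
    if polarity == "dark_on_light":
        work = _white_level(work, arr.dtype) - work
    elif polarity != "light_on_dark":
        raise ValueError(f"unknown polarity {polarity!r}")

    s = 1 if exact else _shrink_factor(ball_radius)
    if s == 1:
        background = _roll_ball_opening(work, ball_radius)
    else:
        small = transform.rescale(work, 1.0 / s, anti_aliasing=True, order=1)
        bg_small = _roll_ball_opening(small, ball_radius / s)
        background = transform.resize(bg_small, work.shape, order=1)
    background = np.minimum(background, work)
    return work - background


def _ball_structure(radius: float):
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (x * x + y * y).astype(float)
    fp = d2 <= radius * radius
    h = np.sqrt(np.clip(radius * radius - d2, 0, None))
    return np.where(fp, h - radius, -np.inf), fp


def _roll_ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a ball-shaped structuring element.

    The erosion pass is the classic rolling-ball lower envelope (the ball's
    apex as it rolls under the surface); the dilation pass lifts that
    envelope back onto the surface, so smooth backgrounds — including tilted
    planes — are reproduced exactly while objects narrower than the ball are
    removed.
    """
    struct, fp = _ball_structure(radius)
    ero = restoration.rolling_ball(img, radius=radius)
    return ndimage.grey_dilation(
        ero, structure=struct, footprint=fp, mode="constant", cval=-np.inf
    )


def otsu_threshold(frame: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of the intensity
    histogram (ties broken toward the lowest qualifying threshold).

    For 8-bit input the threshold is an integer gray level ``t`` with the
    dark class ``{v <= t}``.  Other dtypes are range-scaled onto ``nbins``
    histogram bins first and the chosen bin edge is mapped back to the
    original scale.  A constant image has no separating threshold and is an
    error.
    """
    arr = np.asarray(frame)
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmin == vmax:
        raise ValueError("constant image: no threshold separates two classes")
    if arr.dtype == np.uint8:
        levels = arr.ravel().astype(np.intp)
        scale = None
    else:
        scaled = (arr.astype(float) - vmin) / (vmax - vmin) * (nbins - 1)
        levels = np.clip(scaled.round().astype(np.intp), 0, nbins - 1).ravel()
        scale = (vmin, vmax)
    hist = np.bincount(levels, minlength=nbins).astype(float)
    n = hist.sum()
    omega0 = np.cumsum(hist) / n  # weight of class {v <= t}
    mu_t = np.cumsum(hist * np.arange(nbins)) / n
    mu = mu_t[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu * omega0 - mu_t) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    if scale is None:
        return float(t)
    vmin, vmax = scale
    return vmin + t / (nbins - 1) * (vmax - vmin)


def binarize(
    frame: np.ndarray, threshold: float, polarity: Polarity = "dark_on_light"
) -> np.ndarray:
    """Mask of object pixels: the class ``v <= threshold`` for dark objects,
    ``v > threshold`` for bright ones.  Foreground is always ``True``."""
    arr = np.asarray(frame)
    if polarity == "dark_on_light":
        return arr <= threshold
    if polarity == "light_on_dark":
        return arr > threshold
    raise ValueError(f"unknown polarity {polarity!r}")


def segment_frame(
    frame: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    frozen_threshold: Optional[float] = None,
) -> np.ndarray:
    """Full chain: blur -> background subtraction -> threshold -> binarize.

    After background subtraction the object is a positive residual whatever
    the input polarity, so the final binarization keeps the bright class.
    A frame with no residual structure (nothing above background) yields an
    empty mask rather than an error.  ``frozen_threshold`` bypasses the
    per-frame threshold with one computed on a reference frame.
    """
    blurred = gaussian_blur(frame, params.blur_radius)
    residual = subtract_background(
        blurred, params.rolling_ball_radius, params.object_polarity
    )
    if frozen_threshold is not None:
        thr = float(frozen_threshold)
    elif params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        if residual.max() == residual.min():
            return np.zeros(residual.shape, dtype=bool)
        thr = otsu_threshold(residual)
    return binarize(residual, thr, polarity="light_on_dark")
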