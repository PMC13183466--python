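"""Synthetic phantoms with programmed ground truth.

No public recordings of the assay exist, so validation runs on phantoms:
a dark elliptical "larva" on a brighter, linearly shaded background whose
major axis contracts in lock-step with a programmed light protocol, plus a
blinking indicator dot and optional additive Gaussian noise.  Everything is
driven by one seeded generator, so identical spec + seed gives bit-identical
output.

Ground truth carried alongside each video:

* the analytic ellipse perimeter of the instantaneous axes (Ramanujan's
  second approximation, whose error is orders of magnitude below pixel
  tolerance for the axis ratios used here);
* the programmed LED state per frame;
* the continuous body centroid.

Contraction dynamics are first-order: while the light is on the major axis
relaxes exponentially (time constant ``response_tau``) toward
``a0 * (1 - contraction_fraction)`` and back toward ``a0`` while off.  Real
larvae contract promptly and sustain contraction, so small ``response_tau``
emulates the observed behavior; the time constant stays a free parameter
because the true functional form is unknown.

The module also generates two-channel bouton image stacks for validating
the mitochondrial-content quantification, and trace-level phantoms
(perimeter time series with per-cycle amplitudes) for exercising the
metrics stage at scales where rendering video would be wasteful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io import FrameSequence
from .stimulus import StimulusProtocol, StimulusTrace, build_cycle_grid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "BoutonPhantom",
    "ellipse_perimeter",
    "render_phantom",
    "render_bouton_pair",
    "synthesize_perimeter_trace",
]


def ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    Relative error is below 1e-9 for the mild eccentricities of a larval
    body outline, far under the pixel-level tolerances used anywhere else.
    """
    if a < 0 or b < 0:
        raise ValueError("semi-axes must be non-negative")
    if a + b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render a synthetic larva video.

    Intensities are gray levels within the configured bit depth; the body
    must be darker than the background (the larva appears dark on a bright
    agar plate).  ``contraction_fraction`` is the fractional shortening of
    the semi-major axis at full contraction.
    """

    image_size: Tuple[int, int] = (120, 160)  # (height, width)
    fps: float = 10.0
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(total_s=70.0)
    )
    body_axes: Tuple[float, float] = (30.0, 9.0)  # (semi-major a0, semi-minor b0)
    contraction_fraction: float = 0.2
    response_tau: float = 0.2  # s
    drift_speed: float = 0.0  # px/s
    body_intensity: float = 60.0
    background_intensity: float = 180.0
    background_gradient: float = 40.0  # added linearly left -> right
    indicator_center: Tuple[float, float] = (12.0, 12.0)  # (x, y)
    indicator_radius: float = 3.0
    indicator_on_intensity: float = 255.0
    indicator_off_intensity: float = 90.0
    noise_sd: float = 0.0
    seed: int = 0
    bit_depth: int = 8

    def validate(self) -> None:
        h, w = self.image_size
        maxval = 2**self.bit_depth - 1
        if h < 8 or w < 8:
            raise ValueError("image too small")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 <= self.contraction_fraction < 1:
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.body_intensity >= self.background_intensity:
            raise ValueError("body must be darker than the background")
        for name in (
            "body_intensity",
            "background_intensity",
            "indicator_on_intensity",
            "indicator_off_intensity",
        ):
            v = getattr(self, name)
            if not 0 <= v <= maxval:
                raise ValueError(f"{name}={v} outside [0, {maxval}]")
        if self.background_intensity + max(self.background_gradient, 0) > maxval:
            raise ValueError("background shading exceeds the bit depth")
        if self.response_tau < 0 or self.noise_sd < 0 or self.drift_speed < 0:
            raise ValueError("response_tau, noise_sd, drift_speed must be >= 0")
        if self.indicator_radius <= 0:
            raise ValueError("indicator_radius must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.protocol.total_s * self.fps))


@dataclass
class PhantomTruth:
    """Per-frame ground truth of a rendered phantom."""

    perimeter_true: np.ndarray  # analytic ellipse perimeter, px
    led_state_true: np.ndarray  # bool
    centroid_true: np.ndarray  # (n, 2) of (x, y)
    axes_true: np.ndarray  # (n, 2) of (a, b), px


def _axis_series(spec: PhantomSpec, led: np.ndarray) -> np.ndarray:
    a0 = spec.body_axes[0]
    target_contracted = a0 * (1.0 - spec.contraction_fraction)
    dt = 1.0 / spec.fps
    decay = 0.0 if spec.response_tau == 0 else math.exp(-dt / spec.response_tau)
    a = np.empty(len(led))
    cur = a0
    for t, on in enumerate(led):
        target = target_contracted if on else a0
        cur = target + (cur - target) * decay
        a[t] = cur
    return a


def render_phantom(spec: PhantomSpec) -> Tuple[FrameSequence, PhantomTruth]:
    """Render the video and its ground truth.

    The body is an axis-aligned ellipse centered mid-frame (plus any drift,
    whose direction is drawn once from the seeded generator), filled with
    ``body_intensity`` over the shaded background; the indicator dot is
    drawn last at exactly the on/off intensity, so with ``noise_sd == 0``
    its mean is exact.  Gaussian noise is added to the whole frame and
    clipped to the valid gray range.  A body leaving the frame raises an
    error naming the first offending frame.
    """
    spec.validate()
    h, w = spec.image_size
    n = spec.n_frames
    maxval = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    rng = np.random.default_rng(spec.seed)

    times = np.arange(n) / spec.fps
    led = spec.protocol.led_state(times)
    a_series = _axis_series(spec, led)
    b0 = spec.body_axes[1]

    angle = rng.uniform(0, 2 * math.pi)  # drift direction, fixed per video
    drift = spec.drift_speed * np.stack(
        [times * math.cos(angle), times * math.sin(angle)], axis=1
    )
    center0 = np.array([w / 2.0, h / 2.0])
    centers = center0[None, :] + drift

    # bounds check before rendering anything
    for t in range(n):
        cx, cy = centers[t]
        a = a_series[t]
        if cx - a < 0 or cx + a > w - 1 or cy - b0 < 0 or cy + b0 > h - 1:
            raise ValueError(
                f"body leaves the frame at frame {t} "
                f"(center=({cx:.1f},{cy:.1f}), a={a:.1f})"
            )

    y, x = np.mgrid[:h, :w]
    background = spec.background_intensity + spec.background_gradient * (
        x / (w - 1)
    )
    icx, icy = spec.indicator_center
    indicator = (x - icx) ** 2 + (y - icy) ** 2 <= spec.indicator_radius**2
    if not indicator.any():
        raise ValueError("indicator dot covers no pixels")

    frames = np.empty((n, h, w), dtype=dtype)
    for t in range(n):
        img = background.copy()
        cx, cy = centers[t]
        body = ((x - cx) / a_series[t]) ** 2 + ((y - cy) / b0) ** 2 <= 1.0
        img[body] = spec.body_intensity
        img[indicator] = (
            spec.indicator_on_intensity if led[t] else spec.indicator_off_intensity
        )
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[t] = np.clip(np.rint(img), 0, maxval).astype(dtype)

    truth = PhantomTruth(
        perimeter_true=np.array([ellipse_perimeter(a, b0) for a in a_series]),
        led_state_true=led,
        centroid_true=centers,
        axes_true=np.stack([a_series, np.full(n, b0)], axis=1),
    )
    return FrameSequence(frames=frames, fps=spec.fps), truth


@dataclass
class BoutonPhantom:
    """Registered two-channel synthetic bouton stacks plus their truth."""

    cyto_stack: np.ndarray  # (slices, h, w)
    mito_stack: np.ndarray
    truth_ratio: float
    bouton_rois: list  # EllipseRoi per bouton
    background_roi: object  # EllipseRoi over empty background

    def roi_set(self):
        """The phantom's ROIs packaged for the quantification functions."""
        from .mito import RoiSet

        return RoiSet(
            bouton_rois=tuple(self.bouton_rois),
            background_rois=(self.background_roi,),
        )


def render_bouton_pair(
    mito_level: float,
    cyto_level: float,
    background_level: float = 20.0,
    n_boutons: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    image_size: Tuple[int, int] = (96, 96),
    bouton_radius: float = 5.0,
    n_slices: int = 3,
) -> BoutonPhantom:
    """Two registered channel stacks of disk-shaped boutons.

    Bouton pixels sit ``cyto_level`` (channel 1) and ``mito_level``
    (channel 2) above a uniform ``background_level`` before noise, so the
    true content ratio is ``mito_level / cyto_level``.  Bouton centers are
    jittered on a grid in the right half of the image, leaving the left
    margin free for the background ROI.
    """
    from .roi import EllipseRoi

    if cyto_level <= 0:
        raise ValueError("cyto_level must be positive (ratio undefined at 0)")
    if mito_level < 0 or background_level < 0:
        raise ValueError("levels must be non-negative")
    if n_boutons < 1:
        raise ValueError("need at least one bouton")
    h, w = image_size
    rng = np.random.default_rng(seed)

    # grid of candidate centers in the right two-thirds of the image
    margin = bouton_radius + 3
    x0 = w // 3
    pitch = int(math.ceil(2 * bouton_radius + 6))
    xs = np.arange(x0 + margin, w - margin, pitch)
    ys = np.arange(margin, h - margin, pitch)
    grid = [(float(cx), float(cy)) for cy in ys for cx in xs]
    if len(grid) < n_boutons:
        raise ValueError(f"image too small for {n_boutons} boutons")
    chosen = rng.choice(len(grid), size=n_boutons, replace=False)
    centers = [grid[i] for i in chosen]
    jitter = rng.uniform(-1.5, 1.5, size=(n_boutons, 2))

    yy, xx = np.mgrid[:h, :w]
    bouton_mask = np.zeros((h, w), dtype=bool)
    rois = []
    for (cx, cy), (jx, jy) in zip(centers, jitter):
        cx, cy = cx + jx, cy + jy
        bouton_mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= bouton_radius**2
        rois.append(EllipseRoi(center=(cx, cy), radii=(bouton_radius, bouton_radius)))

    def make_stack(level: float) -> np.ndarray:
        base = np.full((h, w), background_level, dtype=float)
        base[bouton_mask] += level
        stack = np.repeat(base[None], n_slices, axis=0)
        if noise_sd > 0:
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        return stack

    cyto = make_stack(cyto_level)
    mito = make_stack(mito_level)
    bg_roi = EllipseRoi(center=(x0 / 2.0, h / 2.0), radii=(x0 / 3.0, h / 3.0))
    return BoutonPhantom(
        cyto_stack=cyto,
        mito_stack=mito,
        truth_ratio=mito_level / cyto_level,
        bouton_rois=rois,
        background_roi=bg_roi,
    )


def synthesize_perimeter_trace(
    protocol: StimulusProtocol,
    fps: float = 10.0,
    rest_perimeter: float = 300.0,
    amplitudes: Union[float, Sequence[float]] = 0.2,
    response_tau: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, StimulusTrace]:
    """Trace-level phantom: a raw perimeter time series plus its stimulus
    trace, without rendering video.

    ``amplitudes`` gives the fractional perimeter drop per cycle (a scalar
    applies to every cycle); the contraction signal relaxes exponentially
    toward that drop during on-windows and back to rest during off-windows.
    Gaussian noise of ``noise_sd`` (in perimeter pixels) is added per frame.
    Returns a per-frame table with the same columns as the tracker output,
    so the normalization and cycle-metric stages consume it unchanged.
    """
    grid = build_cycle_grid(protocol)
    amps = np.broadcast_to(
        np.asarray(amplitudes, dtype=float).ravel()
        if np.ndim(amplitudes)
        else np.full(len(grid), float(amplitudes)),
        (len(grid),),
    )
    n = int(round(protocol.total_s * fps))
    times = np.arange(n) / fps
    led = protocol.led_state(times)

    # per-frame contraction target: cycle amplitude during on, 0 otherwise
    target = np.zeros(n)
    period = protocol.period_s
    rel = times - protocol.delay_s
    in_stim = rel >= 0
    cyc = np.zeros(n, dtype=int)
    cyc[in_stim] = np.minimum((rel[in_stim] / period).astype(int), len(grid) - 1)
    target[led] = amps[cyc[led]]

    dt = 1.0 / fps
    decay = 0.0 if response_tau == 0 else math.exp(-dt / response_tau)
    c = np.empty(n)
    cur = 0.0
    for t in range(n):
        cur = target[t] + (cur - target[t]) * decay
        c[t] = cur

    rng = np.random.default_rng(seed)
    perim = rest_perimeter * (1.0 - c)
    if noise_sd > 0:
        perim = perim + rng.normal(0.0, noise_sd, size=n)

    track = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": times,
            "area": np.full(n, np.nan),
            "perimeter": perim,
            "x": np.full(n, np.nan),
            "y": np.full(n, np.nan),
            "step_distance": np.zeros(n),
            "valid": np.ones(n, dtype=bool),
        }
    )
    stim = StimulusTrace(
        led_on=led,
        roi_mean=np.where(led, 255.0, 0.0),
        threshold_used=127.5,
    )
    return track, stim
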