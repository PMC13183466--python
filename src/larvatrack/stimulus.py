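"""Stimulus protocol arithmetic and indicator-LED decoding.

The assay drives larval motor neurons with a programmed blue-light cycle
(default: 10 s dark baseline, then 2 s on / 1 s off repeated for 20 minutes).
The camera cannot see the blue LEDs (a long-pass filter blocks them), so a
small red indicator LED wired to the same circuit is kept in frame; averaging
the pixels of an ROI placed over that indicator and thresholding the result
recovers the stimulus state for every frame.

This module owns:

* :class:`StimulusProtocol` — the programmed timing and its cycle grid;
* duty-cycle and metabolic-load arithmetic for comparing protocols with the
  ~78 % duty cycle of endogenous fictive locomotion;
* the indicator-ROI decoder and the alignment of the nominal cycle grid to
  the decoded trace (the recording starts asynchronously with the LED
  program, so the grid is shifted by the measured onset lag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .io import FrameSequence
from .roi import Roi

__all__ = [
    "StimulusProtocol",
    "StimulusTrace",
    "CycleWindow",
    "CycleFrames",
    "DutyCycle",
    "MetabolicLoad",
    "roi_mean_trace",
    "decode_led_status",
    "build_cycle_grid",
    "duty_cycle",
    "metabolic_load",
    "align_status",
]

#: Duty cycle of larval motor neurons during endogenous fictive locomotion.
ENDOGENOUS_DUTY_CYCLE_PERCENT = 78.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Programmed light protocol: ``delay_s`` of darkness, then cycles of
    ``on_s`` illumination followed by ``off_s`` rest, until ``total_s``.

    The default (10 + 400 * 3 s) gives 20 minutes of stimulation after the
    10 s baseline, i.e. 400 complete 2 s-on / 1 s-off cycles.
    """

    delay_s: float = 10.0
    on_s: float = 2.0
    off_s: float = 1.0
    total_s: float = 1210.0

    def __post_init__(self) -> None:
        if self.on_s <= 0:
            raise ValueError("on_s must be positive")
        if self.off_s < 0 or self.delay_s < 0:
            raise ValueError("off_s and delay_s must be non-negative")
        if self.total_s <= self.delay_s:
            raise ValueError("total_s must exceed delay_s")

    @property
    def period_s(self) -> float:
        return self.on_s + self.off_s

    @property
    def n_complete_cycles(self) -> int:
        return int(math.floor((self.total_s - self.delay_s) / self.period_s + 1e-9))

    def led_state(self, t: Union[float, np.ndarray]) -> np.ndarray:
        """Programmed LED state at time(s) ``t`` (seconds from recording
        start): off during the delay, then on for ``on_s`` of every period."""
        t = np.asarray(t, dtype=float)
        rel = t - self.delay_s
        state = (rel >= 0) & (np.mod(rel, self.period_s) < self.on_s - 1e-12)
        state &= t < self.total_s
        return state


@dataclass
class StimulusTrace:
    """Decoded per-frame stimulus state plus the evidence it came from."""

    led_on: np.ndarray  # bool, one per frame
    roi_mean: np.ndarray  # float, one per frame
    threshold_used: float

    def __post_init__(self) -> None:
        self.led_on = np.asarray(self.led_on, dtype=bool)
        self.roi_mean = np.asarray(self.roi_mean, dtype=float)
        if self.led_on.shape != self.roi_mean.shape:
            raise ValueError("led_on and roi_mean must have equal length")


@dataclass(frozen=True)
class CycleWindow:
    """One stimulation cycle: half-open on- and off-windows in seconds."""

    cycle_index: int  # 1-based
    on_window: Tuple[float, float]
    off_window: Tuple[float, float]


class CycleFrames(NamedTuple):
    """A cycle's windows mapped to half-open frame-index ranges."""

    cycle_index: int
    on_frames: Tuple[int, int]
    off_frames: Tuple[int, int]


class DutyCycle(NamedTuple):
    percent: float
    rounded: int


class MetabolicLoad(NamedTuple):
    percent: float
    rounded: int


def roi_mean_trace(frames: FrameSequence, roi: Roi) -> np.ndarray:
    """Mean intensity inside ``roi`` for every frame.

    This is the offline equivalent of averaging an ROI placed over the
    in-frame indicator LED during acquisition.
    """
    arr = frames.frames
    mask = roi.mask(arr.shape[1:])
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI covers no pixels")
    return arr[:, mask].mean(axis=1)


def _two_means(values: np.ndarray, max_iter: int = 100) -> Tuple[float, float, np.ndarray]:
    """Deterministic 1-D two-class Lloyd clustering, initialised at the
    extremes. Returns (low_center, high_center, assignment-to-high)."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("trace is constant; cannot cluster into two classes")
    for _ in range(max_iter):
        assign_hi = np.abs(values - hi) < np.abs(values - lo)
        if assign_hi.all() or (~assign_hi).all():
            break
        new_lo = float(values[~assign_hi].mean())
        new_hi = float(values[assign_hi].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi, assign_hi


def decode_led_status(
    roi_trace: Sequence[float],
    threshold: Union[float, str] = "auto",
) -> StimulusTrace:
    """Threshold the indicator-ROI trace into a per-frame on/off record.

    A frame counts as "on" when its ROI mean is strictly greater than the
    threshold (boundary frames count as off).  In ``"auto"`` mode the
    threshold is the midpoint between the two plateau levels found by
    two-class clustering of the trace; if the trace does not separate into
    two plateaus (the LED never blinked) an error asks for a manual
    threshold.
    """
    trace = np.asarray(roi_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty ROI trace")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        try:
            lo, hi, assign_hi = _two_means(trace)
        except ValueError as exc:
            raise ValueError(
                "indicator trace is unimodal (LED never blinked?); "
                "supply a manual threshold"
            ) from exc
        sd_lo = float(trace[~assign_hi].std()) if (~assign_hi).any() else 0.0
        sd_hi = float(trace[assign_hi].std()) if assign_hi.any() else 0.0
        if hi - lo <= 2.0 * (sd_lo + sd_hi):
            raise ValueError(
                "indicator trace plateaus are not separable "
                f"(centers {lo:.3g}/{hi:.3g}); supply a manual threshold"
            )
        thr = 0.5 * (lo + hi)
    else:
        thr = float(threshold)
    return StimulusTrace(led_on=trace > thr, roi_mean=trace, threshold_used=thr)


def build_cycle_grid(protocol: StimulusProtocol) -> List[CycleWindow]:
    """Enumerate the complete stimulation cycles of a protocol.

    Cycle k (1-based) occupies ``[delay + (k-1)*period, delay + k*period)``,
    split into its on-window then off-window.  Only complete cycles are
    returned; zero complete cycles is an error.
    """
    n = protocol.n_complete_cycles
    if n < 1:
        raise ValueError(
            f"protocol of {protocol.total_s} s holds no complete "
            f"{protocol.period_s} s cycle after the {protocol.delay_s} s delay"
        )
    grid: List[CycleWindow] = []
    for k in range(1, n + 1):
        start = protocol.delay_s + (k - 1) * protocol.period_s
        grid.append(
            CycleWindow(
                cycle_index=k,
                on_window=(start, start + protocol.on_s),
                off_window=(start + protocol.on_s, start + protocol.period_s),
            )
        )
    return grid


def duty_cycle(protocol_or_on: Union[StimulusProtocol, float], off_s: Optional[float] = None) -> DutyCycle:
    """Percent of each cycle during which the stimulus is on.

    Accepts either a :class:`StimulusProtocol` or explicit ``(on_s, off_s)``
    durations.  Returns the raw percentage and its nearest-integer rounding
    (2 s on / 1 s off -> 66.67, reported as 67).
    """
    if isinstance(protocol_or_on, StimulusProtocol):
        on_s, off_s = protocol_or_on.on_s, protocol_or_on.off_s
    else:
        on_s = float(protocol_or_on)
        if off_s is None:
            raise ValueError("off_s required when passing a bare on-duration")
    if on_s + off_s <= 0:
        raise ValueError("cycle period must be positive")
    pct = 100.0 * on_s / (on_s + off_s)
    return DutyCycle(percent=pct, rounded=int(round(pct)))


def metabolic_load(
    assay_duty_percent: float,
    endogenous_duty_percent: float = ENDOGENOUS_DUTY_CYCLE_PERCENT,
) -> MetabolicLoad:
    """Time-averaged metabolic load of the assay relative to endogenous
    locomotion: assay duty cycle divided by the endogenous motor-neuron duty
    cycle, as a percentage (67 / 78 -> ~86 %)."""
    if endogenous_duty_percent <= 0:
        raise ValueError("endogenous duty cycle must be positive")
    pct = 100.0 * assay_duty_percent / endogenous_duty_percent
    return MetabolicLoad(percent=pct, rounded=int(round(pct)))


def _window_to_frames(start_s: float, end_s: float, fps: float) -> Tuple[int, int]:
    eps = 1e-9
    return (int(math.ceil(start_s * fps - eps)), int(math.ceil(end_s * fps - eps)))


def align_status(
    led: StimulusTrace,
    grid: Sequence[CycleWindow],
    fps: float,
    compensate_lag: bool = True,
) -> Tuple[List[CycleFrames], float]:
    """Map cycle windows onto frame indices, compensating the onset lag.

    The LED program starts asynchronously with the recording, so the nominal
    first on-time of the grid rarely matches the first decoded on-frame.  The
    lag between them is measured and (by default) the whole grid is shifted
    by it.  Returns the per-cycle frame windows and the measured lag in
    seconds.  A lag exceeding one full cycle indicates a protocol/video
    mismatch and is an error.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    on_idx = np.flatnonzero(led.led_on)
    if on_idx.size == 0:
        raise ValueError("decoded trace contains no on-frames")
    nominal_first_on = grid[0].on_window[0]
    measured_first_on = float(on_idx[0]) / fps
    lag = measured_first_on - nominal_first_on
    period = grid[0].off_window[1] - grid[0].on_window[0]
    if abs(lag) > period:
        raise ValueError(
            f"measured onset lag {lag:.3f} s exceeds one cycle ({period:.3f} s); "
            "protocol and video appear mismatched"
        )
    shift = lag if compensate_lag else 0.0
    out: List[CycleFrames] = []
    n_frames = len(led.led_on)
    for cw in grid:
        on_f = _window_to_frames(cw.on_window[0] + shift, cw.on_window[1] + shift, fps)
        off_f = _window_to_frames(cw.off_window[0] + shift, cw.off_window[1] + shift, fps)
        if on_f[0] >= n_frames:
            break
        out.append(CycleFrames(cw.cycle_index, on_f, off_f))
    return out, lag
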