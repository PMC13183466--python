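"""Contraction and fatigue metrics over normalized perimeter traces.

A larva's raw perimeter depends on its size and posture, so every trace is
first divided by its mean perimeter over the 2 s window immediately before
the first light pulse; cross-animal comparisons then operate on the
dimensionless normalized perimeter.

Per stimulation cycle the quantities of interest are:

* ``rest_value`` — mean normalized perimeter over the trailing portion of
  the preceding off-window (the larva relaxes while the light is off); the
  first cycle rests at the pre-stimulus baseline, i.e. 1.0;
* ``max_contraction_value`` — the minimum normalized perimeter inside the
  on-window (contraction shortens the outline, so "maximum contraction"
  means minimum perimeter);
* ``amplitude`` — rest minus maximum contraction, positive for a larva that
  contracts.

Fatigue is summarized by comparing the mean amplitude of the first k cycles
against the last k (default k = 3), and groups of larvae by an equal-
variance two-sided Student's t-test on their per-larva amplitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import CycleWindow, StimulusTrace

__all__ = [
    "NormalizedTrace",
    "FatigueSummary",
    "BoxSummary",
    "GroupResult",
    "Epoch",
    "normalize_trace",
    "cycle_metrics",
    "epoch_extract",
    "fatigue_comparison",
    "group_average_trace",
    "two_group_test",
]

logger = logging.getLogger(__name__)

BASELINE_LEN_S = 2.0  # pre-stimulus baseline window length


@dataclass
class NormalizedTrace:
    """Perimeter trace divided by its pre-stimulus baseline mean."""

    time_s: np.ndarray
    perimeter_norm: np.ndarray  # NaN where the frame was invalid
    led_on: np.ndarray
    baseline_value: float
    baseline_window: Tuple[float, float]
    fps: float

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class Epoch:
    """A short sub-trace cut from a long recording."""

    start_s: float
    time_s: np.ndarray
    perimeter_norm: np.ndarray
    is_first: bool
    is_last: bool
    truncated: bool


@dataclass(frozen=True)
class FatigueSummary:
    k: int
    first_k_amplitude: float
    last_k_amplitude: float
    difference: float  # first - last (positive = fatigue)
    ratio: float  # last / first


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary: mean, median, quartile box, 10-90 % whiskers."""

    n: int
    mean: float
    median: float
    q25: float
    q75: float
    whisker_lo: float  # 10th percentile
    whisker_hi: float  # 90th percentile


@dataclass(frozen=True)
class GroupResult:
    label_a: str
    label_b: str
    summary_a: BoxSummary
    summary_b: BoxSummary
    t_statistic: float
    p_value: float
    equal_var: bool


def normalize_trace(
    track: pd.DataFrame,
    led: StimulusTrace,
    fps: float,
    baseline_len_s: float = BASELINE_LEN_S,
) -> NormalizedTrace:
    """Divide the perimeter trace by its mean over the pre-stimulus window
    ``[t_first_on - baseline_len_s, t_first_on)``.

    Invalid frames stay missing (NaN).  An empty or non-positive baseline is
    an error: without it traces from different larvae are not comparable.
    """
    if len(track) != len(led.led_on):
        raise ValueError("track and LED trace lengths differ")
    on_idx = np.flatnonzero(led.led_on)
    if on_idx.size == 0:
        raise ValueError("LED trace contains no on-frames; cannot locate baseline")
    t_first_on = on_idx[0] / fps
    t0 = t_first_on - baseline_len_s
    time_s = track["time_s"].to_numpy(dtype=float)
    perim = track["perimeter"].to_numpy(dtype=float)
    in_window = (time_s >= t0 - 1e-9) & (time_s < t_first_on - 1e-9)
    window_vals = perim[in_window & ~np.isnan(perim)]
    if window_vals.size == 0:
        raise ValueError(
            f"no valid frames in baseline window [{t0:.3f}, {t_first_on:.3f}) s"
        )
    baseline = float(window_vals.mean())
    if baseline <= 0:
        raise ValueError(f"baseline perimeter {baseline} is not positive")
    return NormalizedTrace(
        time_s=time_s,
        perimeter_norm=perim / baseline,
        led_on=np.asarray(led.led_on, dtype=bool),
        baseline_value=baseline,
        baseline_window=(t0, t_first_on),
        fps=fps,
    )


def _frames_in(norm: NormalizedTrace, start_s: float, end_s: float) -> np.ndarray:
    return np.flatnonzero(
        (norm.time_s >= start_s - 1e-9) & (norm.time_s < end_s - 1e-9)
    )


def _fill_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation of interior NaN runs of length <= max_gap;
    longer runs are left entirely missing (we do not invent data across
    long dropouts, and we never fill a long run partially)."""
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    runs = np.split(np.flatnonzero(isnan), np.flatnonzero(np.diff(np.flatnonzero(isnan)) > 1) + 1)
    for run in runs:
        if run.size == 0 or run.size > max_gap:
            continue
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(v) or np.isnan(v[lo]) or np.isnan(v[hi]):
            continue
        v[run] = np.interp(run, [lo, hi], [v[lo], v[hi]])
    return v


def cycle_metrics(
    norm: NormalizedTrace,
    grid: Sequence[CycleWindow],
    rest_fraction: float = 0.5,
    max_gap_frames: int = 3,
    lag_s: float = 0.0,
) -> pd.DataFrame:
    """Per-cycle rest value, maximum contraction, and amplitude.

    ``grid`` is the protocol cycle grid in seconds; ``lag_s`` shifts it onto
    the trace (use the lag measured by ``stimulus.align_status``).
    ``rest_fraction`` is the trailing fraction of the preceding off-window
    averaged into the rest value (the larva needs the start of the off phase
    to relax).  Cycles whose on-window has no valid frame get NaN metrics
    and ``flagged=True`` — they are reported, never silently dropped.
    """
    if not 0 < rest_fraction <= 1:
        raise ValueError("rest_fraction must be in (0, 1]")
    filled = _fill_short_gaps(norm.perimeter_norm, max_gap_frames)
    rows = []
    prev_off: Optional[Tuple[float, float]] = None
    for cw in grid:
        on0, on1 = cw.on_window[0] + lag_s, cw.on_window[1] + lag_s
        if on0 >= norm.time_s[-1] + 0.5 / norm.fps:
            break
        flagged = False
        if prev_off is None:
            rest = 1.0  # first cycle rests at the pre-stimulus baseline
        else:
            off0, off1 = prev_off
            r0 = off1 - rest_fraction * (off1 - off0)
            idx = _frames_in(norm, r0, off1)
            vals = filled[idx]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                rest, flagged = np.nan, True
            else:
                rest = float(vals.mean())
        on_idx = _frames_in(norm, on0, on1)
        on_vals = filled[on_idx]
        # a gap longer than max_gap_frames inside the on-window invalidates
        # the cycle: the extremum could hide in the dropout
        if on_idx.size == 0 or np.isnan(on_vals).any():
            on_vals = on_vals[~np.isnan(on_vals)]
            maxc = np.nan
            flagged = True
        else:
            maxc = float(on_vals.min())
        rows.append(
            {
                "cycle_index": cw.cycle_index,
                "rest_value": rest,
                "max_contraction_value": maxc,
                "amplitude": rest - maxc if not (np.isnan(rest) or np.isnan(maxc)) else np.nan,
                "n_valid_frames": int(on_vals.size),
                "flagged": flagged,
            }
        )
        prev_off = (cw.off_window[0] + lag_s, cw.off_window[1] + lag_s)
    return pd.DataFrame(rows)


def epoch_extract(
    norm: NormalizedTrace,
    epoch_len_s: float = 20.0,
    every_s: float = 120.0,
    start_s: Optional[float] = None,
) -> List[Epoch]:
    """Cut fixed-length epochs sampled at regular intervals.

    Epoch k starts at ``start_s + k * every_s`` (default start: the first
    decoded light onset).  The first and last epochs are flagged for
    highlighting; a final epoch truncated by the end of the trace is
    flagged as such.
    """
    duration = norm.time_s[-1] - norm.time_s[0]
    if epoch_len_s > duration:
        raise ValueError(
            f"epoch length {epoch_len_s} s exceeds trace duration {duration:.1f} s"
        )
    if start_s is None:
        on_idx = np.flatnonzero(norm.led_on)
        start_s = on_idx[0] / norm.fps if on_idx.size else norm.time_s[0]
    starts = []
    t = start_s
    while t <= norm.time_s[-1] - epoch_len_s + 1e-9:
        starts.append(t)
        t += every_s
    # a final, truncated epoch if the stride lands past the end but data remain
    truncated_start = None
    if t < norm.time_s[-1] and starts and t - every_s + epoch_len_s < norm.time_s[-1]:
        truncated_start = t
    epochs: List[Epoch] = []
    all_starts = starts + ([truncated_start] if truncated_start is not None else [])
    for i, s in enumerate(all_starts):
        idx = _frames_in(norm, s, s + epoch_len_s)
        epochs.append(
            Epoch(
                start_s=float(s),
                time_s=norm.time_s[idx],
                perimeter_norm=norm.perimeter_norm[idx],
                is_first=(i == 0),
                is_last=(i == len(all_starts) - 1),
                truncated=(s == truncated_start),
            )
        )
    return epochs


def fatigue_comparison(cycles: pd.DataFrame, k: int = 3) -> FatigueSummary:
    """Mean amplitude of the first k vs the last k complete cycles.

    Cycles with missing amplitude are excluded from "complete"; fewer than
    2k complete cycles is an error (the windows would overlap).
    """
    amps = cycles.loc[~cycles["amplitude"].isna(), "amplitude"].to_numpy()
    if len(amps) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} complete cycles, have {len(amps)}"
        )
    first = float(amps[:k].mean())
    last = float(amps[-k:].mean())
    return FatigueSummary(
        k=k,
        first_k_amplitude=first,
        last_k_amplitude=last,
        difference=first - last,
        ratio=last / first if first != 0 else np.nan,
    )


def group_average_trace(
    traces: Sequence[NormalizedTrace],
    truncate_s: Optional[float] = None,
) -> pd.DataFrame:
    """Pointwise mean and sample standard deviation across larvae.

    Traces must share the frame rate; they are aligned on frame index and
    truncated to the shortest (or to ``truncate_s``).  Missing frames are
    ignored pointwise, so each timepoint reports its own n.  With a single
    trace the mean is returned and dispersion left missing (warning).
    """
    if len(traces) == 0:
        raise ValueError("no traces")
    fps = traces[0].fps
    if any(abs(tr.fps - fps) > 1e-9 for tr in traces):
        raise ValueError("traces have differing frame rates")
    n_common = min(tr.n_frames for tr in traces)
    if truncate_s is not None:
        n_common = min(n_common, int(round(truncate_s * fps)))
    stack = np.vstack([tr.perimeter_norm[:n_common] for tr in traces])
    n_per_point = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    if len(traces) < 2:
        logger.warning("group_average_trace: single trace, dispersion undefined")
        sd = np.full(n_common, np.nan)
    else:
        sd = np.full(n_common, np.nan)
        ok = n_per_point >= 2
        sd[ok] = np.nanstd(stack[:, ok], axis=0, ddof=1)
    return pd.DataFrame(
        {
            "time_s": traces[0].time_s[:n_common],
            "mean": mean,
            "sd": sd,
            "n": n_per_point,
        }
    )


def _box_summary(x: np.ndarray) -> BoxSummary:
    return BoxSummary(
        n=len(x),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        q25=float(np.percentile(x, 25)),
        q75=float(np.percentile(x, 75)),
        whisker_lo=float(np.percentile(x, 10)),
        whisker_hi=float(np.percentile(x, 90)),
    )


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = True,
) -> GroupResult:
    """Two-sided Student's t-test (pooled variance by default; Welch via
    ``equal_var=False``) on per-larva amplitude summaries, plus the
    box-plot quantities for each group.

    Degenerate inputs are handled explicitly: identical zero-variance
    groups give t = 0, p = 1; zero-variance groups with different means
    give p at the smallest positive float rather than a numerical failure.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # zero variance in both groups
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = math.inf if np.mean(a) > np.mean(b) else -math.inf
            p = float(np.finfo(float).tiny)
    elif p == 0.0:
        p = float(np.finfo(float).tiny)
    return GroupResult(
        label_a=label_a,
        label_b=label_b,
        summary_a=_box_summary(a),
        summary_b=_box_summary(b),
        t_statistic=t,
        p_value=p,
        equal_var=equal_var,
    )
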