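"""End-to-end pipeline: video (or phantom) -> per-cycle contraction metrics.

The configuration object captures every knob of the chain — segmentation,
tracking, indicator ROI, stimulus protocol, metric options — and round-trips
losslessly through YAML, so a run is fully described by its config file plus
the seed.  ``run_pipeline`` executes

    segment -> track -> decode LED -> align grid -> normalize -> cycle metrics

and writes the per-frame table, the per-cycle table, and a run log recording
the package version, a hash of the config, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import FrameSequence, read_video, write_aligned_csv, write_frames, write_truth_csv
from .metrics import NormalizedTrace, cycle_metrics, fatigue_comparison, normalize_trace
from .phantom import PhantomSpec, PhantomTruth, render_phantom
from .preprocess import SegmentationParams, segment_frame
from .roi import EllipseRoi
from .stimulus import (
    StimulusProtocol,
    StimulusTrace,
    align_status,
    build_cycle_grid,
    decode_led_status,
    roi_mean_trace,
)
from .track import TrackParams, track_single

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce an analysis run."""

    video_path: Optional[str] = None  # AVI / TIFF / frame directory
    phantom: Optional[PhantomSpec] = None  # alternative to video_path
    fps: float = 10.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackParams = field(default_factory=TrackParams)
    indicator_center: Tuple[float, float] = (12.0, 12.0)  # (x, y)
    indicator_radius: float = 3.0
    led_threshold: Union[float, str] = "auto"
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    rest_fraction: float = 0.5
    fatigue_k: int = 3
    max_gap_frames: int = 3
    compensate_lag: bool = True
    freeze_threshold: bool = False  # Otsu once on frame 0 instead of per frame
    output_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.video_path is None and self.phantom is None:
            raise ValueError("config needs either video_path or a phantom spec")
        if self.video_path is not None and not Path(self.video_path).exists():
            raise FileNotFoundError(f"video source not found: {self.video_path}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.fatigue_k < 1:
            raise ValueError("fatigue_k must be >= 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            ph = dict(d["phantom"])
            if "protocol" in ph and ph["protocol"] is not None:
                ph["protocol"] = StimulusProtocol(**ph["protocol"])
            for key in ("image_size", "body_axes", "indicator_center"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomSpec(**ph)
        if d.get("segmentation") is not None and not isinstance(
            d["segmentation"], SegmentationParams
        ):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if d.get("tracking") is not None and not isinstance(d["tracking"], TrackParams):
            d["tracking"] = TrackParams(**d["tracking"])
        if d.get("protocol") is not None and not isinstance(
            d["protocol"], StimulusProtocol
        ):
            d["protocol"] = StimulusProtocol(**d["protocol"])
        if d.get("indicator_center") is not None:
            d["indicator_center"] = tuple(d["indicator_center"])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of everything a run produced."""

    track: pd.DataFrame
    stimulus: StimulusTrace
    normalized: NormalizedTrace
    cycles: pd.DataFrame
    fatigue: Optional[object]
    lag_s: float
    truth: Optional[PhantomTruth] = None
    output_dir: Optional[Path] = None


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis chain described by ``config``.

    Stage failures surface with the stage name and frame/cycle context.
    When the source is a phantom spec, the rendered ground truth rides along
    in the result for validation.
    """
    config.validate()
    truth = None
    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, seed=config.seed)
        frames, truth = render_phantom(spec)
        indicator = EllipseRoi(
            center=spec.indicator_center,
            radii=(spec.indicator_radius, spec.indicator_radius),
        )
        protocol = spec.protocol
        fps = spec.fps
    else:
        frames = read_video(config.video_path, fps=config.fps)
        indicator = EllipseRoi(
            center=config.indicator_center,
            radii=(config.indicator_radius, config.indicator_radius),
        )
        protocol = config.protocol
        fps = frames.fps

    # segmentation (exclude the indicator dot region from the masks so a
    # bright indicator never competes with the larva)
    ind_mask = indicator.mask(frames.frames.shape[1:])
    frozen_thr = None
    masks = []
    for t in range(frames.n_frames):
        try:
            mask = segment_frame(
                frames.frames[t], config.segmentation, frozen_threshold=frozen_thr
            )
            if config.freeze_threshold and t == 0 and frozen_thr is None:
                from .preprocess import gaussian_blur, otsu_threshold, subtract_background

                residual = subtract_background(
                    gaussian_blur(frames.frames[0], config.segmentation.blur_radius),
                    config.segmentation.rolling_ball_radius,
                    config.segmentation.object_polarity,
                )
                frozen_thr = otsu_threshold(residual)
        except Exception as exc:
            raise RuntimeError(f"segmentation failed at frame {t}: {exc}") from exc
        mask[ind_mask] = False
        masks.append(mask)

    track = track_single(masks, config.tracking, fps=fps)

    try:
        roi_trace = roi_mean_trace(frames, indicator)
        stim = decode_led_status(roi_trace, threshold=config.led_threshold)
    except Exception as exc:
        raise RuntimeError(f"LED decoding failed: {exc}") from exc

    grid = build_cycle_grid(protocol)
    try:
        _, lag = align_status(stim, grid, fps, compensate_lag=config.compensate_lag)
    except Exception as exc:
        raise RuntimeError(f"grid alignment failed: {exc}") from exc
    lag_used = lag if config.compensate_lag else 0.0

    try:
        norm = normalize_trace(track, stim, fps)
    except Exception as exc:
        raise RuntimeError(f"normalization failed: {exc}") from exc

    cycles = cycle_metrics(
        norm,
        grid,
        rest_fraction=config.rest_fraction,
        max_gap_frames=config.max_gap_frames,
        lag_s=lag_used,
    )
    n_flagged = int(cycles["flagged"].sum())
    if n_flagged:
        logger.warning("run_pipeline: %d cycle(s) flagged incomplete", n_flagged)

    fatigue = None
    n_complete = int((~cycles["amplitude"].isna()).sum())
    if n_complete >= 2 * config.fatigue_k:
        fatigue = fatigue_comparison(cycles, k=config.fatigue_k)

    outdir = None
    if write_outputs and config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_aligned_csv(track, stim, outdir / "per_frame.csv")
        cycles.to_csv(outdir / "per_cycle.csv", index=False, float_format="%.6f")
        norm_df = pd.DataFrame(
            {
                "time_s": np.round(norm.time_s, 3),
                "perimeter_norm": norm.perimeter_norm,
                "led_on": norm.led_on.astype(int),
            }
        )
        norm_df.to_csv(outdir / "normalized_trace.csv", index=False, float_format="%.6f")
        if truth is not None:
            write_truth_csv(truth, fps, outdir / "truth.csv")
        log = {
            "larvatrack_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "lag_s": round(float(lag), 4),
            "n_frames": frames.n_frames,
            "n_cycles": len(cycles),
            "n_flagged_cycles": n_flagged,
            "config": config.to_dict(),
        }
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)

    return PipelineResult(
        track=track,
        stimulus=stim,
        normalized=norm,
        cycles=cycles,
        fatigue=fatigue,
        lag_s=lag,
        truth=truth,
        output_dir=outdir,
    )
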