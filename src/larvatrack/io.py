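"""Video and table input/output.

The recording side of the assay produces an AVI plus a per-frame CSV of the
indicator-LED state; offline analysis consumes grayscale frames.  Here we
read either an AVI (when an imageio video backend is available), a
multi-page TIFF, or a directory of numbered image frames, and write the
per-frame results table that mirrors the acquisition CSV contract: one row
per frame with the tracked measurements aligned to the decoded light status.

Color input is converted to grayscale with the Rec. 601 luminance weights
(0.299 R + 0.587 G + 0.114 B).  Frame indices are 0-based and timestamps are
``frame_index / fps`` seconds, written with 3-decimal precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameSequence",
    "read_video",
    "write_frames",
    "write_truth_csv",
    "write_aligned_csv",
    "read_aligned_csv",
    "rgb_to_gray",
]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")

#: Rec. 601 luminance weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """A stack of timestamped grayscale frames at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse a trailing color axis with Rec. 601 luminance weights."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].astype(float) @ _LUMA
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as image")


def read_video(path: Union[str, Path], fps: Optional[float] = None) -> FrameSequence:
    """Read an AVI, a multi-page TIFF, or a directory of numbered frames.

    ``fps`` overrides container metadata; it is required for frame
    directories and TIFFs, which carry no frame rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video source not found: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no image frames found in directory {path}")
        frames = np.stack([rgb_to_gray(iio.imread(f)) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        frames = np.stack([rgb_to_gray(f) for f in arr])
    else:
        try:
            arr = iio.imread(path, plugin="pyav")
        except Exception:
            try:
                arr = iio.imread(path)
            except Exception as exc:
                raise ValueError(
                    f"cannot read video container {path}: no imageio backend "
                    "accepted it (install imageio-ffmpeg/pyav for AVI support, "
                    "or supply a frame directory / TIFF stack)"
                ) from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            arr = arr[None]
        frames = np.stack([rgb_to_gray(f) for f in arr])
        if fps is None:
            try:
                meta = iio.immeta(path)
                fps = float(meta.get("fps")) if meta.get("fps") else None
            except Exception:
                fps = None
    if fps is None:
        raise ValueError(
            f"frame rate unknown for {path}; pass fps= explicitly"
        )
    return FrameSequence(frames=frames, fps=float(fps))


def write_frames(seq: FrameSequence, path: Union[str, Path]) -> Path:
    """Write frames either as a numbered PNG directory (default) or, when
    ``path`` ends in ``.avi``, via an imageio video backend if one is
    installed."""
    path = Path(path)
    if path.suffix.lower() == ".avi":
        try:
            iio.imwrite(path, seq.frames.astype(np.uint8), fps=seq.fps)
        except Exception as exc:
            raise ValueError(
                f"no imageio video backend available to write {path}; "
                "write a PNG frame directory instead"
            ) from exc
        return path
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame.astype(np.uint8))
    return path


def write_truth_csv(truth, fps: float, path: Union[str, Path]) -> Path:
    """Write a phantom's ground truth: one row per frame."""
    path = Path(path)
    n = len(truth.perimeter_true)
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.round(np.arange(n) / fps, 3),
            "perimeter_true": truth.perimeter_true,
            "led_state_true": truth.led_state_true.astype(int),
            "centroid_x": truth.centroid_true[:, 0],
            "centroid_y": truth.centroid_true[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


#: Fixed column order of the per-frame results table.
ALIGNED_CSV_COLUMNS = [
    "frame",
    "time_s",
    "perimeter",
    "area",
    "step_distance",
    "roi_mean",
    "led_on",
    "valid",
]


def write_aligned_csv(track: pd.DataFrame, led, path: Union[str, Path]) -> Path:
    """One row per frame: tracked measurements aligned with the decoded
    light status (the offline analogue of the acquisition CSV).

    ``track`` is the per-frame table from :func:`larvatrack.track.track_single`;
    ``led`` a :class:`larvatrack.stimulus.StimulusTrace` of equal length.
    """
    if len(track) != len(led.led_on):
        raise ValueError(
            f"track ({len(track)} frames) and LED trace ({len(led.led_on)}) "
            "have different lengths"
        )
    out = pd.DataFrame(
        {
            "frame": track["frame"].to_numpy(),
            "time_s": np.round(track["time_s"].to_numpy(), 3),
            "perimeter": track["perimeter"].to_numpy(),
            "area": track["area"].to_numpy(),
            "step_distance": track["step_distance"].to_numpy(),
            "roi_mean": led.roi_mean,
            "led_on": led.led_on.astype(int),
            "valid": track["valid"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def read_aligned_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ALIGNED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"aligned CSV {path} lacks columns {missing}")
    df["led_on"] = df["led_on"].astype(bool)
    df["valid"] = df["valid"].astype(bool)
    return df
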