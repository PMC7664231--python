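"""Radiometric thermal stacks and ROI temperature statistics.

Thermal video arrives as one CSV matrix of temperatures (degrees C) per
frame.  For a tracked head ROI the per-frame summary is the maximum,
the mode and the (population) standard deviation of the ROI pixels; the
recording-level summary takes the per-frame maxima and reports their
mean, max, mode and SD.  Using the per-frame *maximum* makes the
statistic robust to cold occluders (cage bars): as long as part of the
warm face is visible, the max is untouched.

Temperatures are continuous, so the mode is binned: bins are 0.1 degC
wide and centred on multiples of 0.1 degC (thermometer display
precision); ties go to the lower bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .video import FrameStack, TrackedROI, _indexed_files

__all__ = [
    "ROITempStats",
    "read_thermal_stack",
    "write_thermal_stack",
    "roi_temperature_stats",
    "binned_mode",
]

DEFAULT_THERMAL_FPS = 9.0  # radiometric stream frame rate
MODE_BIN_C = 0.1


@dataclass
class ROITempStats:
    """Per-frame and aggregate ROI temperature summary (degrees C)."""

    max_c: np.ndarray   # per valid frame
    mode_c: np.ndarray
    sd_c: np.ndarray
    mean_of_max: float
    max_of_max: float
    mode_of_max: float
    sd_of_max: float
    frame_index: np.ndarray  # indices of the frames included


def binned_mode(values: np.ndarray, bin_c: float = MODE_BIN_C) -> float:
    """Most populated temperature bin, as its centre.

    Bins are ``bin_c`` wide, centred on multiples of ``bin_c``; when two
    bins tie, the lower one wins.
    """
    values = np.asarray(values, float).ravel()
    k = np.rint(values / bin_c).astype(np.int64)
    bins, counts = np.unique(k, return_counts=True)
    best = bins[counts == counts.max()].min()
    return float(best * bin_c)


def write_thermal_stack(stack: FrameStack, path) -> Path:
    """Write a thermal stack as ``frame_%06d.csv`` matrices + meta.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not stack.is_thermal:
        raise ValueError("expected a (T, H, W) temperature stack")
    for i, frame in enumerate(stack.frames):
        np.savetxt(path / f"frame_{i:06d}.csv", frame, delimiter=",", fmt="%.4f")
    meta = {"fps": float(stack.fps), "n_frames": int(stack.n_frames),
            "width": int(stack.width), "height": int(stack.height)}
    (path / "meta.yaml").write_text(yaml.safe_dump(meta))
    return path


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for li, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                row = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path.name} row {li}: non-numeric cell — decimal-comma "
                    f"(locale) formatting is not supported, use '.' decimals"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path.name} row {li}: ragged CSV ({len(row)} cells, "
                    f"expected {width})"
                )
            rows.append(row)
    return np.asarray(rows, float)


def read_thermal_stack(path) -> FrameStack:
    """Read a per-frame CSV thermal directory.

    Frames are ordered by the numeric index in the filename; missing
    indices are an error.  The frame rate comes from ``meta.yaml`` and
    defaults to 9 Hz.
    """
    path = Path(path)
    fps = DEFAULT_THERMAL_FPS
    meta_path = path / "meta.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        fps = float(meta.get("fps", fps))
    files = _indexed_files(path, r"frame_(\d+)\.csv")
    frames = [_read_csv_matrix(p) for _, p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
    return FrameStack(frames=np.stack(frames), fps=fps)


def roi_temperature_stats(stack: FrameStack, track: TrackedROI) -> ROITempStats:
    """ROI temperature statistics per frame and aggregated.

    Frames flagged invalid by the tracker are excluded from both the
    per-frame lists and the aggregates (their box is unreliable).
    """
    if not stack.is_thermal:
        raise ValueError("expected a thermal (T, H, W) stack")
    if track.n_frames != stack.n_frames:
        raise ValueError("track does not cover the stack")
    idx, maxs, modes, sds = [], [], [], []
    for i in range(stack.n_frames):
        if not track.valid[i]:
            continue
        x, y, w, h = (int(round(v)) for v in track.boxes[i])
        roi = stack.frames[i, y:y + h, x:x + w]
        if roi.size == 0:
            raise ValueError(f"empty ROI on frame {i}")
        idx.append(i)
        maxs.append(float(roi.max()))
        modes.append(binned_mode(roi))
        sds.append(float(roi.std()))  # population SD
    if not idx:
        raise ValueError("no valid frames in the track")
    maxs_a = np.asarray(maxs)
    return ROITempStats(
        max_c=maxs_a,
        mode_c=np.asarray(modes),
        sd_c=np.asarray(sds),
        mean_of_max=float(maxs_a.mean()),
        max_of_max=float(maxs_a.max()),
        mode_of_max=binned_mode(maxs_a),
        sd_of_max=float(maxs_a.std()),
        frame_index=np.asarray(idx),
    )
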