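"""Photoplethysmographic luminosity series from cropped frame stacks.

The cardiac signal is read from the green (G) channel of the RGB crop,
the respiratory signal from the a* channel (green-red opponent axis) of
CIELAB; each frame contributes the spatial mean of the chosen channel
over the crop, giving a 1-D series sampled at the video frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _detrend
from skimage.color import rgb2lab

__all__ = ["ChannelSignal", "rgb_to_lab", "extract_series"]


@dataclass
class ChannelSignal:
    """A 1-D luminosity time series.

    Attributes
    ----------
    values : ndarray
        Mean-centered, linearly detrended per-frame channel means.
    fs : float
        Sampling rate in Hz (the stack frame rate).
    channel : str
        ``"G"`` (green, cardiac) or ``"a"`` (CIELAB a*, respiratory).
    frame_valid : ndarray of bool
        Per-sample tracking validity; invalid samples were interpolated.
    """

    values: np.ndarray
    fs: float
    channel: str = "G"
    frame_valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.values.size, dtype=bool)
        else:
            self.frame_valid = np.asarray(self.frame_valid, dtype=bool)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds from the first frame."""
        return np.arange(self.n) / self.fs


def rgb_to_lab(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB frame to float CIELAB (D65).

    sRGB is de-gammaed (IEC 61966-2-1), taken to XYZ under the D65
    illuminant and then to L*a*b*; a* spans the green (negative) to red
    (positive) opponent axis.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 frame, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) sRGB frame")
    return rgb2lab(frame)


def _channel_mean(frame: np.ndarray, channel: str) -> float:
    if channel == "G":
        return float(frame[..., 1].mean())
    if channel == "a":
        return float(rgb_to_lab(frame)[..., 1].mean())
    raise ValueError(f"unknown channel {channel!r}; use 'G' or 'a'")


def extract_series(cropped, channel: str = "G") -> ChannelSignal:
    """Per-frame mean luminosity of one channel over a cropped stack.

    Frames flagged invalid by the tracker are filled by linear
    interpolation between the nearest valid neighbours (zero-filling
    would inject broadband energy).  The series is linearly detrended
    and mean-centered before return, removing slow illumination drift
    that would otherwise dominate the low band edge.

    Parameters
    ----------
    cropped : FrameStack
        Cropped RGB stack (uint8), e.g. from ``video.crop_stack``.
    channel : str
        ``"G"`` or ``"a"``.
    """
    frames = cropped.frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to form a time series")
    valid = getattr(cropped, "frame_valid", None)
    if valid is None:
        valid = np.ones(len(frames), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("all frames are flagged invalid; nothing to extract")

    if channel == "a":
        # one vectorized sRGB->Lab pass over the whole stack
        lab_a = rgb2lab(np.asarray(frames, dtype=np.uint8))[..., 1]
        vals = lab_a.reshape(lab_a.shape[0], -1).mean(axis=1)
    elif channel == "G":
        g = np.asarray(frames)[..., 1].astype(float)
        vals = g.reshape(g.shape[0], -1).mean(axis=1)
    else:
        raise ValueError(f"unknown channel {channel!r}; use 'G' or 'a'")

    if not valid.all():
        idx = np.arange(vals.size)
        vals = np.interp(idx, idx[valid], vals[valid])
    vals = _detrend(vals, type="linear")
    return ChannelSignal(values=vals, fs=cropped.fps, channel=channel,
                         frame_valid=valid)
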