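"""Frame-stack I/O, KLT-style ROI tracking, and per-frame cropping.

A recording is a directory of numbered PNG frames plus a ``meta.yaml``
(fps, dimensions).  An anatomical region of interest (nose/mouth for the
RGB stream, whole head for thermal) is seeded once as a rectangle and
followed across frames with the Kanade-Lucas-Tomasi scheme: minimum-
eigenvalue corner features inside the box, propagated frame to frame by
pyramidal Lucas-Kanade optical flow; the box moves by the median
displacement of the surviving features, which keeps it robust to partial
occlusion by cage bars.  When fewer than a quarter of the features
survive, the frame is flagged invalid, the last valid box is kept and
features are re-detected inside it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.color import rgb2gray
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import resize

__all__ = [
    "FrameStack",
    "TrackedROI",
    "LKConfig",
    "NoTrackableFeaturesError",
    "read_frame_dir",
    "write_frame_dir",
    "detect_corner_features",
    "track_roi",
    "crop_stack",
    "read_label_file",
    "write_label_file",
]


@dataclass
class FrameStack:
    """Time-ordered frames with a frame rate.

    ``frames`` is a (T, H, W, 3) uint8 array for RGB video or a
    (T, H, W) float array of temperatures in degrees C for thermal video.
    """

    frames: np.ndarray
    fps: float
    frame_valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (T,H,W,3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frame_valid is not None:
            self.frame_valid = np.asarray(self.frame_valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def is_thermal(self) -> bool:
        return self.frames.ndim == 3

    @property
    def timestamps(self) -> np.ndarray:
        """Seconds from the first frame."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class TrackedROI:
    """Per-frame rectangle following a tracked feature.

    Boxes are (x, y, w, h) in 0-based pixel coordinates, half-open on
    the right/bottom edge.  Frames where tracking failed carry the last
    valid box with ``valid=False``.
    """

    boxes: np.ndarray  # (T, 4) float
    valid: np.ndarray  # (T,) bool
    source: str = "manual-seed"

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.boxes.shape[0] != self.valid.shape[0]:
            raise ValueError("boxes and valid must have one entry per frame")
        if np.any(self.boxes[:, 2:] <= 0):
            raise ValueError("box width/height must be positive")

    @property
    def n_frames(self) -> int:
        return self.boxes.shape[0]

    @classmethod
    def static(cls, box, n_frames: int, source: str = "manual-seed") -> "TrackedROI":
        """A ROI fixed at ``box`` for all frames."""
        boxes = np.tile(np.asarray(box, float), (n_frames, 1))
        return cls(boxes=boxes, valid=np.ones(n_frames, bool), source=source)


class NoTrackableFeaturesError(RuntimeError):
    """Raised when a region contains no corner above threshold."""


@dataclass
class LKConfig:
    """Pyramidal Lucas-Kanade tracker parameters."""

    levels: int = 3            # pyramid levels (full resolution included)
    window: int = 15           # odd patch side in pixels
    max_iter: int = 30         # iterations per level
    eps: float = 0.01          # convergence threshold on the update, px
    max_features: int = 40     # cap on tracked corners
    min_distance: int = 3      # corner spacing, px
    quality: float = 0.05      # corner score threshold relative to best
    min_response: float = 1e-5 # absolute corner floor (0-1 intensity scale)
    max_residual: float = 0.08 # mean abs patch residual to keep a feature
    min_survival: float = 0.25 # fraction of features below which a frame
                               # is flagged invalid and features re-seeded


# ---------------------------------------------------------------------------
# frame stack I/O

def write_frame_dir(stack: FrameStack, path) -> Path:
    """Write an RGB stack as ``frame_%06d.png`` files plus ``meta.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if stack.is_thermal:
        raise ValueError("PNG frame directories hold RGB stacks; "
                         "use thermal.write_thermal_stack for temperature data")
    for i, frame in enumerate(stack.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame)
    meta = {"fps": float(stack.fps), "n_frames": int(stack.n_frames),
            "width": int(stack.width), "height": int(stack.height)}
    (path / "meta.yaml").write_text(yaml.safe_dump(meta))
    return path


def _indexed_files(path: Path, pattern: str) -> list[tuple[int, Path]]:
    rx = re.compile(pattern)
    found = sorted(
        (int(m.group(1)), p)
        for p in path.iterdir()
        if (m := rx.fullmatch(p.name))
    )
    if not found:
        raise FileNotFoundError(f"no frames matching {pattern!r} in {path}")
    idx = [i for i, _ in found]
    missing = sorted(int(v) for v in set(range(idx[0], idx[-1] + 1)) - set(idx))
    if missing:
        raise ValueError(f"frame index gaps in {path}: missing {missing}")
    return found


def read_frame_dir(path) -> FrameStack:
    """Read a PNG frame directory written by :func:`write_frame_dir`."""
    path = Path(path)
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    files = _indexed_files(path, r"frame_(\d+)\.png")
    frames = np.stack([iio.imread(p) for _, p in files])
    return FrameStack(frames=frames, fps=float(meta["fps"]))


# ---------------------------------------------------------------------------
# feature detection and tracking

def _as_gray(frames: np.ndarray) -> np.ndarray:
    """Stack of float grayscale images in [0, 1] for tracking.

    Thermal (2-D float) stacks are min-max normalized over the whole
    stack so the tracker sees a consistent intensity image.
    """
    frames = np.asarray(frames)
    if frames.ndim == 4:
        return rgb2gray(frames)
    lo, hi = float(frames.min()), float(frames.max())
    span = hi - lo if hi > lo else 1.0
    return (frames.astype(float) - lo) / span


def _clip_box(box, width, height):
    x, y, w, h = box
    x = float(np.clip(x, 0, max(width - w, 0)))
    y = float(np.clip(y, 0, max(height - h, 0)))
    return np.array([x, y, w, h], float)


def detect_corner_features(frame: np.ndarray, roi, config: LKConfig = None) -> np.ndarray:
    """Minimum-eigenvalue (Shi-Tomasi) corners inside ``roi``.

    Returns an (N, 2) array of (x, y) positions ranked by corner score,
    capped at ``config.max_features``.  Raises
    :class:`NoTrackableFeaturesError` when no corner exceeds the
    absolute response floor (e.g. a uniform region).
    """
    config = config or LKConfig()
    gray = _as_gray(frame[None])[0] if frame.ndim in (2, 3) else None
    if gray is None:
        raise ValueError("frame must be a single (H,W) or (H,W,3) image")
    h_img, w_img = gray.shape
    x, y, w, h = (int(round(v)) for v in roi)
    if not (0 <= x < x + w <= w_img and 0 <= y < y + h <= h_img):
        raise ValueError(f"roi {tuple(roi)} outside frame bounds {w_img}x{h_img}")
    response = corner_shi_tomasi(gray, sigma=1)
    mask = np.zeros_like(response, dtype=bool)
    # margin keeps the tracking window inside the frame
    m = config.window // 2 + 1
    y0, y1 = max(y, m), min(y + h, h_img - m)
    x0, x1 = max(x, m), min(x + w, w_img - m)
    if y0 >= y1 or x0 >= x1:
        raise NoTrackableFeaturesError("roi too close to the frame edge to track")
    mask[y0:y1, x0:x1] = True
    roi_max = response[mask].max() if mask.any() else 0.0
    thr = max(config.quality * roi_max, config.min_response)
    masked = np.where(mask, response, -np.inf)
    peaks = corner_peaks(masked, min_distance=config.min_distance,
                         threshold_abs=thr, num_peaks=config.max_features)
    if peaks.size == 0:
        raise NoTrackableFeaturesError(
            f"no trackable features: no corner above {thr:.2e} inside roi"
        )
    order = np.argsort(-response[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        prev = gaussian_filter(pyr[-1], sigma=1.0)
        pyr.append(prev[::2, ::2])
    return pyr


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_point(pyr0, pyr1, pt, config: LKConfig):
    """Track one point from pyramid ``pyr0`` to ``pyr1``.

    Coarse-to-fine iterative minimization of the local patch SSD;
    returns (new_point, converged, mean_abs_residual).
    """
    half = config.window // 2
    oy, ox = np.mgrid[-half:half + 1, -half:half + 1]
    ox = ox.ravel().astype(float)
    oy = oy.ravel().astype(float)
    d = np.zeros(2)
    ok = True
    resid = np.inf
    for lvl in range(len(pyr0) - 1, -1, -1):
        scale = 2.0 ** lvl
        img0, img1 = pyr0[lvl], pyr1[lvl]
        px, py = pt[0] / scale, pt[1] / scale
        xs, ys = px + ox, py + oy
        patch0 = _sample(img0, xs, ys)
        # template gradients via central differences
        ix = 0.5 * (_sample(img0, xs + 1, ys) - _sample(img0, xs - 1, ys))
        iy = 0.5 * (_sample(img0, xs, ys + 1) - _sample(img0, xs, ys - 1))
        g = np.array([[np.dot(ix, ix), np.dot(ix, iy)],
                      [np.dot(ix, iy), np.dot(iy, iy)]])
        det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        if det < 1e-12:
            ok = False
            break
        g_inv = np.array([[g[1, 1], -g[0, 1]], [-g[1, 0], g[0, 0]]]) / det
        d = d * 1.0  # displacement expressed at this level below
        dl = d / scale
        for _ in range(config.max_iter):
            e = _sample(img1, xs + dl[0], ys + dl[1]) - patch0
            b = np.array([np.dot(e, ix), np.dot(e, iy)])
            step = -g_inv @ b
            dl = dl + step
            if np.hypot(*step) < config.eps:
                break
        d = dl * scale
        if lvl == 0:
            e = _sample(img1, xs + dl[0], ys + dl[1]) - patch0
            resid = float(np.mean(np.abs(e)))
    new_pt = pt + d
    return new_pt, ok, resid


def track_roi(stack: FrameStack, seed_box, config: LKConfig = None) -> TrackedROI:
    """Track ``seed_box`` (x, y, w, h on frame 0) across the stack.

    Features are propagated by pyramidal Lucas-Kanade; the box moves by
    the median displacement of features that converged with an
    acceptable patch residual.  Frames where fewer than
    ``config.min_survival`` of the features survive are flagged invalid:
    the box freezes at the last valid position and features are
    re-detected inside it (silently retried on later frames if the
    region is featureless, e.g. fully occluded by a uniform bar).
    """
    config = config or LKConfig()
    if stack.n_frames == 0:
        raise ValueError("empty frame stack")
    gray = _as_gray(stack.frames)
    n, h_img, w_img = gray.shape[0], gray.shape[1], gray.shape[2]
    box = _clip_box(np.asarray(seed_box, float), w_img, h_img)
    if tuple(box[:2]) != tuple(np.asarray(seed_box, float)[:2]):
        raise ValueError(f"seed box {tuple(seed_box)} outside frame bounds")

    pts = detect_corner_features(gray[0], box, config)
    n_seeded = len(pts)
    boxes = np.empty((n, 4))
    valid = np.ones(n, dtype=bool)
    boxes[0] = box
    pyr_prev = _pyramid(gray[0], config.levels)
    margin = config.window // 2 + 1

    for i in range(1, n):
        pyr_cur = _pyramid(gray[i], config.levels)
        survivors = []
        disps = []
        if pts is not None:
            for pt in pts:
                new_pt, ok, resid = _lk_point(pyr_prev, pyr_cur, pt, config)
                inside = (margin <= new_pt[0] < w_img - margin
                          and margin <= new_pt[1] < h_img - margin)
                if ok and inside and resid <= config.max_residual:
                    survivors.append(new_pt)
                    disps.append(new_pt - pt)
        need = max(3, int(np.ceil(config.min_survival * n_seeded)))
        if len(survivors) >= need:
            disp = np.median(np.asarray(disps), axis=0)
            box = _clip_box(box + np.array([disp[0], disp[1], 0, 0]), w_img, h_img)
            boxes[i] = box
            pts = np.asarray(survivors)
        else:
            valid[i] = False
            boxes[i] = box  # last valid box
            try:
                pts = detect_corner_features(gray[i], box, config)
                n_seeded = len(pts)
            except NoTrackableFeaturesError:
                pts = None
        pyr_prev = pyr_cur
    return TrackedROI(boxes=boxes, valid=valid, source="manual-seed")


# ---------------------------------------------------------------------------
# cropping

def crop_stack(stack: FrameStack, track: TrackedROI, out_size=None) -> FrameStack:
    """Crop each frame to its tracked box, resampled to a fixed size.

    ``out_size`` is (width, height); it defaults to the first box size.
    Boxes are rounded to integer pixels; resampling is nearest-neighbour
    so planted pixel content is preserved exactly when sizes agree.
    """
    if track.n_frames != stack.n_frames:
        raise ValueError(
            f"track covers {track.n_frames} frames, stack has {stack.n_frames}"
        )
    if out_size is None:
        out_size = (int(round(track.boxes[0, 2])), int(round(track.boxes[0, 3])))
    ow, oh = int(out_size[0]), int(out_size[1])
    crops = np.empty((stack.n_frames, oh, ow) + stack.frames.shape[3:],
                     dtype=stack.frames.dtype)
    for i, frame in enumerate(stack.frames):
        x, y, w, h = (int(round(v)) for v in track.boxes[i])
        x = min(max(x, 0), stack.width - w)
        y = min(max(y, 0), stack.height - h)
        sub = frame[y:y + h, x:x + w]
        if (w, h) != (ow, oh):
            sub = resize(sub, (oh, ow) + sub.shape[2:], order=0,
                         preserve_range=True, anti_aliasing=False
                         ).astype(stack.frames.dtype)
        crops[i] = sub
    return FrameStack(frames=crops, fps=stack.fps, frame_valid=track.valid.copy())


# ---------------------------------------------------------------------------
# label files

def write_label_file(track: TrackedROI, path) -> Path:
    """Write a ROI track as CSV with header ``frame,x,y,w,h,valid``."""
    path = Path(path)
    df = pd.DataFrame({
        "frame": np.arange(track.n_frames),
        "x": track.boxes[:, 0], "y": track.boxes[:, 1],
        "w": track.boxes[:, 2], "h": track.boxes[:, 3],
        "valid": track.valid.astype(int),
    })
    df.to_csv(path, index=False)
    return path


def read_label_file(path) -> TrackedROI:
    """Read a ROI label CSV (header ``frame,x,y,w,h[,valid]``).

    Frame indices are 0-based by default; a leading comment line
    ``# index_base: 1`` declares 1-based indices, which are shifted
    down on read.  Missing frame indices are an error.
    """
    path = Path(path)
    index_base = 0
    with open(path) as fh:
        first = fh.readline()
    m = re.match(r"#\s*index_base\s*:\s*(\d+)", first)
    if m:
        index_base = int(m.group(1))
    df = pd.read_csv(path, comment="#")
    required = {"frame", "x", "y", "w", "h"}
    if not required.issubset(df.columns):
        raise ValueError(f"label file {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    frames = df["frame"].to_numpy(int) - index_base
    expect = np.arange(frames.min(), frames.max() + 1)
    missing = sorted(int(v) for v in set(expect) - set(frames))
    if missing:
        raise ValueError(f"label file {path} has frame gaps: missing {missing}")
    df = df.iloc[np.argsort(frames)]
    boxes = df[["x", "y", "w", "h"]].to_numpy(float)
    valid = (df["valid"].to_numpy().astype(bool)
             if "valid" in df.columns else np.ones(len(df), bool))
    return TrackedROI(boxes=boxes, valid=valid, source="label-file")
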