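"""Synthetic RGB and radiometric thermal scenes with known vital signs.

No animal recordings are distributed, so every pipeline stage is
exercised on generated scenes with exact ground truth: a textured moving
background whose region of interest carries a cardiac sinusoid in the
green channel and a respiratory sinusoid in the red channel (red-green
opponency drives the CIELAB a* series downstream), optionally crossed by
occluding bars; and thermal frame stacks with a Gaussian hotspot riding
on a uniform background.

The default scene emulates a one-minute recording: 1800 frames at
30 fps, a sub-digital-number cardiac amplitude (0.4 DN, the typical
remote-PPG pulsatile scale on an 8-bit sensor), a 3 DN respiratory
amplitude, and per-pixel Gaussian sensor noise added *before* 8-bit
quantization so sub-unit amplitudes are dithered through the quantizer.
Heart rates span 1.05-2.2 Hz (63-132 BPM) and respiration 0.2-3.2 Hz
(12-192 BrPM) over the three class bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .video import FrameStack, write_frame_dir

__all__ = [
    "SceneSpec",
    "ThermalSceneSpec",
    "Occluder",
    "CohortSample",
    "SNR_PRESETS",
    "RR_CLASS_RANGES",
    "HR_RANGE_HZ",
    "generate_rgb_scene",
    "generate_thermal_scene",
    "generate_cohort",
    "write_cohort",
]

#: Pixel-noise SD (8-bit digital numbers) per named signal-to-noise preset.
SNR_PRESETS = {"default": 2.0, "clean": 0.5}

#: Respiration-class frequency ranges in Hz (half-open: a boundary
#: frequency belongs to the lower class).
RR_CLASS_RANGES = {"low": (0.2, 1.2), "medium": (1.2, 2.2), "high": (2.2, 3.2)}

#: Cardiac frequency range in Hz (63-132 BPM).
HR_RANGE_HZ = (1.05, 2.2)


@dataclass(frozen=True)
class Occluder:
    """A vertical bar overwriting pixels for a frame interval."""

    x: int
    width: int
    frame_start: int = 0
    frame_end: int = None  # exclusive; None = until the last frame
    value: int = 0         # 8-bit gray level of the bar


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic RGB recording."""

    width: int = 64
    height: int = 48
    n_frames: int = 1800
    fps: float = 30.0
    roi_true: tuple = (18, 12, 28, 20)  # x, y, w, h; 0-based, half-open
    hr_hz: float = 1.5
    rr_hz: float = 0.9
    amp_hr: float = 0.4     # green-channel cardiac amplitude, DN
    amp_rr: float = 3.0     # red-channel respiratory amplitude, DN
    noise_sd: float = 2.0   # per-pixel Gaussian noise SD, DN
    motion: object = 0      # scalar 0, (dx, dy) per frame, or (n, 2) array
    occluders: tuple = ()
    phase_hr: float = 0.0
    phase_rr: float = 0.0
    base_level: float = 128.0
    texture_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        nyq = self.fps / 2.0
        for name, f in (("hr_hz", self.hr_hz), ("rr_hz", self.rr_hz)):
            if f >= nyq:
                raise ValueError(
                    f"{name}={f} Hz violates Nyquist: fps={self.fps} "
                    f"requires frequencies below {nyq} Hz"
                )
        if self.amp_hr < 0 or self.amp_rr < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        x, y, w, h = self.roi_true
        if w <= 0 or h <= 0:
            raise ValueError("roi_true must have positive size")
        offs = _cumulative_offsets(self.motion, self.n_frames)
        xs = x + offs[:, 0]
        ys = y + offs[:, 1]
        if (xs.min() < 0 or ys.min() < 0
                or xs.max() + w > self.width or ys.max() + h > self.height):
            raise ValueError("roi_true leaves the frame bounds under the "
                             "specified motion")


@dataclass(frozen=True)
class ThermalSceneSpec:
    """Parameters of a synthetic radiometric thermal recording."""

    width: int = 80
    height: int = 64
    n_frames: int = 90
    fps: float = 9.0               # thermal camera frame rate
    background_c: float = 20.0
    hotspot_peak_c: object = 38.5  # scalar or per-frame trajectory, degrees C
    hotspot_sigma: float = 3.0     # Gaussian radius, px; <=0 disables hotspot
    roi_true: tuple = (24, 18, 32, 28)
    noise_sd_c: float = 0.0
    seed: int = 0

    def peaks(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.hotspot_peak_c, float),
                            (self.n_frames,)).copy()
        return p

    def validate(self) -> None:
        x, y, w, h = self.roi_true
        if not (0 <= x < x + w <= self.width and 0 <= y < y + h <= self.height):
            raise ValueError(f"roi_true {self.roi_true} outside the "
                             f"{self.width}x{self.height} frame")
        peaks = self.peaks()
        if not np.isfinite(peaks).all():
            raise ValueError("hotspot trajectory contains non-finite values")
        if self.hotspot_sigma > 0 and np.any(peaks <= self.background_c):
            raise ValueError("hotspot peak must exceed the background "
                             "temperature")


@dataclass
class CohortSample:
    """One labelled synthetic recording in a cohort."""

    scene_id: str
    spec: SceneSpec
    band: str          # respiration class: low | medium | high
    hr_hz: float
    rr_hz: float

    @property
    def hr_bpm(self) -> float:
        return 60.0 * self.hr_hz

    @property
    def rr_brpm(self) -> float:
        return 60.0 * self.rr_hz


def _cumulative_offsets(motion, n_frames: int) -> np.ndarray:
    """Per-frame cumulative (dx, dy) offsets from a motion spec."""
    if np.isscalar(motion) and motion == 0:
        return np.zeros((n_frames, 2))
    motion = np.asarray(motion, dtype=float)
    if motion.ndim == 1:
        motion = np.tile(motion, (n_frames, 1))
    if motion.shape != (n_frames, 2):
        raise ValueError("motion must be 0, a (dx, dy) pair, or an "
                         "(n_frames, 2) array of per-frame steps")
    offs = np.cumsum(motion, axis=0)
    offs[1:] = offs[:-1]
    offs[0] = 0.0
    return offs


def _texture(height: int, width: int, rng, base: float, sd: float) -> np.ndarray:
    """Smooth random background field (no attempt at photorealism)."""
    field_ = rng.standard_normal((height, width))
    field_ = gaussian_filter(field_, sigma=3, mode="wrap")
    scale = field_.std()
    if scale > 0:
        field_ = field_ / scale * sd
    return base + field_


def generate_rgb_scene(spec: SceneSpec) -> tuple[FrameStack, dict]:
    """Render an RGB scene and its ground-truth record.

    Inside the (moving) true ROI the green channel carries
    ``amp_hr * sin(2 pi hr_hz t + phase)`` and the red channel
    ``amp_rr * sin(2 pi rr_hz t + phase)`` on top of a smooth seeded
    texture.  Per-pixel Gaussian noise is added in floating point before
    rounding to uint8.  The truth record carries the planted
    frequencies, the per-frame ROI box and the per-frame occluded
    fraction of the ROI.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    offs = _cumulative_offsets(spec.motion, spec.n_frames)
    x0, y0, w, h = spec.roi_true
    tex = _texture(spec.height, spec.width, rng, spec.base_level, spec.texture_sd)
    t = np.arange(spec.n_frames) / spec.fps
    g_mod = spec.amp_hr * np.sin(2 * np.pi * spec.hr_hz * t + spec.phase_hr)
    r_mod = spec.amp_rr * np.sin(2 * np.pi * spec.rr_hz * t + spec.phase_rr)

    frames = np.empty((spec.n_frames, spec.height, spec.width, 3), dtype=np.uint8)
    roi_boxes = np.empty((spec.n_frames, 4))
    occ_frac = np.zeros(spec.n_frames)

    for i in range(spec.n_frames):
        dx, dy = offs[i]
        if dx == int(dx) and dy == int(dy):
            base = np.roll(tex, (int(dy), int(dx)), axis=(0, 1))
        else:
            base = nd_shift(tex, (dy, dx), order=1, mode="grid-wrap")
        frame = np.repeat(base[:, :, None], 3, axis=2)
        rx = int(round(x0 + dx))
        ry = int(round(y0 + dy))
        frame[ry:ry + h, rx:rx + w, 0] += r_mod[i]
        frame[ry:ry + h, rx:rx + w, 1] += g_mod[i]
        roi_boxes[i] = (rx, ry, w, h)

        occ_cols = np.zeros(spec.width, dtype=bool)
        for bar in spec.occluders:
            end = spec.n_frames if bar.frame_end is None else bar.frame_end
            if bar.frame_start <= i < end:
                frame[:, bar.x:bar.x + bar.width, :] = bar.value
                occ_cols[bar.x:bar.x + bar.width] = True
        occ_frac[i] = occ_cols[rx:rx + w].mean() if w else 0.0

        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    truth = {
        "hr_hz": spec.hr_hz,
        "rr_hz": spec.rr_hz,
        "hr_bpm": 60.0 * spec.hr_hz,
        "rr_brpm": 60.0 * spec.rr_hz,
        "roi": roi_boxes,
        "occluded_fraction": occ_frac,
    }
    return FrameStack(frames=frames, fps=spec.fps), truth


def generate_thermal_scene(spec: ThermalSceneSpec, out_dir=None):
    """Render a radiometric thermal stack (and optionally write CSVs).

    The hotspot is a Gaussian bump centred in the true ROI whose peak
    follows ``hotspot_peak_c``; the noise-free per-frame maximum over
    the ROI equals the trajectory exactly.  With ``out_dir`` given, the
    frames are written as ``frame_%06d.csv`` matrices of degrees C plus
    ``meta.yaml``, and the directory path is returned alongside.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    peaks = spec.peaks()
    x, y, w, h = spec.roi_true
    cy, cx = y + (h - 1) / 2.0, x + (w - 1) / 2.0
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    if spec.hotspot_sigma > 0:
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                      / (2.0 * spec.hotspot_sigma ** 2))
        # force an exact peak: the max of the discrete bump may fall
        # between pixels, so normalise by its sampled maximum
        bump = bump / bump.max()
    else:
        bump = np.zeros((spec.height, spec.width))
    frames = np.empty((spec.n_frames, spec.height, spec.width))
    for i in range(spec.n_frames):
        frame = spec.background_c + (peaks[i] - spec.background_c) * bump
        if spec.noise_sd_c > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd_c, frame.shape)
        frames[i] = frame
    stack = FrameStack(frames=frames, fps=spec.fps)
    truth = {
        "hotspot_peak_c": peaks,
        "roi": np.tile(np.asarray(spec.roi_true, float), (spec.n_frames, 1)),
    }
    if out_dir is not None:
        from .thermal import write_thermal_stack
        write_thermal_stack(stack, out_dir)
        return stack, truth, Path(out_dir)
    return stack, truth


def generate_cohort(
    n_animals: int = 134,
    band_mix: tuple = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    snr: str = "default",
    n_frames: int = 1800,
    fps: float = 30.0,
) -> list[CohortSample]:
    """A labelled cohort of scene specs spanning the three RR classes.

    Class sizes follow ``band_mix`` (balanced within +-1 sample for the
    default equal mix); respiration frequencies are uniform within each
    class band, cardiac frequencies uniform in 1.05-2.2 Hz, and phases
    random.  Reference labels are 60 x the planted frequency.  Scenes
    are returned as lightweight specs; frames are rendered on demand.
    """
    if abs(sum(band_mix) - 1.0) > 1e-9:
        raise ValueError(f"band_mix must sum to 1, got {band_mix}")
    if snr not in SNR_PRESETS:
        raise KeyError(f"unknown SNR preset {snr!r}; known: {sorted(SNR_PRESETS)}")
    noise_sd = SNR_PRESETS[snr]
    rng = np.random.default_rng(seed)
    names = list(RR_CLASS_RANGES)
    counts = np.floor(np.asarray(band_mix) * n_animals).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = n_animals - counts.sum()
    frac = np.asarray(band_mix) * n_animals - counts
    for j in np.argsort(-frac)[:rem]:
        counts[j] += 1
    samples = []
    k = 0
    for band, count in zip(names, counts):
        lo, hi = RR_CLASS_RANGES[band]
        for _ in range(count):
            rr = float(rng.uniform(lo, hi))
            hr = float(rng.uniform(*HR_RANGE_HZ))
            spec = SceneSpec(
                n_frames=n_frames, fps=fps, hr_hz=hr, rr_hz=rr,
                noise_sd=noise_sd,
                phase_hr=float(rng.uniform(0, 2 * np.pi)),
                phase_rr=float(rng.uniform(0, 2 * np.pi)),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            samples.append(CohortSample(
                scene_id=f"scene_{k:04d}", spec=spec, band=band,
                hr_hz=hr, rr_hz=rr,
            ))
            k += 1
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def cohort_truth_frame(cohort: list) -> pd.DataFrame:
    """Reference-label table (one row per scene)."""
    return pd.DataFrame({
        "scene_id": [s.scene_id for s in cohort],
        "hr_hz": [s.hr_hz for s in cohort],
        "rr_hz": [s.rr_hz for s in cohort],
        "band": [s.band for s in cohort],
        "hr_bpm": [s.hr_bpm for s in cohort],
        "rr_brpm": [s.rr_brpm for s in cohort],
    })


def write_cohort(cohort: list, out_dir) -> Path:
    """Materialize a cohort to disk: one frame directory per scene plus
    ``truth.csv``.  Intended for small cohorts / CLI use."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        stack, _ = generate_rgb_scene(s.spec)
        write_frame_dir(stack, out_dir / s.scene_id)
        box = s.spec.roi_true
        meta = {"roi": [int(v) for v in box]}
        (out_dir / s.scene_id / "roi.yaml").write_text(yaml.safe_dump(meta))
    cohort_truth_frame(cohort).to_csv(out_dir / "truth.csv", index=False)
    return out_dir
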