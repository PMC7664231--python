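"""Band-pass spectral analysis of luminosity signals (the RVA/RVAm core).

The raw-video-analysis chain is: zero-phase second-order Butterworth
band-pass -> Hann-windowed, zero-padded FFT magnitude spectrum ->
dominant-frequency estimate inside a physiological band, refined by
three-point parabolic interpolation.  Frequencies are reported in Hz and
converted to beats/breaths per minute (BPM/BrPM) with ``to_bpm``.

Named bands (Hz):

========== ===========  =================================================
name       lo -- hi     use
========== ===========  =================================================
HR         0.83 -- 3.00 cardiac band, green channel (50-180 BPM)
RR-wide    0.33 -- 3.1  first-pass respiration band, CIELAB a* channel
RR-low     0.2 -- 1.2   band-specific re-analysis, low respiration class
RR-medium  1.2 -- 2.2   medium respiration class
RR-high    2.2 -- 3.2   high respiration class (panting)
========== ===========  =================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import ChannelSignal

__all__ = [
    "BandSpec",
    "BANDS",
    "SpectralEstimate",
    "butterworth_bandpass",
    "fft_spectrum",
    "dominant_frequency",
    "analyze_band",
    "to_bpm",
]


@dataclass(frozen=True)
class BandSpec:
    """A physiological frequency band [lo, hi] in Hz."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.lo}-{self.hi} Hz")


#: Canonical named bands.
BANDS: dict[str, BandSpec] = {
    "HR": BandSpec(0.83, 3.00, "HR"),
    "RR-wide": BandSpec(0.33, 3.1, "RR-wide"),
    "RR-low": BandSpec(0.2, 1.2, "RR-low"),
    "RR-medium": BandSpec(1.2, 2.2, "RR-medium"),
    "RR-high": BandSpec(2.2, 3.2, "RR-high"),
}

#: Re-analysis band for each respiration class label.
RR_BAND_FOR_CLASS = {"low": "RR-low", "medium": "RR-medium", "high": "RR-high"}


@dataclass
class SpectralEstimate:
    """Dominant frequency and amplitude of a signal inside one band."""

    f_peak: float
    amplitude: float
    band: BandSpec
    edge_peak: bool = False
    freqs: np.ndarray = field(default=None, repr=False)
    mags: np.ndarray = field(default=None, repr=False)

    @property
    def bpm(self) -> float:
        return to_bpm(self)


def get_band(band: "BandSpec | str") -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


def butterworth_bandpass(sig: ChannelSignal, band: "BandSpec | str") -> ChannelSignal:
    """Zero-phase band-pass filter.

    A second-order Butterworth low/high prototype mapped to a band-pass
    (4 poles) via the bilinear transform with frequency pre-warping,
    applied forward then backward (``filtfilt``) so the pass is zero
    phase and the effective magnitude response is |H(f)|^2.  Signal
    edges are reflection-padded over three filter lengths.
    """
    band = get_band(band)
    nyq = sig.fs / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name or ''} [{band.lo}, {band.hi}] Hz exceeds the "
            f"Nyquist frequency {nyq} Hz at fs={sig.fs} Hz"
        )
    b, a = sps.butter(2, [band.lo, band.hi], btype="bandpass", fs=sig.fs)
    padlen = 3 * max(len(a), len(b))
    if sig.n <= padlen:
        raise ValueError(f"signal too short to filter: n={sig.n} <= {padlen}")
    y = sps.filtfilt(b, a, sig.values, padtype="even", padlen=padlen)
    return ChannelSignal(values=y, fs=sig.fs, channel=sig.channel,
                         frame_valid=sig.frame_valid)


def bandpass_gain(band: "BandSpec | str", f: np.ndarray, fs: float) -> np.ndarray:
    """|H(f)|^2 of the bidirectional band-pass at frequencies ``f`` (Hz)."""
    band = get_band(band)
    b, a = sps.butter(2, [band.lo, band.hi], btype="bandpass", fs=fs)
    _, h = sps.freqz(b, a, worN=np.atleast_1d(f), fs=fs)
    return np.abs(h) ** 2


def fft_spectrum(sig: ChannelSignal) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the Hann-windowed series.

    Magnitudes are scaled so a unit-amplitude sinusoid at a bin center
    yields magnitude 1.0; the grid is zero-padded to the next power of
    two >= 4n, giving ~fs/(4n) Hz spacing before peak interpolation.
    """
    x = np.asarray(sig.values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    w = np.hanning(n)
    n_fft = 1 << int(np.ceil(np.log2(4 * n)))
    spec = np.fft.rfft(x * w, n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sig.fs)
    mags = 2.0 * np.abs(spec) / w.sum()
    return freqs, mags


def dominant_frequency(
    freqs: np.ndarray, mags: np.ndarray, band: "BandSpec | str"
) -> SpectralEstimate:
    """Largest spectral peak restricted to ``band``.

    The argmax over the in-band grid is refined by 3-point parabolic
    interpolation (using neighbours that may lie just outside the band);
    a peak sitting on the first or last in-band bin is flagged
    ``edge_peak`` — typically the true rate lies outside the band.
    """
    band = get_band(band)
    freqs = np.asarray(freqs, float)
    mags = np.asarray(mags, float)
    sel = np.nonzero((freqs >= band.lo) & (freqs <= band.hi))[0]
    if sel.size == 0:
        raise ValueError(
            f"no spectral bins inside [{band.lo}, {band.hi}] Hz "
            f"(grid spacing {freqs[1] - freqs[0]:.4g} Hz)"
        )
    k = sel[np.argmax(mags[sel])]
    edge = k == sel[0] or k == sel[-1]
    f_peak, amp = float(freqs[k]), float(mags[k])
    if 0 < k < freqs.size - 1 and not edge:
        ym, y0, yp = mags[k - 1], mags[k], mags[k + 1]
        denom = ym - 2 * y0 + yp
        if denom < 0:  # proper local maximum
            delta = 0.5 * (ym - yp) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            f_peak += delta * (freqs[1] - freqs[0])
            amp = float(y0 - 0.25 * (ym - yp) * delta)
    f_peak = float(np.clip(f_peak, band.lo, band.hi))
    return SpectralEstimate(f_peak=f_peak, amplitude=amp, band=band,
                            edge_peak=bool(edge), freqs=freqs, mags=mags)


def analyze_band(sig: ChannelSignal, band: "BandSpec | str") -> tuple[ChannelSignal, SpectralEstimate]:
    """Filter ``sig`` to ``band`` and estimate the dominant frequency.

    The spectrum is computed on the band-filtered series (the band
    re-analysis semantics: each class-specific pass filters first).
    Returns ``(filtered_signal, estimate)``.
    """
    filt = butterworth_bandpass(sig, band)
    freqs, mags = fft_spectrum(filt)
    return filt, dominant_frequency(freqs, mags, band)


def to_bpm(estimate: "SpectralEstimate | float") -> float:
    """Convert a frequency estimate in Hz to per-minute units (60 f)."""
    f = estimate.f_peak if isinstance(estimate, SpectralEstimate) else float(estimate)
    return 60.0 * f
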