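"""Parameter engineering: the 8-value signal feature vector.

Each analyzed signal is summarized by eight parameters: mean, minimum,
maximum and standard deviation of the luminosity *changes* (first
differences of the detrended raw series), mean and SD of the
band-filtered series, and the dominant frequency and its spectral
amplitude.  Model 1 consumes the 8 respiration-channel parameters from
the wide-band pass; Model 2 consumes 16 = 8 cardiac + 8 band-specific
respiration parameters.  Features are min-max normalized to [-1, 1]
with parameters learned on training rows only (matching the tan-sigmoid
input convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .signals import ChannelSignal
from .spectral import SpectralEstimate

__all__ = [
    "SignalFeatures",
    "FEATURE_FIELDS",
    "compute_features",
    "assemble_model1_matrix",
    "assemble_model2_matrix",
    "MinMaxNormalizer",
]

FEATURE_FIELDS = (
    "raw_mean", "raw_min", "raw_max", "raw_sd",
    "filt_mean", "filt_sd", "freq", "amp",
)


@dataclass
class SignalFeatures:
    """The 8 engineered parameters of one analyzed signal."""

    raw_mean: float
    raw_min: float
    raw_max: float
    raw_sd: float
    filt_mean: float
    filt_sd: float
    freq: float   # dominant frequency, Hz
    amp: float    # spectral amplitude at the peak, series units
    band: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_FIELDS], float)


def compute_features(
    raw: ChannelSignal,
    filtered: ChannelSignal,
    estimate: SpectralEstimate,
    changes: str = "diff",
) -> SignalFeatures:
    """Build the 8-parameter feature vector.

    ``changes`` selects the reading of "luminosity changes": ``"diff"``
    (default) takes first differences of the detrended raw series,
    ``"raw"`` uses the detrended series itself.
    """
    if raw.n != filtered.n or raw.fs != filtered.fs:
        raise ValueError("raw and filtered series must share length and rate")
    if raw.n < 16:
        raise ValueError(f"series too short for feature extraction: n={raw.n}")
    if changes == "diff":
        ch = np.diff(raw.values)
    elif changes == "raw":
        ch = raw.values
    else:
        raise ValueError(f"changes must be 'diff' or 'raw', got {changes!r}")
    return SignalFeatures(
        raw_mean=float(ch.mean()),
        raw_min=float(ch.min()),
        raw_max=float(ch.max()),
        raw_sd=float(ch.std()),
        filt_mean=float(filtered.values.mean()),
        filt_sd=float(filtered.values.std()),
        freq=float(estimate.f_peak),
        amp=float(estimate.amplitude),
        band=estimate.band.name,
    )


class MinMaxNormalizer:
    """Per-column min-max scaling to [-1, 1], fit on training rows only.

    Constant columns map to 0 (with a warning); test rows may fall
    outside [-1, 1] when they exceed the training range, by design.
    """

    def fit(self, df: pd.DataFrame) -> "MinMaxNormalizer":
        self.columns_ = list(df.columns)
        self.min_ = df.to_numpy(float).min(axis=0)
        self.max_ = df.to_numpy(float).max(axis=0)
        span = self.max_ - self.min_
        degenerate = span <= 0
        if degenerate.any():
            bad = [c for c, d in zip(self.columns_, degenerate) if d]
            warnings.warn(f"constant feature column(s) {bad} map to 0",
                          stacklevel=2)
        self.span_ = np.where(degenerate, np.inf, span)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if list(df.columns) != self.columns_:
            raise ValueError("column order differs from the fitted matrix")
        x = df.to_numpy(float)
        z = 2.0 * (x - self.min_) / self.span_ - 1.0
        z = np.where(np.isinf(self.span_), 0.0, z)
        return pd.DataFrame(z, columns=self.columns_, index=df.index)

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df.to_numpy(float)
        span = np.where(np.isinf(self.span_), 0.0, self.span_)
        orig = (x + 1.0) / 2.0 * span + self.min_
        orig = np.where(span == 0.0, self.min_, orig)
        return pd.DataFrame(orig, columns=self.columns_, index=df.index)

    def to_dict(self) -> dict:
        return {"columns": self.columns_, "min": self.min_.tolist(),
                "max": self.max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        self = cls()
        self.columns_ = list(d["columns"])
        self.min_ = np.asarray(d["min"], float)
        self.max_ = np.asarray(d["max"], float)
        span = self.max_ - self.min_
        self.span_ = np.where(span <= 0, np.inf, span)
        return self


def _matrix(samples, prefix: str) -> pd.DataFrame:
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    rows = np.stack([s.as_array() for s in samples])
    cols = [f"{prefix}_{f}" for f in FEATURE_FIELDS]
    return pd.DataFrame(rows, columns=cols)


def assemble_model1_matrix(rr_wide_samples) -> pd.DataFrame:
    """n x 8 matrix of wide-band respiration features (Model 1 inputs)."""
    return _matrix(rr_wide_samples, "rr")


def assemble_model2_matrix(hr_samples, rr_band_samples) -> pd.DataFrame:
    """n x 16 matrix: cardiac features next to band-specific respiration
    features (Model 2 inputs).  Both lists must share sample order."""
    if len(hr_samples) != len(rr_band_samples):
        raise ValueError(
            f"sample count mismatch: {len(hr_samples)} HR vs "
            f"{len(rr_band_samples)} RR feature sets"
        )
    return pd.concat([_matrix(hr_samples, "hr"),
                      _matrix(rr_band_samples, "rr")], axis=1)
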