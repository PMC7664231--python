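"""Sheep temperature-humidity index (THI) from environment logger CSVs.

The sheep-specific index is

    THI = T - (0.31 - 0.31 RH) (T - 14.4)

with dry-bulb temperature ``T`` in degrees C and relative humidity
``RH`` as a fraction in [0, 1].  At RH = 1 or T = 14.4 degC the index
equals the temperature; above 14.4 degC, drier air lowers the index
(evaporative cooling is effective) while humid air pushes it back
toward T.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["thi", "read_env_log", "classify_chamber"]

#: Chamber condition ranges: (T_min, T_max, RH_min, RH_max).
CHAMBER_RANGES = {
    "control-range": (18.0, 21.0, 0.40, 0.50),
    "heat-range": (28.0, 40.0, 0.40, 0.60),
}


def thi(t_c, rh):
    """Sheep THI for temperature(s) in degC and RH fraction(s) in [0, 1].

    Values of RH in (1, 100] are interpreted as percentages and divided
    by 100 with a warning; RH < 0 or > 100 is an error.
    """
    t_c = np.asarray(t_c, float)
    rh = np.asarray(rh, float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be in [0, 1] "
                         "(or (1, 100] as a percentage)")
    if np.any(rh > 1):
        warnings.warn("RH > 1 interpreted as percent and divided by 100",
                      stacklevel=2)
        rh = np.where(rh > 1, rh / 100.0, rh)
    out = t_c - (0.31 - 0.31 * rh) * (t_c - 14.4)
    return out.item() if out.ndim == 0 else out


def classify_chamber(t_c: float, rh: float) -> str:
    """Label a record by the study chamber ranges (control 18-21 degC /
    40-50% RH; heat 28-40 degC / 40-60% RH) or ``"out-of-range"``."""
    for label, (t0, t1, r0, r1) in CHAMBER_RANGES.items():
        if t0 <= t_c <= t1 and r0 <= rh <= r1:
            return label
    return "out-of-range"


def read_env_log(path, expected_interval_min: float = 30.0) -> pd.DataFrame:
    """Read a logger CSV (``timestamp,t_c,rh``) and compute THI.

    Returns a DataFrame with columns timestamp, t_c, rh (fraction),
    thi and chamber classification.  Irregular logging intervals
    (loggers record every 30 min) trigger a warning, not an error.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "t_c", "rh"}
    if not required.issubset(df.columns):
        raise ValueError(f"environment log missing columns "
                         f"{sorted(required - set(df.columns))}")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    rh = df["rh"].to_numpy(float)
    if np.any(rh > 1):
        rh = np.where(rh > 1, rh / 100.0, rh)
    df["rh"] = rh
    df["thi"] = thi(df["t_c"].to_numpy(float), rh)
    df["chamber"] = [classify_chamber(t, r)
                     for t, r in zip(df["t_c"], df["rh"])]
    if len(df) > 1:
        gaps = df["timestamp"].diff().dropna()
        bad = gaps[np.abs(gaps.dt.total_seconds() / 60.0
                          - expected_interval_min) > 1.0]
        if len(bad):
            warnings.warn(
                f"{len(bad)} logging interval(s) deviate from "
                f"{expected_interval_min} min", stacklevel=2)
    return df
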