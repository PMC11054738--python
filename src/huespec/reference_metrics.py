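"""Instrument-side ripeness indices: DA-index and acoustic firmness.

The DA-index I_AD = A(670 nm) - A(720 nm) differences the absorbance at
the chlorophyll-a peak against a reference wavelength; it tracks
photosynthetically active chlorophyll and decays toward 0 as fruit
ripens.  Handheld DA meters report it on a 0-5 scale.

The acoustic firmness (stiffness) coefficient S = f^2 * m^(2/3), with
resonance frequency f (Hz) and mass m (g), declines monotonically as
the flesh softens.  Bench instruments report S on a g^(2/3) s^(-2)
scale of order 1-10; with f in raw Hz the formula is ~10^6 larger, so a
configurable instrument scale factor (default 1e-6, i.e. f effectively
in kHz) maps onto the reported scale without altering the formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DAReading",
    "FirmnessReading",
    "da_index",
    "acoustic_firmness",
    "READINGS_COLUMNS",
    "read_readings",
    "write_readings",
    "DEFAULT_FIRMNESS_SCALE",
]

DA_RANGE = (0.0, 5.0)
DEFAULT_FIRMNESS_SCALE = 1e-6

#: Schema of the instrument-readings CSV (one row per fruit per day).
#: l_star and b_star are stored for completeness but not analyzed.
READINGS_COLUMNS = [
    "sample_id",
    "group",
    "treatment",
    "day",
    "a670",
    "a720",
    "f_hz",
    "mass_g",
    "a_star",
    "l_star",
    "b_star",
]


def da_index(a670, a720):
    """I_AD = A670 - A720. Values outside the instrument's 0-5 range are flagged, never clamped."""
    a670 = np.asarray(a670, dtype=float)
    a720 = np.asarray(a720, dtype=float)
    if not (np.isfinite(a670).all() and np.isfinite(a720).all()):
        raise ValueError("absorbances must be finite")
    index = a670 - a720
    if ((index < DA_RANGE[0]) | (index > DA_RANGE[1])).any():
        warnings.warn(
            "DA-index outside the instrument range [0, 5]; value kept as-is",
            stacklevel=2,
        )
    return index if index.ndim else float(index)


def acoustic_firmness(f, m, scale: float = DEFAULT_FIRMNESS_SCALE):
    """S = scale * f^2 * m^(2/3) with f in Hz and m in g."""
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if (m <= 0).any():
        raise ValueError("mass must be positive")
    if (f < 0).any():
        raise ValueError("resonance frequency must be nonnegative")
    s = scale * f**2 * m ** (2.0 / 3.0)
    return s if s.ndim else float(s)


@dataclass(frozen=True)
class DAReading:
    """Two-wavelength absorbance reading and the derived chlorophyll index."""

    a670: float
    a720: float

    @property
    def index(self) -> float:
        return da_index(self.a670, self.a720)

    @property
    def in_range(self) -> bool:
        return DA_RANGE[0] <= self.a670 - self.a720 <= DA_RANGE[1]


@dataclass(frozen=True)
class FirmnessReading:
    """Resonance frequency (Hz) + mass (g) and the derived stiffness coefficient."""

    f: float
    m: float
    scale: float = DEFAULT_FIRMNESS_SCALE

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("mass must be positive")
        if self.f < 0:
            raise ValueError("resonance frequency must be nonnegative")

    @property
    def s(self) -> float:
        return acoustic_firmness(self.f, self.m, self.scale)


def read_readings(path) -> pd.DataFrame:
    """Load an instrument-readings CSV, validating the schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in READINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings CSV missing columns: {missing}")
    return df


def write_readings(df: pd.DataFrame, path) -> None:
    """Write a readings CSV; float formatting is round-trip exact."""
    missing = [c for c in READINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings table missing columns: {missing}")
    df.to_csv(path, index=False, columns=READINGS_COLUMNS)
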