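"""Polar Qualification System (PQS) surface compression of circular spectra.

A hue spectrum is read as a polar curve r(theta): the angle is the hue
bin center, the radius the bin's saturation mass.  The PQS *surface*
method summarizes the whole spectrum by the area centroid ("gravity
point") of the region enclosed by that curve, computed exactly per
sector for a piecewise-constant r:

    A = 1/2 * sum_i r_i^2 * dtheta
    X = 1/(3A) * sum_i r_i^3 * cos(theta_i) * dtheta
    Y = 1/(3A) * sum_i r_i^3 * sin(theta_i) * dtheta

Two axis orientations are supported.  ``"math"`` is the textbook
convention above (y up, angles counterclockwise).  ``"screen"`` — the
package default, matching raster-graphics axes with y pointing down —
negates Y, so that as fruit ripens from green hues (~110 deg) to red
(~8 deg) both coordinates of the gravity point increase.  The screen
convention is what the pipeline feature columns ``pqs_x``/``pqs_y`` use;
it makes PQS-Y co-vary positively with redness measures such as CIELAB
a*, mirroring how these coordinates behave in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .color_features import HueSpectrum

__all__ = ["PQSPoint", "OraclePoint", "gravity_point", "gravity_point_oracle"]

Orientation = Literal["math", "screen"]


@dataclass(frozen=True)
class PQSPoint:
    """Gravity point of a polar spectrum; dimensionless, on the spectrum's scale."""

    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class OraclePoint:
    """Monte-Carlo gravity-point estimate with per-coordinate standard errors."""

    x: float
    y: float
    se_x: float
    se_y: float
    n_accepted: int


def _spectrum_values(spectrum) -> np.ndarray:
    if isinstance(spectrum, HueSpectrum):
        return np.asarray(spectrum.values, dtype=float)
    values = np.asarray(spectrum, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("spectrum must be a 1-D array of at least 2 bins")
    return values


def _arc_mask(centers_deg: np.ndarray, hue_range: tuple[float, float]) -> np.ndarray:
    """Bins whose centers lie on the arc [a, b) degrees, wrapping through 0."""
    a, b = (hue_range[0] % 360.0, hue_range[1] % 360.0)
    if a == b:
        raise ValueError("hue_range must be a nonempty arc")
    c = centers_deg % 360.0
    if a < b:
        return (c >= a) & (c < b)
    return (c >= a) | (c < b)


def gravity_point(
    spectrum,
    hue_range: tuple[float, float] | None = None,
    orientation: Orientation = "screen",
) -> PQSPoint:
    """Area centroid of the polar region enclosed by the spectrum curve.

    Parameters
    ----------
    spectrum
        A :class:`~huespec.color_features.HueSpectrum` or a 1-D
        nonnegative array of n bins, taken to tile the full circle with
        width 360/n degrees each.
    hue_range
        Optional arc (start_deg, stop_deg), start inclusive / stop
        exclusive, wrapping through 0; bins outside are dropped before
        the centroid is taken (trimming indifferent hue segments).
    orientation
        ``"screen"`` (default; y axis down) or ``"math"`` (y axis up).

    Raises
    ------
    ValueError
        If the spectrum is negative anywhere or encloses zero area.
    """
    r = _spectrum_values(spectrum)
    if (r < 0).any():
        raise ValueError("spectrum must be nonnegative")
    n = r.size
    dtheta = 2.0 * np.pi / n
    centers_deg = (np.arange(n) + 0.5) * (360.0 / n)
    if hue_range is not None:
        keep = _arc_mask(centers_deg, hue_range)
        if not keep.any():
            raise ValueError("hue_range selects no bins")
        r = np.where(keep, r, 0.0)
    theta = np.deg2rad(centers_deg)
    area = 0.5 * np.sum(r**2) * dtheta
    if area == 0.0:
        raise ValueError("zero-area spectrum: gravity point undefined")
    x = np.sum(r**3 * np.cos(theta)) * dtheta / (3.0 * area)
    y = np.sum(r**3 * np.sin(theta)) * dtheta / (3.0 * area)
    if orientation == "screen":
        y = -y
    elif orientation != "math":
        raise ValueError(f"unknown orientation {orientation!r}")
    return PQSPoint(float(x), float(y))


def gravity_point_oracle(
    spectrum,
    n_samples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    orientation: Orientation = "math",
) -> OraclePoint:
    """Monte-Carlo gravity point: rejection sampling in the bounding disk.

    Uniform points are drawn in the disk of radius max(r); those with
    rho <= r(theta) are uniform over the enclosed region, so their mean
    estimates the centroid.  Intended as an independent cross-check of
    :func:`gravity_point`, not for production use.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10_000 for a usable standard error")
    r = _spectrum_values(spectrum)
    if (r < 0).any():
        raise ValueError("spectrum must be nonnegative")
    rmax = r.max()
    if rmax == 0.0:
        raise ValueError("zero-area spectrum: gravity point undefined")
    rng = np.random.default_rng(seed)
    n = r.size
    theta = rng.uniform(0.0, 2.0 * np.pi, n_samples)
    rho = rmax * np.sqrt(rng.uniform(0.0, 1.0, n_samples))
    bins = np.floor(theta / (2.0 * np.pi) * n).astype(np.intp) % n
    keep = rho <= r[bins]
    n_acc = int(keep.sum())
    if n_acc == 0:
        raise ValueError("acceptance rate 0: spectrum encloses a negligible region")
    xs = rho[keep] * np.cos(theta[keep])
    ys = rho[keep] * np.sin(theta[keep])
    if orientation == "screen":
        ys = -ys
    elif orientation != "math":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OraclePoint(
        x=float(xs.mean()),
        y=float(ys.mean()),
        se_x=float(xs.std(ddof=1) / np.sqrt(n_acc)),
        se_y=float(ys.std(ddof=1) / np.sqrt(n_acc)),
        n_accepted=n_acc,
    )
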