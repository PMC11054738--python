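"""ROI-restricted color descriptors for produce photographed on a white background.

The processing chain implemented here turns a raw RGB frame into the
color fingerprints used throughout the package:

1. white-balance against the (near-white, low-saturation) background so
   frames taken under drifting illumination are comparable;
2. convert to HSV, with hue in degrees [0, 360) and saturation in
   percent [0, 100];
3. threshold the saturation histogram (Otsu by default) to separate the
   vividly colored fruit from the gray background and specular glare;
4. accumulate the *hue spectrum* — a 360-bin circular distribution in
   which every ROI pixel contributes its saturation, so colors are
   weighted by their vividness rather than merely counted;
5. summarize mean RGB over the ROI and its intensity-normalized
   fractions R_N = R/(R+G+B), G_N, B_N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "RGBImage",
    "ROIMask",
    "HueSpectrum",
    "ColorSummary",
    "white_balance",
    "to_hsv",
    "saturation_threshold",
    "segment_roi",
    "hue_spectrum",
    "color_summary",
]

Normalization = Literal["raw_sum", "per_pixel"]

MIN_IMAGE_SIDE = 16
MIN_WHITE_PIXELS = 100


@dataclass
class RGBImage:
    """An 8-bit RGB raster (H x W x 3) plus provenance metadata."""

    pixels: np.ndarray
    source: str | None = None
    tag: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 raster, got shape {px.shape}")
        h, w = px.shape[:2]
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(f"image too small ({h}x{w}); need at least {MIN_IMAGE_SIDE} px per side")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ROIMask:
    """Boolean region-of-interest raster with the same H x W as its source."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise ValueError("mask must be a 2-D boolean raster")
        self.mask = m

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class HueSpectrum:
    """360-bin circular saturation-mass distribution; bin b covers [b, b+1) degrees."""

    values: np.ndarray
    normalization: Normalization = "per_pixel"
    roi_pixels: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (360,):
            raise ValueError(f"expected 360 bins, got {v.shape}")
        if (v < 0).any():
            raise ValueError("hue spectrum values must be nonnegative")
        self.values = v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"bin_deg": np.arange(360), "value": self.values})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ColorSummary:
    """Mean ROI channel intensities (0-255) and their intensity-free fractions."""

    red: float
    green: float
    blue: float
    r_n: float
    g_n: float
    b_n: float


def to_hsv(image: RGBImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone RGB -> HSV.

    Returns ``(hue_deg, sat_pct, value)`` with hue in degrees [0, 360),
    saturation in percent [0, 100] and value in [0, 1].  Achromatic
    pixels (max = min) get hue 0 and saturation 0.
    """
    hsv = rgb2hsv(image.pixels)
    hue_deg = hsv[..., 0] * 360.0
    # guard against 360.0 from rounding so the [0,360) contract holds
    hue_deg = np.where(hue_deg >= 360.0, 0.0, hue_deg)
    sat_pct = hsv[..., 1] * 100.0
    value = hsv[..., 2]
    return hue_deg, sat_pct, value


def _auto_white_region(image: RGBImage, sat_max_pct: float = 12.0, value_min: float = 0.65) -> ROIMask:
    """Low-saturation, high-value pixels taken as the white background."""
    _, sat, val = to_hsv(image)
    return ROIMask((sat <= sat_max_pct) & (val >= value_min))


def white_balance(
    image: RGBImage,
    white_region: ROIMask | None = None,
    reference_level: float = 240.0,
) -> RGBImage:
    """Apply per-channel gains so the white-region medians all equal ``reference_level``.

    ``white_region=None`` derives the region automatically from
    low-saturation, high-value pixels.  Output is clipped to [0, 255].
    """
    if white_region is None:
        white_region = _auto_white_region(image)
    m = white_region.mask
    if m.shape != image.shape:
        raise ValueError("white region shape does not match image")
    n_white = int(m.sum())
    if n_white < MIN_WHITE_PIXELS:
        raise ValueError(
            f"degenerate white region: {n_white} pixels (< {MIN_WHITE_PIXELS}); "
            "supply an explicit white_region"
        )
    px = image.pixels.astype(float)
    medians = np.median(px[m], axis=0)
    for channel, name in zip(medians, "RGB"):
        if channel == 0:
            raise ValueError(f"degenerate white region: channel {name} has zero median")
    gains = reference_level / medians
    balanced = np.clip(np.rint(px * gains), 0, 255).astype(np.uint8)
    return RGBImage(balanced, source=image.source, tag=image.tag)


#: minimum separation (saturation points) between the two Otsu classes for a
#: frame to count as containing vivid fruit at all
MIN_CLASS_SEPARATION = 5.0


def saturation_threshold(
    sat_pct: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    value: float | None = None,
    min_separation: float = MIN_CLASS_SEPARATION,
) -> float:
    """Threshold (percent, open interval (0,100)) separating background from fruit.

    Otsu's criterion is applied to the integer-percent saturation
    histogram (101 bins); ties in the between-class variance are broken
    by taking the midpoint of the optimal plateau, so a two-level image
    yields a threshold centered between the levels.  If the two classes
    the threshold induces have mean saturations closer than
    ``min_separation`` points, the histogram is effectively unimodal
    (a background-only frame) and segmentation is refused.
    """
    sat = np.asarray(sat_pct, dtype=float)
    if sat.size == 0:
        raise ValueError("empty saturation raster")
    if method == "fixed":
        if value is None or not 0.0 < value < 100.0:
            raise ValueError("fixed method requires a threshold value in (0, 100)")
        return float(value)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")

    levels = np.clip(np.floor(sat.ravel()), 0, 100).astype(np.intp)
    if levels.min() == levels.max():
        raise ValueError(
            "constant saturation raster: Otsu threshold undefined; use a fixed threshold"
        )
    hist = np.bincount(levels, minlength=101).astype(float)
    p = hist / hist.sum()
    grid = np.arange(101, dtype=float)
    w0 = np.cumsum(p)  # P(level <= t)
    mu = np.cumsum(p * grid)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    best = np.flatnonzero(between == between.max())
    threshold = float(best.mean())
    lo, hi = levels[levels <= threshold], levels[levels > threshold]
    if hi.size == 0 or lo.size == 0 or hi.mean() - lo.mean() < min_separation:
        raise ValueError(
            "no fruit found: saturation histogram is unimodal (class separation "
            f"< {min_separation} points); supply a fixed threshold to override"
        )
    return min(max(threshold, np.nextafter(0.0, 1.0)), np.nextafter(100.0, 0.0))


def segment_roi(sat_pct: np.ndarray, threshold: float) -> ROIMask:
    """Mask of pixels strictly above the saturation threshold.

    Gray background and specular glare fall below the threshold by
    construction and are excluded.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError(f"threshold must lie in (0, 100), got {threshold}")
    mask = np.asarray(sat_pct, dtype=float) > threshold
    if not mask.any():
        raise ValueError("no fruit found: no pixel exceeds the saturation threshold")
    return ROIMask(mask)


def hue_spectrum(
    hue_deg: np.ndarray,
    sat_pct: np.ndarray,
    mask: ROIMask,
    normalization: Normalization = "per_pixel",
) -> HueSpectrum:
    """Accumulate ROI saturation mass per integer hue degree.

    ``raw_sum`` conserves total ROI saturation exactly; ``per_pixel``
    divides by the ROI pixel count so frames with different fruit sizes
    are comparable.
    """
    m = mask.mask
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty ROI")
    bins = np.floor(np.asarray(hue_deg)[m]).astype(np.intp) % 360
    values = np.bincount(bins, weights=np.asarray(sat_pct, dtype=float)[m], minlength=360)
    if normalization == "per_pixel":
        values = values / n
    elif normalization != "raw_sum":
        raise ValueError(f"unknown normalization {normalization!r}")
    return HueSpectrum(values, normalization=normalization, roi_pixels=n)


def color_summary(image: RGBImage, mask: ROIMask) -> ColorSummary:
    """Mean R, G, B over the ROI and the normalized fractions R_N, G_N, B_N."""
    m = mask.mask
    if m.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("empty ROI")
    means = image.pixels[m].astype(float).mean(axis=0)
    total = means.sum()
    if total == 0:
        raise ValueError("black ROI: R + G + B = 0, normalized color undefined")
    r, g, b = means
    return ColorSummary(r, g, b, r / total, g / total, b / total)
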