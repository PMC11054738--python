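"""Synthetic tomato-ripening study generator with exact ground truth.

Emulates a two-week postharvest storage trial of cluster tomatoes
harvested at six maturity stages (CTIFL-based groups A mature-green
through F full-red), half of groups A-E treated with gaseous 1-MCP
(an ethylene-receptor blocker that slows climacteric ripening), group F
kept as the fully ripe absolute control with no treated arm.

Every fruit carries a latent ripeness state u in [0, 1] following a
logistic ("saturation") trajectory from its group-specific starting
point.  1-MCP multiplies the logistic rate by (1 - rho * efficacy_g),
with efficacy strongest for the mature-green and breaker groups.  All
observables derive monotonically from u:

* CIELAB a* rises linearly from green (~ -15) to red (~ +26);
* the DA chlorophyll index decays exponentially toward (but never
  below) zero;
* acoustic stiffness S declines from an initial 5-8 band toward a
  floor near 2, with a slow time-driven softening on top;
* surface hue drifts from ~115 deg (green) through yellow (~60 deg)
  down to ~8 deg (red), with saturation increasing as color develops.

Rendered frames place a noisy-hue disk on a near-white low-saturation
background with optional specular glare spots and color cast, and
return exact per-pixel ground truth (masks and the per-bin saturation
tally of the final quantized image) so segmentation and spectrum code
can be validated pixel-for-pixel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from . import reference_metrics
from .color_features import RGBImage, ROIMask, to_hsv

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RenderResult",
    "simulate_trajectories",
    "render_tomato_image",
    "simulate_study",
    "GROUPS",
    "TREATED_GROUPS",
]

GROUPS = ("A", "B", "C", "D", "E", "F")
#: group F is the fully ripe absolute control and is never treated
TREATED_GROUPS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and kinetic parameters of the synthetic trial.

    Defaults encode the trial layout (20 fruits per group and arm,
    sampling over a 14-day window) and kinetics calibrated to the
    published ranges: initial DA-index spanning ~1.3 down to ~0.003,
    initial stiffness uniform in 5-8 g^(2/3) s^-2, day-14 a* in the
    green-red band observed for control vs treated mature-green fruit.
    """

    n_fruit_per_group: int = 20
    sampling_days: tuple[int, ...] = (0, 2, 5, 7, 9, 12, 14)
    #: fractional slowing of the logistic ripening rate under 1-MCP
    treatment_effect: float = 0.9
    #: group-specific 1-MCP efficacy multipliers (strongest for A, B)
    efficacy: tuple[float, ...] = (1.0, 1.0, 0.6, 0.3, 0.2)
    #: baseline logistic rate (1/day)
    ripening_rate: float = 0.45
    #: initial latent ripeness per group A..F
    initial_ripeness: tuple[float, ...] = (0.02, 0.10, 0.25, 0.45, 0.65, 1.0)

    a_star_min: float = -15.0
    a_star_max: float = 26.0
    a_star_noise_sd: float = 2.0

    da_initial: float = 1.32
    da_decay: float = 6.1
    da_noise_sd: float = 0.02

    s_floor: float = 1.8
    s_initial_range: tuple[float, float] = (5.0, 8.0)
    s_time_decay: float = 0.02
    s_noise_sd: float = 0.3

    mass_mean_g: float = 110.0
    mass_sd_g: float = 5.0
    mass_range_g: tuple[float, float] = (100.0, 120.0)
    a720_base: float = 0.05
    a720_sd: float = 0.005
    firmness_scale: float = reference_metrics.DEFAULT_FIRMNESS_SCALE

    hue_green_deg: float = 115.0
    hue_red_deg: float = 8.0
    hue_noise_sd_deg: float = 6.0
    sat_base_pct: float = 45.0
    sat_span_pct: float = 25.0
    sat_noise_sd_pct: float = 8.0

    frame_px: int = 64
    diameter_px: int = 40
    glare_fraction: float = 0.05
    background_rgb: tuple[int, int, int] = (246, 245, 244)

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.treatment_effect <= 1.0:
            raise ValueError("treatment_effect must lie in [0, 1]")
        if len(self.efficacy) != len(TREATED_GROUPS):
            raise ValueError("one efficacy multiplier per treated group A-E required")
        if len(self.initial_ripeness) != len(GROUPS):
            raise ValueError("one initial ripeness per group A-F required")
        for name in ("a_star_noise_sd", "da_noise_sd", "s_noise_sd", "hue_noise_sd_deg", "sat_noise_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_fruit_per_group < 1:
            raise ValueError("need at least one fruit per group")

    def without_noise(self) -> "SimulationConfig":
        """Copy with every observation-noise SD set to zero (latent kinetics kept)."""
        return replace(
            self,
            a_star_noise_sd=0.0,
            da_noise_sd=0.0,
            s_noise_sd=0.0,
            hue_noise_sd_deg=0.0,
            sat_noise_sd_pct=0.0,
            a720_sd=0.0,
        )


@dataclass
class GroundTruth:
    """Latent states underlying the generated readings, one row per fruit per day."""

    table: pd.DataFrame  # sample_id, group, treatment, day, u, hue_center, sat_mean,
    #                      a_true, da_true, s_true

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table.sample_id == sample_id].sort_values("day")


@dataclass
class RenderResult:
    """A rendered frame plus pixel-exact bookkeeping."""

    image: RGBImage
    #: per-hue-degree saturation tally over the colored fruit pixels of the
    #: final quantized frame (raw-sum scale)
    tally: np.ndarray
    fruit_mask: np.ndarray  # colored fruit pixels (glare excluded)
    glare_mask: np.ndarray
    background_mask: np.ndarray

    @property
    def roi(self) -> ROIMask:
        return ROIMask(self.fruit_mask)


def _latent_ripeness(u0: float, t: np.ndarray, rate: float) -> np.ndarray:
    """Logistic trajectory from u0 toward 1; fully ripe fruit stays at 1."""
    if u0 >= 1.0:
        return np.ones_like(t, dtype=float)
    odds0 = (1.0 - u0) / u0
    return 1.0 / (1.0 + odds0 * np.exp(-rate * np.asarray(t, dtype=float)))


def simulate_trajectories(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the instrument-readings table and its latent ground truth.

    Returns ``(readings, truth)`` where ``readings`` follows the
    :data:`huespec.reference_metrics.READINGS_COLUMNS` schema (one row
    per fruit per sampling day) and ``truth`` carries the noise-free
    latent states the readings were derived from.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.sampling_days, dtype=float)
    eff = dict(zip(TREATED_GROUPS, config.efficacy))
    u0s = dict(zip(GROUPS, config.initial_ripeness))
    span = config.a_star_max - config.a_star_min

    readings_rows: list[dict] = []
    truth_rows: list[dict] = []
    for group in GROUPS:
        arms = ("control", "SF") if group in TREATED_GROUPS else ("control",)
        for arm in arms:
            slow = config.treatment_effect * eff[group] if arm == "SF" else 0.0
            rate = config.ripening_rate * (1.0 - slow)
            for fruit in range(config.n_fruit_per_group):
                sample_id = f"{group}-{arm}-{fruit:02d}"
                s0 = rng.uniform(*config.s_initial_range)
                mass = float(
                    np.clip(
                        rng.normal(config.mass_mean_g, config.mass_sd_g), *config.mass_range_g
                    )
                )
                u = _latent_ripeness(u0s[group], days, rate)
                a_true = config.a_star_min + span * u
                da_true = config.da_initial * np.exp(-config.da_decay * u)
                s_true = config.s_floor + (s0 - config.s_floor) * (1.0 - u) * np.exp(
                    -config.s_time_decay * days
                )
                hue_true = config.hue_green_deg - (config.hue_green_deg - config.hue_red_deg) * u
                sat_true = config.sat_base_pct + config.sat_span_pct * u

                a_star = a_true + rng.normal(0.0, config.a_star_noise_sd, days.size)
                da = np.maximum(da_true + rng.normal(0.0, config.da_noise_sd, days.size), 0.0)
                s_obs = np.maximum(s_true + rng.normal(0.0, config.s_noise_sd, days.size), 0.0)
                a720 = np.maximum(
                    config.a720_base + rng.normal(0.0, config.a720_sd, days.size), 0.001
                )
                f_hz = np.sqrt(s_obs / (config.firmness_scale * mass ** (2.0 / 3.0)))
                l_star = rng.normal(48.0, 3.0, days.size)
                b_star = rng.normal(25.0, 2.0, days.size) - 5.0 * u

                for i, day in enumerate(config.sampling_days):
                    readings_rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "treatment": arm,
                            "day": int(day),
                            "a670": float(da[i] + a720[i]),
                            "a720": float(a720[i]),
                            "f_hz": float(f_hz[i]),
                            "mass_g": mass,
                            "a_star": float(a_star[i]),
                            "l_star": float(l_star[i]),
                            "b_star": float(b_star[i]),
                        }
                    )
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "treatment": arm,
                            "day": int(day),
                            "u": float(u[i]),
                            "hue_center": float(hue_true[i]),
                            "sat_mean": float(sat_true[i]),
                            "a_true": float(a_true[i]),
                            "da_true": float(da_true[i]),
                            "s_true": float(s_true[i]),
                        }
                    )
    readings = pd.DataFrame(readings_rows, columns=reference_metrics.READINGS_COLUMNS)
    return readings, GroundTruth(pd.DataFrame(truth_rows))


def render_tomato_image(
    hue_center: float,
    sat_mean: float,
    diameter_px: int = 40,
    frame_px: int | tuple[int, int] = 64,
    background_rgb: tuple[int, int, int] = (246, 245, 244),
    glare_fraction: float = 0.05,
    hue_sd_deg: float = 6.0,
    sat_sd_pct: float = 8.0,
    value_mean: float = 0.85,
    value_sd: float = 0.04,
    seed: int | np.random.Generator | None = None,
) -> RenderResult:
    """Render one fruit disk on a near-white background with exact bookkeeping.

    Fruit pixels draw hue from a wrapped normal around ``hue_center``
    and saturation from a truncated normal around ``sat_mean`` (kept
    >= 20% so the fruit always clears a histogram threshold), while the
    background stays below ~6% saturation; glare spots are rendered
    near-white so segmentation must exclude them.  The returned tally
    is the per-degree saturation mass of the *final 8-bit frame* over
    the colored fruit pixels — the reference any spectrum extraction
    must conserve.
    """
    if not 0.0 <= hue_center < 360.0:
        raise ValueError("hue_center must lie in [0, 360)")
    if not 0.0 < sat_mean <= 100.0:
        raise ValueError("sat_mean must lie in (0, 100]")
    h, w = (frame_px, frame_px) if isinstance(frame_px, int) else frame_px
    if diameter_px > min(h, w):
        raise ValueError(f"disk diameter {diameter_px} exceeds frame {h}x{w}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = diameter_px / 2.0
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    glare = np.zeros_like(disk)
    if glare_fraction > 0 and disk.any():
        g_radius = radius * np.sqrt(glare_fraction)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        dist = rng.uniform(0.0, 0.5) * radius
        gy, gx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        glare = disk & ((yy - gy) ** 2 + (xx - gx) ** 2 <= g_radius**2)
    fruit = disk & ~glare
    background = ~disk
    if not fruit.any():
        raise ValueError("no colored fruit pixels; reduce glare_fraction")

    hsv = np.zeros((h, w, 3), dtype=float)
    n_f = int(fruit.sum())
    hsv[fruit, 0] = ((hue_center + rng.normal(0.0, hue_sd_deg, n_f)) % 360.0) / 360.0
    hsv[fruit, 1] = np.clip(rng.normal(sat_mean, sat_sd_pct, n_f), 20.0, 100.0) / 100.0
    hsv[fruit, 2] = np.clip(rng.normal(value_mean, value_sd, n_f), 0.3, 1.0)
    n_g = int(glare.sum())
    if n_g:
        hsv[glare, 0] = rng.uniform(0.0, 1.0, n_g)
        hsv[glare, 1] = rng.uniform(0.005, 0.03, n_g)
        hsv[glare, 2] = np.clip(rng.normal(0.96, 0.01, n_g), 0.9, 1.0)

    rgb = np.empty((h, w, 3), dtype=float)
    fg = fruit | glare
    rgb[fg] = hsv2rgb(hsv[fg][:, None, :]).reshape(-1, 3)
    base = np.asarray(background_rgb, dtype=float) / 255.0
    n_b = int(background.sum())
    rgb[background] = np.clip(base + rng.normal(0.0, 1.5 / 255.0, (n_b, 3)), 0.0, 1.0)
    pixels = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    image = RGBImage(pixels, tag="synthetic-render")

    # bookkeeping on the quantized frame, restricted to the true fruit mask
    hue_deg, sat_pct, _ = to_hsv(image)
    bins = np.floor(hue_deg[fruit]).astype(np.intp) % 360
    tally = np.bincount(bins, weights=sat_pct[fruit], minlength=360)
    return RenderResult(
        image=image, tally=tally, fruit_mask=fruit, glare_mask=glare, background_mask=background
    )


def simulate_study(config: SimulationConfig, outdir) -> Path:
    """Write the full synthetic study to disk; byte-identical under a fixed seed.

    Layout::

        outdir/
          images/{group}_{arm}_{fruit:02d}_{day:02d}.png
          readings.csv      (instrument schema)
          truth.json        (latent trajectories)
          config.yaml       (resolved configuration snapshot)
    """
    from PIL import Image
    import yaml

    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"parent directory {outdir.parent} does not exist")
    (outdir / "images").mkdir(parents=True, exist_ok=True)

    readings, truth = simulate_trajectories(config)
    reference_metrics.write_readings(readings, outdir / "readings.csv")

    render_seeds = np.random.SeedSequence(config.seed).spawn(len(truth.table))
    for row, seq in zip(truth.table.itertuples(), render_seeds):
        result = render_tomato_image(
            hue_center=row.hue_center % 360.0,
            sat_mean=row.sat_mean,
            diameter_px=config.diameter_px,
            frame_px=config.frame_px,
            background_rgb=config.background_rgb,
            glare_fraction=config.glare_fraction,
            hue_sd_deg=config.hue_noise_sd_deg,
            sat_sd_pct=config.sat_noise_sd_pct,
            seed=np.random.default_rng(seq),
        )
        name = f"{row.group}_{row.treatment}_{int(row.sample_id.split('-')[-1]):02d}_{row.day:02d}.png"
        Image.fromarray(result.image.pixels).save(outdir / "images" / name)

    truth.table.to_json(outdir / "truth.json", orient="records", indent=2)
    snapshot = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config).items()
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    return outdir
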