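"""End-to-end glue: extract features from frames, join instruments, analyze.

These functions back the command-line interface but are usable directly:
``extract_image_features`` handles one frame, ``run_study`` performs the
whole simulate -> render -> extract -> join loop in memory, and
``analyze_features`` produces the factorial-ANOVA / post-hoc /
correlation report.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import color_features as cf
from . import reference_metrics, stats
from .pqs import gravity_point
from .synthetic_data import (
    GROUPS,
    TREATED_GROUPS,
    SimulationConfig,
    render_tomato_image,
    simulate_trajectories,
)

__all__ = [
    "ExtractionConfig",
    "extract_image_features",
    "extract_directory",
    "run_study",
    "analyze_features",
    "report_markdown",
    "IMAGE_FEATURES",
    "TABLE8_FEATURES",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

#: machine-vision feature columns, in the canonical report order
IMAGE_FEATURES = ["red", "green", "blue", "r_n", "g_n", "b_n", "pqs_x", "pqs_y"]
#: cross-instrument correlation panel: stiffness, chlorophyll index,
#: colorimeter a*, normalized color, PQS coordinates
TABLE8_FEATURES = ["firmness_s", "da_index", "a_star", "r_n", "g_n", "pqs_x", "pqs_y"]

_NAME_RE = re.compile(r"^(?P<group>[A-F])_(?P<arm>control|SF)_(?P<fruit>\d+)_(?P<day>\d+)\.(png|jpg|jpeg)$", re.I)


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-extraction knobs shared by the CLI and the in-memory pipeline."""

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    threshold_value: float | None = None
    normalization: Literal["per_pixel", "raw_sum"] = "per_pixel"
    hue_range: tuple[float, float] | None = None
    orientation: Literal["screen", "math"] = "screen"
    white_balance: bool = True
    reference_level: float = 240.0


def extract_image_features(
    image: cf.RGBImage, config: ExtractionConfig = ExtractionConfig()
) -> dict[str, float]:
    """Full single-frame chain: balance -> HSV -> threshold -> ROI -> spectrum -> PQS."""
    if config.white_balance:
        image = cf.white_balance(image, reference_level=config.reference_level)
    hue, sat, _ = cf.to_hsv(image)
    threshold = cf.saturation_threshold(
        sat, method=config.threshold_method, value=config.threshold_value
    )
    roi = cf.segment_roi(sat, threshold)
    spectrum = cf.hue_spectrum(hue, sat, roi, normalization=config.normalization)
    point = gravity_point(spectrum, hue_range=config.hue_range, orientation=config.orientation)
    summary = cf.color_summary(image, roi)
    return {
        "red": summary.red,
        "green": summary.green,
        "blue": summary.blue,
        "r_n": summary.r_n,
        "g_n": summary.g_n,
        "b_n": summary.b_n,
        "pqs_x": point.x,
        "pqs_y": point.y,
        "roi_pixels": float(roi.pixel_count),
        "threshold": float(threshold),
    }


def extract_directory(
    images_dir, config: ExtractionConfig = ExtractionConfig()
) -> pd.DataFrame:
    """One feature row per readable ``{group}_{arm}_{fruit}_{day}`` frame.

    Unreadable or unparseable files are skipped with a warning.
    """
    from PIL import Image

    images_dir = Path(images_dir)
    paths = sorted(p for p in images_dir.iterdir() if p.is_file())
    if not paths:
        raise ValueError(f"no images found in {images_dir}")
    rows = []
    for path in paths:
        m = _NAME_RE.match(path.name)
        if m is None:
            warnings.warn(f"skipping {path.name}: name does not match the study layout")
            continue
        try:
            pixels = np.asarray(Image.open(path).convert("RGB"))
            feats = extract_image_features(cf.RGBImage(pixels, source=str(path)), config)
        except Exception as exc:  # noqa: BLE001 - skip-with-warning contract
            warnings.warn(f"skipping {path.name}: {exc}")
            continue
        rows.append(
            {
                "sample_id": f"{m['group']}-{m['arm']}-{int(m['fruit']):02d}",
                "group": m["group"],
                "treatment": m["arm"],
                "day": int(m["day"]),
                **feats,
            }
        )
    if not rows:
        raise ValueError(f"no readable study images in {images_dir}")
    return pd.DataFrame(rows)


def _derive_instrument_features(readings: pd.DataFrame, firmness_scale: float) -> pd.DataFrame:
    out = readings.copy()
    out["da_index"] = reference_metrics.da_index(out["a670"].to_numpy(), out["a720"].to_numpy())
    out["firmness_s"] = reference_metrics.acoustic_firmness(
        out["f_hz"].to_numpy(), out["mass_g"].to_numpy(), scale=firmness_scale
    )
    return out


def run_study(
    config: SimulationConfig = SimulationConfig(),
    extraction: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Simulate, render and extract the whole study in memory.

    Returns the joined feature table: instrument readings (a*, DA-index,
    stiffness) plus machine-vision features per fruit per day.
    """
    readings, truth = simulate_trajectories(config)
    readings = _derive_instrument_features(readings, config.firmness_scale)
    render_seeds = np.random.SeedSequence(config.seed).spawn(len(truth.table))
    feats = []
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
        feats.append(extract_image_features(result.image, extraction))
    image_feats = pd.DataFrame(feats)
    return pd.concat([readings.reset_index(drop=True), image_feats], axis=1)


def _route_posthoc(groups: dict[str, np.ndarray], alpha: float) -> tuple[str, stats.PosthocResult]:
    """Levene-routed post hoc: Tukey HSD if variances homogeneous, else Games-Howell."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, lev_p = stats.levene(groups)
    if np.isnan(lev_p) or lev_p >= alpha:
        return "tukey_hsd", stats.tukey_hsd(groups, alpha=alpha)
    return "games_howell", stats.games_howell(groups, alpha=alpha)


def analyze_features(
    features: pd.DataFrame,
    alpha: float = stats.DEFAULT_ALPHA,
    final_day: int | None = None,
) -> dict:
    """Factorial ANOVA, day-final post hocs and correlation matrices.

    The factorial design (maturity group x treatment x storage day,
    pairwise interactions) excludes the untreated fully ripe group F,
    whose treated cell is empty and would make the group x treatment
    interaction inestimable.
    """
    if features.empty:
        raise ValueError("empty feature table")
    final_day = int(features.day.max()) if final_day is None else final_day
    factorial = features[features.group.isin(TREATED_GROUPS)]
    if factorial.group.nunique() < 2 or factorial.treatment.nunique() < 2:
        raise ValueError("factorial analysis needs >= 2 maturity groups and both treatment arms")

    anova: dict[str, dict] = {}
    responses = [c for c in IMAGE_FEATURES + ["a_star", "da_index", "firmness_s"] if c in features]
    for response in responses:
        res = stats.factorial_anova(
            factorial, response, factors=["group", "treatment", "day"], interactions="pairwise"
        )
        anova[response] = {
            r.term: {"F": r.F, "df_num": r.df_num, "df_den": r.df_den, "p": r.p}
            for r in res.table.itertuples()
        }

    day_final = features[features.day == final_day]
    posthoc: dict[str, dict] = {}
    for response in [c for c in ("a_star", "da_index", "firmness_s") if c in features]:
        entry: dict = {"by_maturity": {}, "by_treatment": {}}
        for arm in ("control", "SF"):
            sub = day_final[(day_final.treatment == arm) & day_final.group.isin(TREATED_GROUPS)]
            groups = {g: sub[sub.group == g][response].to_numpy() for g in sorted(sub.group.unique())}
            if len(groups) < 2:
                continue
            test, result = _route_posthoc(groups, alpha)
            entry["by_maturity"][arm] = {
                "test": test,
                "letters": result.letters,
                "p": {
                    f"{a}|{b}": result.p(a, b)
                    for a, b in itertools.combinations(result.letters, 2)
                },
            }
        for g in TREATED_GROUPS:
            sub = day_final[day_final.group == g]
            groups = {arm: sub[sub.treatment == arm][response].to_numpy() for arm in ("control", "SF")}
            if any(v.size < 2 for v in groups.values()):
                continue
            test, result = _route_posthoc(groups, alpha)
            entry["by_treatment"][g] = {
                "test": test,
                "p": result.p("control", "SF"),
                "significant": bool(result.significant("control", "SF")),
            }
        posthoc[response] = entry

    pearson_r, pearson_p = stats.correlation_matrix(features, IMAGE_FEATURES, "pearson")
    spear_feats = [c for c in TABLE8_FEATURES if c in features]
    spearman_r, spearman_p = stats.correlation_matrix(features, spear_feats, "spearman")

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "alpha": alpha,
        "final_day": final_day,
        "n_rows": int(len(features)),
        "anova": anova,
        "posthoc_day_final": posthoc,
        "pearson": {"r": pearson_r.round(6).to_dict(), "p": pearson_p.to_dict()},
        "spearman": {"r": spearman_r.round(6).to_dict(), "p": spearman_p.to_dict()},
    }


def _letters_row(letters: dict[str, str]) -> str:
    return " | ".join(f"{k}: {v}" for k, v in sorted(letters.items()))


def report_markdown(report: dict) -> str:
    """Render the analysis report as Markdown tables."""
    lines = ["# Ripeness analysis report", ""]
    lines += [f"alpha = {report['alpha']}, final day = {report['final_day']}, rows = {report['n_rows']}", ""]

    lines += ["## Factorial ANOVA (F values)", ""]
    terms = ["group", "treatment", "day", "group:treatment", "group:day", "treatment:day"]
    lines += ["| Parameter | " + " | ".join(terms) + " |",
              "|" + "---|" * (len(terms) + 1)]
    for response, table in report["anova"].items():
        cells = []
        for t in terms:
            row = table.get(t)
            mark = "" if row is None else ("**" if row["p"] < 0.01 else "*" if row["p"] < 0.05 else "")
            cells.append("" if row is None else f"{row['F']:.2f}{mark}")
        lines.append(f"| {response} | " + " | ".join(cells) + " |")
    lines.append("")

    lines += ["## Final-day post hocs (letters: levels sharing a letter are not different)", ""]
    for response, entry in report["posthoc_day_final"].items():
        lines.append(f"### {response}")
        for arm, block in entry["by_maturity"].items():
            lines.append(f"- {arm} ({block['test']}): {_letters_row(block['letters'])}")
        sig = [g for g, b in entry["by_treatment"].items() if b["significant"]]
        lines.append(f"- treatment effect significant in groups: {', '.join(sig) if sig else 'none'}")
        lines.append("")

    for method in ("pearson", "spearman"):
        r = pd.DataFrame(report[method]["r"])
        lines += [f"## {method.capitalize()} correlation (r)", "", r.round(3).to_markdown(), ""]
    return "\n".join(lines)
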