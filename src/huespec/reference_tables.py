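"""Published day-14 summary statistics used as worked-example inputs.

Group means and standard deviations reported for a two-week 15 degC
storage trial of 'Pitenza' cluster tomatoes harvested at five maturity
stages (A mature green, B breaker, C turning, D pink, E light red),
half of each group treated with gaseous 1-MCP (SmartFresh, "SF").
Each group held 20 fruits measured at two points per fruit, so the
per-cell sample size for reconstructing the published post hoc letter
displays is 40 readings.

These are *inputs* for the Games-Howell worked example (reconstructing
the published compact-letter superscripts from summary statistics
alone), not outputs of this package.
"""

from __future__ import annotations

__all__ = [
    "A_STAR_DAY14",
    "DA_INDEX_DAY14",
    "FIRMNESS_DAY14",
    "N_FRUITS_PER_GROUP",
    "READINGS_PER_FRUIT",
    "N_READINGS",
    "summaries",
]

N_FRUITS_PER_GROUP = 20
READINGS_PER_FRUIT = 2
N_READINGS = N_FRUITS_PER_GROUP * READINGS_PER_FRUIT

#: CIELAB a* (green-red axis) at day 14: {arm: {group: (mean, sd)}}
A_STAR_DAY14 = {
    "control": {
        "A": (21.09, 3.48),
        "B": (20.73, 2.85),
        "C": (23.64, 1.80),
        "D": (24.83, 1.79),
        "E": (25.46, 1.16),
    },
    "SF": {
        "A": (-11.43, 2.95),
        "B": (-11.07, 2.19),
        "C": (12.63, 4.76),
        "D": (18.73, 2.32),
        "E": (20.89, 3.23),
    },
}

#: DA chlorophyll index at day 14
DA_INDEX_DAY14 = {
    "control": {
        "A": (0.055, 0.065),
        "B": (0.094, 0.169),
        "C": (0.010, 0.019),
        "D": (0.006, 0.011),
        "E": (0.007, 0.011),
    },
    "SF": {
        "A": (1.050, 0.290),
        "B": (0.939, 0.246),
        "C": (0.047, 0.070),
        "D": (0.005, 0.011),
        "E": (0.007, 0.017),
    },
}

#: acoustic stiffness S (g^(2/3) s^-2) at day 14
FIRMNESS_DAY14 = {
    "control": {
        "A": (2.37, 0.64),
        "B": (2.29, 0.62),
        "C": (2.23, 0.63),
        "D": (2.10, 0.56),
        "E": (2.04, 0.59),
    },
    "SF": {
        "A": (4.20, 0.87),
        "B": (3.95, 0.83),
        "C": (3.07, 0.95),
        "D": (2.94, 1.10),
        "E": (3.13, 0.75),
    },
}


def summaries(table: dict, arm: str, n: int = N_READINGS) -> dict[str, tuple[float, float, int]]:
    """One arm's column as Games-Howell summary input {group: (mean, sd, n)}."""
    return {g: (m, sd, n) for g, (m, sd) in table[arm].items()}
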