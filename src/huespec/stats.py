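"""Factorial ANOVA, variance-homogeneity routing, post hocs and correlations.

The analysis layer mirrors a standard postharvest quality workflow:

* fixed-effects factorial ANOVA (Type III sums of squares with
  sum-to-zero contrasts, the SPSS convention) for maturity group,
  treatment and storage-time effects plus pairwise interactions;
* Levene's test routes each response to Tukey's HSD (homogeneous
  variances) or the Games-Howell procedure (heterogeneous variances);
* pairwise post-hoc p-values are condensed into a compact letter
  display — levels sharing a letter are not significantly different;
* Pearson and Spearman correlation matrices relate instrument indices
  to machine-vision features (Spearman covers the expected nonlinear,
  saturating kinetics).

Games-Howell accepts either raw samples or published summary statistics
(mean, SD, n), so letter displays can be reconstructed directly from a
printed table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "levene",
    "factorial_anova",
    "tukey_hsd",
    "games_howell",
    "compact_letters",
    "correlation_matrix",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05

_F_CAP = np.finfo(float).max


@dataclass
class AnovaResult:
    """Per-term F statistics of a fixed-effects factorial model."""

    table: pd.DataFrame  # columns: term, F, df_num, df_den, p
    response: str

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(f"no term {name!r} in ANOVA table")
        return rows.iloc[0]


@dataclass
class PosthocResult:
    """Pairwise adjusted p-values plus a compact letter display."""

    table: pd.DataFrame  # columns: level_i, level_j, diff, se, statistic, df, p_adj
    letters: dict[str, str]
    alpha: float = DEFAULT_ALPHA

    def p(self, a: str, b: str) -> float:
        t = self.table
        hit = t[((t.level_i == a) & (t.level_j == b)) | ((t.level_i == b) & (t.level_j == a))]
        if hit.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(hit.iloc[0].p_adj)

    def significant(self, a: str, b: str) -> bool:
        return self.p(a, b) < self.alpha

    def partition(self) -> list[frozenset[str]]:
        """Levels grouped by identical letter strings (exact-tie partition)."""
        out: dict[str, set[str]] = {}
        for level, letters in self.letters.items():
            out.setdefault(letters, set()).add(level)
        return [frozenset(v) for v in out.values()]


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def levene(
    groups,
    center: Literal["mean", "median"] = "mean",
) -> tuple[float, float]:
    """Levene's variance-homogeneity test on absolute deviations from the group center.

    Returns ``(statistic, p)``.  With every group internally constant
    the statistic is undefined (0/0); the pair ``(nan, nan)`` is
    returned with a warning so callers can route explicitly.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("levene requires at least 2 groups")
    for name, values in g.items():
        if values.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    devs = [np.abs(v - (np.mean(v) if center == "mean" else np.median(v))) for v in g.values()]
    if all((d == 0).all() for d in devs):
        warnings.warn("all groups internally constant: Levene statistic undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    stat, p = sps.levene(*g.values(), center=center)
    return float(stat), float(p)


def _check_cells(table: pd.DataFrame, pair: tuple[str, str]) -> None:
    counts = pd.crosstab(table[pair[0]], table[pair[1]])
    empty = counts.stack()[counts.stack() == 0]
    if not empty.empty:
        (a, b) = empty.index[0]
        raise ValueError(
            f"empty cell ({pair[0]}={a}, {pair[1]}={b}): interaction "
            f"{pair[0]}:{pair[1]} is inestimable"
        )


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interactions: Literal["pairwise", "none"] | Sequence[tuple[str, str]] = "pairwise",
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with Type III sums of squares.

    Factors are coded with sum-to-zero contrasts so Type III main
    effects are interpretable in the presence of interactions.
    ``interactions`` may be ``"pairwise"`` (all two-way terms),
    ``"none"``, or an explicit list of factor pairs.  Perfect fits are
    reported with F capped at the largest representable float.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(factors) < 1:
        raise ValueError("at least one factor required")
    data = table[[response, *factors]].dropna().copy()
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, found {data[f].nunique()}")
        data[f] = data[f].astype(str)
    if not np.issubdtype(np.asarray(data[response]).dtype, np.number):
        raise ValueError(f"response {response!r} must be numeric")

    if interactions == "pairwise":
        pairs = list(itertools.combinations(factors, 2))
    elif interactions == "none":
        pairs = []
    else:
        pairs = [tuple(p) for p in interactions]
    for pair in pairs:
        _check_cells(data, pair)

    def enc(f: str) -> str:
        return f'C(Q("{f}"), Sum)'

    terms = [enc(f) for f in factors] + [f"{enc(a)}:{enc(b)}" for a, b in pairs]
    formula = f'Q("{response}") ~ ' + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual fits emit divide warnings
        aov = sm.stats.anova_lm(model, typ=3)

    pretty = {enc(f): f for f in factors}
    pretty.update({f"{enc(a)}:{enc(b)}": f"{a}:{b}" for a, b in pairs})
    df_resid = float(aov.loc["Residual", "df"])
    rows = []
    for raw_name, friendly in pretty.items():
        row = aov.loc[raw_name]
        f_val = float(row["F"])
        p_val = float(row["PR(>F)"])
        if np.isnan(f_val):  # constant response: 0/0
            f_val, p_val = 0.0, 1.0
        elif not np.isfinite(f_val):  # perfect fit: report at the numerical cap
            f_val, p_val = _F_CAP, 0.0
        rows.append(
            {"term": friendly, "F": f_val, "df_num": float(row["df"]), "df_den": df_resid, "p": p_val}
        )
    return AnovaResult(table=pd.DataFrame(rows), response=response)


def _letters_from_pairs(
    levels: Sequence[str], pvals: Mapping[tuple[str, str], float], alpha: float
) -> dict[str, str]:
    sets: list[set[str]] = [set(levels)]
    for (a, b), p in pvals.items():
        if p >= alpha:
            continue
        next_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                next_sets.extend([s - {a}, s - {b}])
            else:
                next_sets.append(s)
        # absorb: drop any set contained in another
        sets = [
            s
            for i, s in enumerate(next_sets)
            if s and not any(i != j and s < t or (s == t and i > j) for j, t in enumerate(next_sets))
        ]
    order = {lv: i for i, lv in enumerate(levels)}
    sets.sort(key=lambda s: min(order[lv] for lv in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, s in zip(alphabet, sets):
        for lv in s:
            out[lv] += letter
    return out


def compact_letters(
    pvals: Mapping[tuple[str, str], float] | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    levels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a complete pairwise p map.

    Levels connected by an adjusted p >= alpha share at least one
    letter; the letter set is minimal in the insert-absorb sense.
    """
    if isinstance(pvals, pd.DataFrame):
        pairs = {
            (str(r.level_i), str(r.level_j)): float(r.p_adj) for r in pvals.itertuples()
        }
    else:
        pairs = {(str(a), str(b)): float(p) for (a, b), p in pvals.items()}
    if levels is None:
        seen: list[str] = []
        for a, b in pairs:
            for lv in (a, b):
                if lv not in seen:
                    seen.append(lv)
        levels = seen
    expected = {frozenset(p) for p in itertools.combinations(levels, 2)}
    got = {frozenset(p) for p in pairs}
    if expected - got:
        raise ValueError(f"incomplete pairwise matrix; missing {sorted(map(sorted, expected - got))}")
    return _letters_from_pairs(list(levels), pairs, alpha)


def _posthoc_frame(rows: list[dict], levels: Sequence[str], alpha: float) -> PosthocResult:
    table = pd.DataFrame(rows)
    pvals = {(r["level_i"], r["level_j"]): r["p_adj"] for r in rows}
    letters = _letters_from_pairs(list(levels), pvals, alpha)
    return PosthocResult(table=table, letters=letters, alpha=alpha)


def tukey_hsd(groups, alpha: float = DEFAULT_ALPHA) -> PosthocResult:
    """Tukey's HSD (Tukey-Kramer for unequal n) on raw samples.

    Pairwise p-values come from the studentized-range distribution with
    the pooled within-group variance; intended for the
    homogeneous-variance route after Levene.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    for name, v in g.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    k = len(g)
    n_total = sum(v.size for v in g.values())
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in g.values()) / df_err
    levels = list(g)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        va, vb = g[a], g[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        if se == 0.0:
            if diff == 0.0:
                q, p = 0.0, 1.0
            else:
                warnings.warn("zero pooled SE with unequal means; p set to 0", stacklevel=2)
                q, p = np.inf, 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append(
            {
                "level_i": a,
                "level_j": b,
                "diff": float(diff),
                "se": float(se),
                "statistic": float(q),
                "df": float(df_err),
                "p_adj": float(np.clip(p, 0.0, 1.0)),
            }
        )
    return _posthoc_frame(rows, levels, alpha)


def _as_summaries(data) -> dict[str, tuple[float, float, int]]:
    out: dict[str, tuple[float, float, int]] = {}
    for name, v in data.items():
        if isinstance(v, tuple) and len(v) == 3:
            mean, sd, n = float(v[0]), float(v[1]), int(v[2])
        else:
            arr = np.asarray(v, dtype=float)
            mean, sd, n = float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
        if n < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        if sd < 0:
            raise ValueError(f"group {name!r} has negative SD")
        out[str(name)] = (mean, sd, n)
    return out


def games_howell(data, alpha: float = DEFAULT_ALPHA) -> PosthocResult:
    """Games-Howell pairwise comparisons (unequal variances and n).

    ``data`` maps level -> raw sample array or level -> (mean, sd, n),
    so published summary tables can be re-analyzed directly.  Each pair
    uses a Welch t statistic with Welch-Satterthwaite degrees of
    freedom, referred to the studentized-range distribution via
    q = t * sqrt(2).
    """
    summ = _as_summaries(data)
    if len(summ) < 2:
        raise ValueError("games_howell requires at least 2 groups")
    k = len(summ)
    levels = list(summ)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        m1, s1, n1 = summ[a]
        m2, s2, n2 = summ[b]
        v1, v2 = s1**2 / n1, s2**2 / n2
        diff = m1 - m2
        se = np.sqrt(v1 + v2)
        if se == 0.0:
            if diff == 0.0:
                t, df, p = 0.0, float(n1 + n2 - 2), 1.0
            else:
                warnings.warn("zero pooled SE with unequal means; p set to 0", stacklevel=2)
                t, df, p = np.inf, float(n1 + n2 - 2), 0.0
        else:
            t = abs(diff) / se
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        rows.append(
            {
                "level_i": a,
                "level_j": b,
                "diff": float(diff),
                "se": float(se),
                "statistic": float(t),
                "df": float(df),
                "p_adj": float(np.clip(p, 0.0, 1.0)),
            }
        )
    return _posthoc_frame(rows, levels, alpha)


def correlation_matrix(
    table: pd.DataFrame,
    features: Sequence[str],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric (r, p) matrices over pairwise-complete rows.

    Constant features yield NaN entries with a warning rather than an
    error, mirroring how statistics packages report undefined r.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    r = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    p = pd.DataFrame(np.zeros((len(features), len(features))), index=features, columns=features)
    for a, b in itertools.combinations(features, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete rows for pair ({a}, {b})")
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            warnings.warn(f"constant feature in pair ({a}, {b}); correlation undefined", stacklevel=2)
            rv = pv = float("nan")
        else:
            res = fn(sub[a], sub[b])
            rv, pv = float(res.statistic), float(res.pvalue)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p
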