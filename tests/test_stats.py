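"""Statistics layer: Levene, factorial ANOVA, post hocs, letters, correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from huespec import stats as hs


class TestLevene:
    def test_hand_arithmetic_oracle(self):
        # Levene statistic = one-way ANOVA F on |deviations from group mean|
        g1, g2 = np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0])
        stat, p = hs.levene([g1, g2])
        d1, d2 = np.abs(g1 - g1.mean()), np.abs(g2 - g2.mean())
        grand = np.concatenate([d1, d2]).mean()
        ss_between = 3 * (d1.mean() - grand) ** 2 + 3 * (d2.mean() - grand) ** 2
        ss_within = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert stat == pytest.approx(f_hand, rel=1e-12)

    def test_degenerate_constant_groups_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            stat, p = hs.levene([[5.0, 5.0, 5.0], [7.0, 7.0]])
        assert np.isnan(stat) and np.isnan(p)

    def test_median_center_matches_scipy(self, rng):
        groups = [rng.normal(size=15), rng.normal(size=20)]
        from scipy.stats import levene as scipy_levene

        stat, p = hs.levene(groups, center="median")
        ref = scipy_levene(*groups, center="median")
        assert (stat, p) == pytest.approx((ref.statistic, ref.pvalue))

    def test_small_group_fails(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            hs.levene([[1.0], [2.0, 3.0]])


def balanced_twoway_oracle(df, response):
    """Textbook sums-of-squares decomposition for a balanced two-way layout."""
    y = df[response]
    grand = y.mean()
    out = {}
    ss = {}
    for factor in ("fa", "fb"):
        parts = df.groupby(factor)[response]
        ss[factor] = sum(len(v) * (v.mean() - grand) ** 2 for _, v in parts)
    cells = df.groupby(["fa", "fb"])[response]
    ss_cells = sum(len(v) * (v.mean() - grand) ** 2 for _, v in cells)
    ss["ab"] = ss_cells - ss["fa"] - ss["fb"]
    ss_err = sum(((v - v.mean()) ** 2).sum() for _, v in cells)
    a, b = df.fa.nunique(), df.fb.nunique()
    df_err = len(df) - a * b
    out["fa"] = (ss["fa"] / (a - 1)) / (ss_err / df_err)
    out["fb"] = (ss["fb"] / (b - 1)) / (ss_err / df_err)
    out["fa:fb"] = (ss["ab"] / ((a - 1) * (b - 1))) / (ss_err / df_err)
    return out


class TestFactorialAnova:
    def make_2x2(self, rng, effect_a=0.0, noise=1.0, n=3):
        rows = []
        for fa in ("a1", "a2"):
            for fb in ("b1", "b2"):
                for _ in range(n):
                    y = (effect_a if fa == "a2" else 0.0) + noise * rng.normal()
                    rows.append({"fa": fa, "fb": fb, "y": y})
        return pd.DataFrame(rows)

    def test_constant_response_gives_zero_f(self, rng):
        df = self.make_2x2(rng, noise=0.0)
        res = hs.factorial_anova(df, "y", ["fa", "fb"])
        assert (res.table.F == 0.0).all() and (res.table.p == 1.0).all()

    def test_pure_shift_hits_f_cap(self, rng):
        df = self.make_2x2(rng, effect_a=5.0, noise=0.0)
        res = hs.factorial_anova(df, "y", ["fa", "fb"])
        # residual SS is at numerical zero: the shifted factor's F explodes
        # (finite, possibly at the cap) while the null terms stay small
        assert res.term("fa").F > 1e10
        assert res.term("fa").p < 1e-10
        assert np.isfinite(res.table.F).all()
        assert res.term("fb").F < 1e3

    def test_matches_hand_sums_of_squares(self, rng):
        df = self.make_2x2(rng, effect_a=1.0, noise=0.5, n=3)
        res = hs.factorial_anova(df, "y", ["fa", "fb"])
        oracle = balanced_twoway_oracle(df, "y")
        assert res.term("fa").F == pytest.approx(oracle["fa"], rel=1e-9)
        assert res.term("fb").F == pytest.approx(oracle["fb"], rel=1e-9)
        assert res.term("fa:fb").F == pytest.approx(oracle["fa:fb"], rel=1e-9)

    def test_empty_cell_named_in_error(self, rng):
        df = self.make_2x2(rng)
        df = df[~((df.fa == "a2") & (df.fb == "b2"))]
        with pytest.raises(ValueError, match=r"fa=a2, fb=b2"):
            hs.factorial_anova(df, "y", ["fa", "fb"])

    def test_interaction_selection(self, rng):
        df = self.make_2x2(rng, noise=1.0)
        res = hs.factorial_anova(df, "y", ["fa", "fb"], interactions="none")
        assert list(res.table.term) == ["fa", "fb"]

    def test_single_level_factor_rejected(self, rng):
        df = self.make_2x2(rng)
        df["fc"] = "only"
        with pytest.raises(ValueError, match="2 levels"):
            hs.factorial_anova(df, "y", ["fa", "fc"])


class TestTukey:
    def test_identical_groups_share_letter(self):
        res = hs.tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p("a", "b") == pytest.approx(1.0)
        assert res.letters["a"] == res.letters["b"]

    def test_outlier_gets_own_letter(self, rng):
        eps = rng.normal(0, 1e-6, (3, 5))
        res = hs.tukey_hsd({"a": eps[0], "b": eps[1], "c": 50.0 + eps[2]})
        assert res.letters["a"] == res.letters["b"] != res.letters["c"]

    def test_matches_scipy_reference(self, rng):
        groups = {k: rng.normal(loc, 1.0, 12) for k, loc in [("a", 0), ("b", 0.8), ("c", 2.0)]}
        from scipy.stats import tukey_hsd as scipy_tukey

        ours = hs.tukey_hsd(groups)
        ref = scipy_tukey(*groups.values())
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")), ((1, "b"), (2, "c"))]:
            assert ours.p(a, b) == pytest.approx(ref.pvalue[i, j], abs=1e-9)


class TestGamesHowell:
    def test_matches_pingouin_on_raw_samples(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = {
            "a": rng.normal(0.0, 1.0, 15),
            "b": rng.normal(1.0, 2.0, 20),
            "c": rng.normal(2.0, 0.5, 12),
        }
        ours = hs.games_howell(data)
        long = pd.concat(
            [pd.DataFrame({"g": k, "y": v}) for k, v in data.items()], ignore_index=True
        )
        ref = pingouin.pairwise_gameshowell(data=long, dv="y", between="g")
        for row in ref.itertuples():
            assert ours.p(row.A, row.B) == pytest.approx(row.pval, abs=1e-6)

    def test_summary_and_raw_inputs_agree(self, rng):
        raw = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 2, 25)}
        summ = {k: (v.mean(), v.std(ddof=1), v.size) for k, v in raw.items()}
        assert hs.games_howell(raw).p("a", "b") == pytest.approx(
            hs.games_howell(summ).p("a", "b"), rel=1e-12
        )

    def test_reduces_to_tukey_for_two_equal_variance_groups(self, rng):
        base = rng.normal(0, 1, 20)
        groups = {"a": base, "b": base + 0.7}  # identical variances and n
        gh = hs.games_howell(groups)
        tk = hs.tukey_hsd(groups)
        assert gh.p("a", "b") == pytest.approx(tk.p("a", "b"), abs=1e-6)

    def test_identical_summaries_give_p_one(self):
        res = hs.games_howell({"a": (5.0, 1.0, 10), "b": (5.0, 1.0, 10)})
        assert res.p("a", "b") == 1.0
        assert res.table.statistic.iloc[0] == 0.0

    def test_zero_se_unequal_means_warns(self):
        with pytest.warns(UserWarning, match="zero pooled SE"):
            res = hs.games_howell({"a": (1.0, 0.0, 10), "b": (2.0, 0.0, 10)})
        assert res.p("a", "b") == 0.0


class TestCompactLetters:
    def test_all_significant_all_distinct(self):
        p = {("A", "B"): 0.001, ("A", "C"): 0.001, ("B", "C"): 0.001}
        letters = hs.compact_letters(p)
        assert len({letters["A"], letters["B"], letters["C"]}) == 3

    def test_none_significant_one_letter(self):
        p = {("A", "B"): 0.5, ("A", "C"): 0.9, ("B", "C"): 0.2}
        letters = hs.compact_letters(p)
        assert letters["A"] == letters["B"] == letters["C"] == "a"

    def test_chain_structure(self):
        # A~B, B~C, A!~C: minimal display is {a, ab, b}
        p = {("A", "B"): 0.3, ("B", "C"): 0.3, ("A", "C"): 0.001}
        letters = hs.compact_letters(p, levels=["A", "B", "C"])
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])
        assert len(set("".join(letters.values()))) == 2

    def test_order_invariant_partition(self):
        p = {("A", "B"): 0.3, ("B", "C"): 0.3, ("A", "C"): 0.001}
        base = hs.compact_letters(p, levels=["A", "B", "C"])
        relabeled = hs.compact_letters(
            {tuple("XYZ"["ABC".index(c)] for c in pair): v for pair, v in p.items()},
            levels=["X", "Y", "Z"],
        )
        partition = lambda L, order: {k: frozenset(v) for k, v in L.items()}
        for orig, new in zip("ABC", "XYZ"):
            same_orig = [o for o in "ABC" if set(base[o]) & set(base[orig])]
            same_new = [n for n in "XYZ" if set(relabeled[n]) & set(relabeled[new])]
            assert ["XYZ"["ABC".index(o)] for o in same_orig] == same_new

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            hs.compact_letters({("A", "B"): 0.5}, levels=["A", "B", "C"])


class TestCorrelation:
    def test_self_and_exact_negative(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        for method in ("pearson", "spearman"):
            r, p = hs.correlation_matrix(df, ["x", "y"], method)
            assert r.loc["x", "x"] == 1.0
            assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_monotone_nonlinear_case(self):
        x = np.arange(1.0, 21.0)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        r_s, _ = hs.correlation_matrix(df, ["x", "y"], "spearman")
        r_p, _ = hs.correlation_matrix(df, ["x", "y"], "pearson")
        assert r_s.loc["x", "y"] == pytest.approx(1.0)
        assert r_p.loc["x", "y"] < 1.0

    def test_constant_feature_warns_nan(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": np.ones(5)})
        with pytest.warns(UserWarning, match="constant feature"):
            r, p = hs.correlation_matrix(df, ["x", "c"], "pearson")
        assert np.isnan(r.loc["x", "c"])

    def test_too_few_rows_fails(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            hs.correlation_matrix(df, ["x", "y"], "pearson")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_spearman_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        df1 = pd.DataFrame({"x": x, "y": y})
        df2 = pd.DataFrame({"x": np.exp(x), "y": y**3})
        r1, _ = hs.correlation_matrix(df1, ["x", "y"], "spearman")
        r2, _ = hs.correlation_matrix(df2, ["x", "y"], "spearman")
        assert r1.loc["x", "y"] == pytest.approx(r2.loc["x", "y"], abs=1e-12)
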