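import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycodiv import anova_three_way, f_statistic, p_value
from mycodiv.anova import significance_stars

from conftest import make_balanced


def brute_force_decomposition(df, response="response"):
    """Oracle: exhaustive mean subtraction over explicit nested loops."""
    factors = ("season", "site", "tissue")
    y = df[response].to_numpy(float)
    grand = y.mean()
    levels = {f: sorted(df[f].unique()) for f in factors}
    ss = {}
    mean = lambda mask: df.loc[mask, response].mean()
    # main effects
    for f in factors:
        others = np.prod([len(levels[g]) for g in factors if g != f])
        r = len(df) / (len(levels[f]) * others)
        ss[f] = others * r * sum((mean(df[f] == lv) - grand) ** 2 for lv in levels[f])
    # two-way
    for f, g in itertools.combinations(factors, 2):
        (h,) = [x for x in factors if x not in (f, g)]
        r = len(df) / (len(levels[f]) * len(levels[g]) * len(levels[h]))
        acc = 0.0
        for lf in levels[f]:
            for lg in levels[g]:
                cell = mean((df[f] == lf) & (df[g] == lg))
                acc += (cell - mean(df[f] == lf) - mean(df[g] == lg) + grand) ** 2
        ss[f"{f} x {g}"] = len(levels[h]) * r * acc
    # three-way
    r = len(df) / np.prod([len(levels[f]) for f in factors])
    acc = 0.0
    for la in levels["season"]:
        for lb in levels["site"]:
            for lc in levels["tissue"]:
                full = mean((df["season"] == la) & (df["site"] == lb) & (df["tissue"] == lc))
                acc += (
                    full
                    - mean((df["season"] == la) & (df["site"] == lb))
                    - mean((df["season"] == la) & (df["tissue"] == lc))
                    - mean((df["site"] == lb) & (df["tissue"] == lc))
                    + mean(df["season"] == la)
                    + mean(df["site"] == lb)
                    + mean(df["tissue"] == lc)
                    - grand
                ) ** 2
    ss["season x site x tissue"] = r * acc
    ss["total"] = float(np.sum((y - grand) ** 2))
    return ss


class TestStatistics:
    @pytest.mark.parametrize(
        "ms, expected", [(8.614, 3.314), (0.821, 0.316)]
    )
    def test_f_from_printed_mean_squares(self, ms, expected):
        assert round(f_statistic(ms, 2.599), 3) == expected

    def test_f_identity_and_domain(self):
        assert f_statistic(2.599, 2.599) == 1.0
        with pytest.raises(ValueError):
            f_statistic(1.0, 0.0)

    def test_p_value_limits_and_site_row(self):
        assert p_value(0.0, 5, 108) == 1.0
        assert p_value(np.inf, 5, 108) == 0.0
        assert p_value(1.046, 5, 108) == pytest.approx(0.395, abs=5e-4)

    def test_p_value_agrees_with_scipy_f(self):
        for F, d1, d2 in [(0.5, 2, 10), (3.3, 10, 108), (192.8, 2, 108), (1.4, 20, 108)]:
            assert p_value(F, d1, d2) == pytest.approx(stats.f.sf(F, d1, d2), rel=1e-10)

    def test_stars_follow_legend(self):
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.012) == "**"
        assert significance_stars(0.05) == "ns"


class TestAnovaTable:
    def test_df_column_for_study_design(self, rng):
        table = anova_three_way(make_balanced(rng))
        expected = {
            "season": 2, "site": 5, "tissue": 2,
            "season x site": 10, "season x tissue": 4, "site x tissue": 10,
            "season x site x tissue": 20, "error": 108, "total": 161,
        }
        got = dict(zip(table.frame["source"], table.frame["df"]))
        assert got == expected

    def test_constant_response_degenerate(self, rng):
        df = make_balanced(rng, sd=0.0)
        df["response"] = 7.0
        table = anova_three_way(df)
        eff = table.frame[~table.frame["source"].isin(["error", "total"])]
        assert (eff["SS"] == 0).all()
        assert (eff["F"] == 0).all()
        assert (eff["p"] == 1).all()

    def test_noiseless_tissue_effect_isolated(self, rng):
        shift = {"leaf": 4.0, "stem": 0.0, "petiole": -4.0}
        df = make_balanced(rng, sd=0.0, effects={"tissue": shift})
        table = anova_three_way(df)
        ss = dict(zip(table.frame["source"], table.frame["SS"]))
        assert ss["tissue"] > 0
        for src, v in ss.items():
            if src not in ("tissue", "total"):
                assert v == pytest.approx(0.0, abs=1e-12)
        oracle = brute_force_decomposition(df)
        assert ss["tissue"] == pytest.approx(oracle["tissue"], rel=1e-12)

    def test_matches_bruteforce_oracle_on_random_data(self, rng):
        df = make_balanced(rng, seasons=2, sites=3, tissues=3, r=2)
        table = anova_three_way(df)
        ss = dict(zip(table.frame["source"], table.frame["SS"]))
        oracle = brute_force_decomposition(df)
        for src, v in oracle.items():
            assert ss[src] == pytest.approx(v, rel=1e-10, abs=1e-12)

    def test_additivity_random_designs(self, rng):
        for _ in range(25):
            dims = rng.integers(2, 4, size=3)
            df = make_balanced(
                rng, seasons=int(dims[0]), sites=int(dims[1]), tissues=int(dims[2]),
                r=int(rng.integers(2, 4)),
            )
            t = anova_three_way(df).frame.set_index("source")
            comp = t.drop("total")
            assert comp["df"].sum() == t.loc["total", "df"]
            assert comp["SS"].sum() == pytest.approx(t.loc["total", "SS"], rel=1e-9)

    def test_replicate_order_invariance(self, rng):
        df = make_balanced(rng)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            anova_three_way(df).frame, anova_three_way(shuffled).frame
        )

    def test_unbalanced_rejected_naming_cell(self, rng):
        df = make_balanced(rng).drop(index=0)
        with pytest.raises(ValueError, match="unbalanced .*season=winter.*site=1.*tissue=leaf"):
            anova_three_way(df)

    def test_single_replicate_rejected(self, rng):
        df = make_balanced(rng, r=1)
        with pytest.raises(ValueError, match="replicates"):
            anova_three_way(df)

    def test_null_rejection_rate_close_to_alpha(self, rng):
        # quick calibration smoke check; the full 1000-dataset CI check
        # lives with the acceptance suite
        n, hits = 200, 0
        for _ in range(n):
            t = anova_three_way(make_balanced(rng))
            hits += t["tissue"]["p"] < 0.05
        assert 0.01 < hits / n < 0.12
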