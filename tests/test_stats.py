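import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thetalink import ValidationError
from thetalink.stats import (
    bootstrap_slope_ci,
    coherence_performance_regression,
    fractional_change_table,
    oneway_anova_posthoc,
    paired_test,
    rm_anova,
)


# ---------------------------------------------------------------------------
# hand sums-of-squares oracles
# ---------------------------------------------------------------------------


def mixed_anova_oracle(df):
    """Explicit balanced mixed-design sums of squares."""
    subj_means = df.groupby("animal_id")["value"].mean()
    grp_of = df.groupby("animal_id")["group"].first()
    grand = df["value"].mean()
    groups = sorted(df["group"].unique())
    levels = sorted(df["level"].unique())
    G, L = len(groups), len(levels)
    N = subj_means.size
    n_g = {g: (grp_of == g).sum() for g in groups}
    m_g = df.groupby("group")["value"].mean()
    m_l = df.groupby("level")["value"].mean()
    m_gl = df.groupby(["group", "level"])["value"].mean()
    ss_group = L * sum(n_g[g] * (m_g[g] - grand) ** 2 for g in groups)
    ss_subj = L * sum(
        (subj_means[s] - m_g[grp_of[s]]) ** 2 for s in subj_means.index
    )
    ss_level = N * sum((m_l[l] - grand) ** 2 for l in levels)
    ss_inter = sum(
        n_g[g] * (m_gl[(g, l)] - m_g[g] - m_l[l] + grand) ** 2
        for g in groups
        for l in levels
    )
    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_level - ss_inter
    df_g, df_s = G - 1, N - G
    df_l, df_e = L - 1, (N - G) * (L - 1)
    f_group = (ss_group / df_g) / (ss_subj / df_s)
    f_level = (ss_level / df_l) / (ss_err / df_e)
    f_inter = (ss_inter / (df_g * df_l)) / (ss_err / df_e)
    return {
        "group": (f_group, sps.f.sf(f_group, df_g, df_s)),
        "level": (f_level, sps.f.sf(f_level, df_l, df_e)),
        "interaction": (f_inter, sps.f.sf(f_inter, df_g * df_l, df_e)),
    }


def tukey_oracle(values, labels):
    """Studentized-range p-values from pooled error MS (equal n)."""
    k = len(values)
    n = values[0].size
    df_err = sum(v.size for v in values) - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in values) / df_err
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(values[i].mean() - values[j].mean()) / np.sqrt(mse / n)
            out[f"{labels[i]} vs {labels[j]}"] = sps.studentized_range.sf(
                q, k, df_err
            )
    return out


class TestRmAnova:
    def _toy(self):
        rows = []
        data = {
            ("A", "s1"): [3.0, 4.0, 6.0],
            ("A", "s2"): [5.0, 7.0, 8.0],
            ("A", "s3"): [4.0, 5.0, 7.0],
            ("B", "s4"): [2.0, 2.5, 2.0],
            ("B", "s5"): [1.0, 3.0, 2.5],
            ("B", "s6"): [2.5, 2.0, 3.5],
        }
        for (g, s), vals in data.items():
            for lev, v in enumerate(vals):
                rows.append((s, g, f"L{lev}", v))
        return pd.DataFrame(rows, columns=["animal_id", "group", "level", "value"])

    def test_matches_hand_sums_of_squares(self):
        df = self._toy()
        res = rm_anova(df, correction=False).set_index("effect")
        oracle = mixed_anova_oracle(df)
        assert res.loc["group", "F"] == pytest.approx(oracle["group"][0], abs=1e-10)
        assert res.loc["level", "F"] == pytest.approx(oracle["level"][0], abs=1e-10)
        assert res.loc["group x level", "F"] == pytest.approx(
            oracle["interaction"][0], abs=1e-10
        )
        assert res.loc["group", "p"] == pytest.approx(oracle["group"][1], abs=1e-10)
        assert res.loc["group x level", "p"] == pytest.approx(
            oracle["interaction"][1], abs=1e-10
        )

    def test_constant_data_degenerate(self):
        rows = [
            (s, g, l, 1.0)
            for g, ss in (("A", ["s1", "s2"]), ("B", ["s3", "s4"]))
            for s in ss
            for l in ("L0", "L1")
        ]
        df = pd.DataFrame(rows, columns=["animal_id", "group", "level", "value"])
        res = rm_anova(df)
        assert res["degenerate"].any()

    def test_missing_cell_rejected(self):
        df = self._toy().iloc[:-1]
        with pytest.raises(ValidationError):
            rm_anova(df)


class TestOnewayPosthoc:
    def _df(self):
        rng = np.random.default_rng(7)
        vals = {
            "a": rng.normal(0.0, 1.0, 6),
            "b": rng.normal(2.5, 1.0, 6),
            "c": rng.normal(0.3, 1.0, 6),
        }
        return pd.DataFrame(
            {
                "group": np.repeat(list(vals), 6),
                "value": np.concatenate(list(vals.values())),
            }
        ), vals

    def test_tukey_matches_studentized_range_oracle(self):
        df, vals = self._df()
        res = oneway_anova_posthoc(df, method="tukey")
        oracle = tukey_oracle(list(vals.values()), list(vals))
        assert res.posthoc is not None
        for row in res.posthoc.itertuples(index=False):
            assert row.p_adjusted == pytest.approx(
                oracle[row.comparison], abs=1e-6
            )

    def test_lsd_not_more_conservative_than_tukey(self):
        df, _ = self._df()
        tukey = oneway_anova_posthoc(df, method="tukey").posthoc
        lsd = oneway_anova_posthoc(df, method="lsd").posthoc
        bonf = oneway_anova_posthoc(df, method="bonferroni").posthoc
        for t, l, b in zip(
            tukey["p_adjusted"], lsd["p_adjusted"], bonf["p_adjusted"]
        ):
            assert l <= t + 1e-12
            assert l <= b + 1e-12

    def test_identical_groups_not_significant(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 4 + ["b"] * 4,
                "value": [1.0, 2.0, 1.5, 1.8] * 2,
            }
        )
        res = oneway_anova_posthoc(df, method="tukey")
        assert res.table["p"].iloc[0] > 0.9
        assert res.posthoc is None  # gatekeeping: no post-hoc without omnibus
        forced = oneway_anova_posthoc(df, method="tukey", gatekeep=False)
        assert (forced.posthoc["p_adjusted"] > 0.9).all()

    def test_omnibus_matches_scipy(self):
        df, vals = self._df()
        res = oneway_anova_posthoc(df)
        f, p = sps.f_oneway(*vals.values())
        assert res.table["F"].iloc[0] == pytest.approx(f, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(p, abs=1e-10)


class TestPairedTest:
    def test_identical_vectors(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.table["t"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0
        assert res.degenerate

    def test_hand_computed_t(self):
        a = np.array([3.1, 2.8, 3.6, 3.3, 3.0])
        b = np.array([2.9, 2.6, 3.1, 3.4, 2.7])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_hand = 2 * sps.t.sf(abs(t_hand), d.size - 1)
        res = paired_test(a, b)
        assert res.table["t"].iloc[0] == pytest.approx(t_hand, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(p_hand, abs=1e-10)

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.01, 8)
        noise = rng.normal(0, 0.01, 8)
        ps = [
            paired_test(base + delta + noise, base).table["p"].iloc[0]
            for delta in (0.002, 0.01, 0.05)
        ]
        assert ps[0] > ps[1] > ps[2]


class TestRegression:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(0)
        coh = rng.uniform(0, 1, 24)
        grp = np.repeat(["WT", "KO", "RE"], 8)
        perf = 0.4 * coh + 0.2
        res = coherence_performance_regression(perf, coh, grp)
        assert res.slope == pytest.approx(0.4, abs=1e-10)
        assert res.r == pytest.approx(1.0, abs=1e-6)

    def test_wt_scope_simple_pearson(self):
        rng = np.random.default_rng(2)
        coh = rng.uniform(0, 1, 24)
        grp = np.repeat(["WT", "KO", "RE"], 8)
        perf = 0.5 * coh + rng.normal(0, 0.05, 24)
        res = coherence_performance_regression(perf, coh, grp, scope="wt_only")
        r, p = sps.pearsonr(coh[:8], perf[:8])
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.n == 8

    def test_independence_null_r_p_small(self):
        rng = np.random.default_rng(3)
        grp = np.repeat(["WT", "KO", "RE"], 8)
        rs, ps = [], []
        for _ in range(60):
            coh = rng.uniform(0, 1, 24)
            perf = rng.normal(0.7, 0.1, 24)
            res = coherence_performance_regression(perf, coh, grp)
            rs.append(res.r)
            ps.append(res.p)
        assert abs(np.mean(rs)) < 0.08
        assert 0.3 < np.mean(ps) < 0.7  # roughly uniform p under the null

    def test_single_animal_group_rejected(self):
        grp = np.array(["WT"] * 10 + ["KO"])
        with pytest.raises(ValidationError):
            coherence_performance_regression(
                np.arange(11.0), np.arange(11.0) * 0.1, grp
            )

    def test_bootstrap_ci_covers_true_slope(self):
        rng = np.random.default_rng(5)
        grp = np.repeat(["WT", "KO", "RE"], 8)
        offs = {"WT": 0.1, "KO": -0.1, "RE": 0.0}
        coh = rng.uniform(0, 1, 24)
        perf = 0.5 * coh + np.array([offs[g] for g in grp]) + rng.normal(0, 0.05, 24)
        lo, hi = bootstrap_slope_ci(perf, coh, grp, n_boot=800, seed=1)
        assert lo < 0.5 < hi


class TestFractionalChangeTable:
    def test_builder(self):
        df = pd.DataFrame(
            {
                "animal_id": ["m1", "m2", "m3"],
                "group": ["WT", "WT", "KO"],
                "performance": [0.9, 0.8, np.nan],
                "sample": [0.5, 0.4, 0.5],
                "choice": [0.6, np.nan, 0.55],
            }
        )
        out = fractional_change_table(df)
        assert len(out) == 1  # only m1 has both phases and performance
        assert out["frac_change"].iloc[0] == pytest.approx(0.2)
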