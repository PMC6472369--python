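"""Group-level inference for virtual (or real) cohorts.

Implements the statistical framework the derived metrics feed into:
mixed-design (group x time/phase) repeated-measures ANOVA, one-way ANOVA
with Tukey-HSD / LSD / Bonferroni post-hocs gated on the omnibus test,
paired t tests, and ordinary-least-squares regression of working-memory
performance on coherence metrics with partial correlations that control for
group identity.

Standard fits are delegated to pingouin / statsmodels / scipy; the tests
validate them against explicit sums-of-squares oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dataio import ValidationError
from .coherence import fractional_change

logger = logging.getLogger("thetalink")

__all__ = [
    "TestResult",
    "RegressionResult",
    "rm_anova",
    "oneway_anova_posthoc",
    "paired_test",
    "coherence_performance_regression",
    "bootstrap_slope_ci",
    "fractional_change_table",
]


@dataclass
class TestResult:
    """An omnibus test plus (optionally gated) pairwise post-hoc table."""

    table: pd.DataFrame  # effect, statistic, df..., p
    posthoc: pd.DataFrame | None = None
    method: str = ""
    alpha: float = 0.05
    degenerate: bool = False


@dataclass
class RegressionResult:
    slope: float
    r: float  # partial r_p (all-groups scope) or simple Pearson r (WT scope)
    p: float
    n: int
    scope: str
    intercept: float = float("nan")


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------


def _check_balanced(
    df: pd.DataFrame, dv: str, within: str, subject: str, between: str
) -> None:
    pivot = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="size")
    if pivot.isna().any().any() or (pivot != 1).any().any():
        missing = pivot.stack(future_stack=True)
        bad = missing[missing != 1]
        logger.error("missing/duplicated cells (subject, level): %s",
                     list(bad.index[:10]))
        raise ValidationError(
            "mixed ANOVA requires exactly one value per subject x level; "
            "exclude incomplete animals explicitly (listwise) before calling"
        )
    per_group = df.groupby(between)[subject].nunique()
    if (per_group < 2).any():
        raise ValidationError("need at least 2 animals per group")


def rm_anova(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "animal_id",
    between: str = "group",
    correction: str | bool = "auto",
) -> pd.DataFrame:
    """Mixed-design ANOVA: between-group, within-subject and interaction.

    ``correction`` controls sphericity handling for the within/interaction
    effects: False = never correct, True = always use Greenhouse-Geisser,
    "auto" = use the corrected p only when Mauchly's test rejects sphericity.
    Returns a frame (effect, F, df1, df2, p, p_unc, eps, degenerate).
    """
    _check_balanced(df, dv, within, subject, between)
    aov = pg.mixed_anova(
        data=df,
        dv=dv,
        within=within,
        subject=subject,
        between=between,
        correction=(correction is not False),
    )
    spher_ok = True
    if "sphericity" in aov.columns:
        s = aov["sphericity"].dropna()
        spher_ok = bool(s.iloc[0]) if len(s) else True
    use_gg = correction is True or (correction == "auto" and not spher_ok)
    eps_all = aov["eps"].dropna()
    eps = float(eps_all.iloc[0]) if len(eps_all) else np.nan
    rows = []
    for _, r in aov.iterrows():
        p_unc = float(r.get("p_unc", np.nan))
        p_gg = float(r.get("p_GG_corr", np.nan))
        f_val = float(r.get("F", np.nan))  # absent on zero-variance input
        source = r["Source"]
        effect = source if source != "Interaction" else f"{between} x {within}"
        is_within = source in (within, "Interaction")
        if use_gg and source == "Interaction" and np.isfinite(eps) and np.isfinite(
            f_val
        ):
            # pingouin reports the corrected p only for the within effect;
            # apply the same epsilon to the interaction's dfs
            p_gg = float(sps.f.sf(f_val, eps * r["DF1"], eps * r["DF2"]))
        p = p_gg if (use_gg and is_within and np.isfinite(p_gg)) else p_unc
        rows.append(
            {
                "effect": effect,
                "F": f_val,
                "df1": int(r["DF1"]),
                "df2": int(r["DF2"]),
                "p": p,
                "p_unc": p_unc,
                "eps": float(r.get("eps", np.nan)),
                "degenerate": not np.isfinite(f_val),
            }
        )
    return pd.DataFrame(rows)


def _omnibus_f(values: list[np.ndarray]) -> tuple[float, int, int, float, float]:
    """One-way ANOVA F, dfs, p and pooled error mean square."""
    k = len(values)
    ns = np.array([v.size for v in values])
    grand = np.concatenate(values).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df1, df2 = k - 1, int(ns.sum()) - k
    mse = ss_within / df2
    if mse == 0:
        return np.nan, df1, df2, np.nan, 0.0
    f = (ss_between / df1) / mse
    return f, df1, df2, float(sps.f.sf(f, df1, df2)), mse


def oneway_anova_posthoc(
    df: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    method: str = "tukey",
    alpha: float = 0.05,
    gatekeep: bool = True,
) -> TestResult:
    """One-way ANOVA with a named pairwise adjustment.

    Pairwise comparisons are only computed when the omnibus test is
    significant at ``alpha`` (gatekeeping, the convention the derived
    metrics' reporting follows); pass gatekeep=False to force them.
    """
    groups = [g for _, g in df.groupby(between)[dv]]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 animals each")
    values = [g.to_numpy(dtype=float) for g in groups]
    labels = [name for name, _ in df.groupby(between)[dv]]
    f, df1, df2, p, mse = _omnibus_f(values)
    table = pd.DataFrame(
        [{"effect": between, "F": f, "df1": df1, "df2": df2, "p": p}]
    )
    degenerate = not np.isfinite(f)
    posthoc = None
    if not degenerate and (p < alpha or not gatekeep):
        posthoc = _pairwise(values, labels, method, mse, df2)
    return TestResult(table, posthoc, method, alpha, degenerate)


def _pairwise(values, labels, method, mse, df_err) -> pd.DataFrame:
    method = method.lower()
    rows = []
    m = len(values) * (len(values) - 1) // 2
    if method == "tukey":
        data = np.concatenate(values)
        grp = np.concatenate([[lab] * len(v) for lab, v in zip(labels, values)])
        res = pairwise_tukeyhsd(data, grp)
        uniq = list(res.groupsunique)
        pairs = [
            (uniq[i], uniq[j])
            for i in range(len(uniq))
            for j in range(i + 1, len(uniq))
        ]
        for (g1, g2), p in zip(pairs, np.atleast_1d(res.pvalues)):
            rows.append((f"{g1} vs {g2}", float(p), "tukey"))
    elif method in ("lsd", "bonferroni"):
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                vi, vj = values[i], values[j]
                se = np.sqrt(mse * (1 / vi.size + 1 / vj.size))
                t = (vi.mean() - vj.mean()) / se
                p = 2 * sps.t.sf(abs(t), df_err)
                if method == "bonferroni":
                    p = min(1.0, p * m)
                rows.append((f"{labels[i]} vs {labels[j]}", float(p), method))
    else:
        raise ValidationError(f"unknown post-hoc method {method!r}")
    return pd.DataFrame(rows, columns=["comparison", "p_adjusted", "method"])


def paired_test(values_a, values_b) -> TestResult:
    """Two-sided paired t test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired test needs equal-length vectors, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
        degenerate = True
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        degenerate = False
    table = pd.DataFrame([{"effect": "paired", "t": t, "df": n - 1, "p": p}])
    return TestResult(table, None, "paired_t", degenerate=degenerate)


# ---------------------------------------------------------------------------
# coherence -> performance regression
# ---------------------------------------------------------------------------


def _design(coherence: np.ndarray, groups: np.ndarray) -> np.ndarray:
    dummies = pd.get_dummies(pd.Series(groups), drop_first=True).to_numpy(float)
    return np.column_stack([np.ones_like(coherence), coherence, dummies])


def coherence_performance_regression(
    performance,
    coherence,
    groups,
    scope: str = "all_groups",
    wt_label: str = "WT",
) -> RegressionResult:
    """OLS of performance on a coherence metric.

    all_groups: multiple regression with group-identity dummies as
    covariates; reports the coherence slope, its p-value and the partial
    correlation r_p of coherence with performance controlling for group.
    wt_only: simple regression within the wildtype subgroup, reporting the
    plain Pearson r.
    """
    perf = np.asarray(performance, dtype=float)
    coh = np.asarray(coherence, dtype=float)
    grp = np.asarray(groups)
    if scope == "wt_only":
        m = grp == wt_label
        perf, coh = perf[m], coh[m]
        if perf.size < 4:
            raise ValidationError("need >= 4 animals in scope")
        slope, intercept = np.polyfit(coh, perf, 1)
        r, p = sps.pearsonr(coh, perf)
        return RegressionResult(
            float(slope), float(r), float(p), perf.size, scope, float(intercept)
        )
    if scope != "all_groups":
        raise ValidationError("scope must be 'all_groups' or 'wt_only'")
    if perf.size < 4:
        raise ValidationError("need >= 4 animals in scope")
    counts = pd.Series(grp).value_counts()
    if (counts < 2).any():
        raise ValidationError(
            f"groups with a single animal make the dummies collinear: "
            f"{list(counts[counts < 2].index)}"
        )
    X = _design(coh, grp)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear predictors in regression design")
    import statsmodels.api as sm

    fit = sm.OLS(perf, X).fit()
    slope = float(fit.params[1])
    t = float(fit.tvalues[1])
    dfres = int(fit.df_resid)
    r_p = t / np.sqrt(t**2 + dfres)  # exact partial correlation from the t stat
    return RegressionResult(
        slope, float(r_p), float(fit.pvalues[1]), perf.size, scope,
        float(fit.params[0]),
    )


def bootstrap_slope_ci(
    performance,
    coherence,
    groups,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bootstrap CI for the all-groups coherence slope.

    Animals are resampled with replacement within group (stratified) so the
    group dummies stay full rank in every replicate.  The interval is the
    normal-approximation bootstrap interval with a Student-t critical value
    at the residual degrees of freedom — better calibrated than percentile
    intervals at cohort-sized n, where the slope's sampling distribution is
    t-shaped and within-group resampling slightly shrinks the bootstrap SD.
    """
    perf = np.asarray(performance, dtype=float)
    coh = np.asarray(coherence, dtype=float)
    grp = np.asarray(groups)
    rng = np.random.default_rng(seed)
    idx_by_group = [np.flatnonzero(grp == g) for g in np.unique(grp)]
    X_full = _design(coh, grp)
    beta_full, *_ = np.linalg.lstsq(X_full, perf, rcond=None)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_group]
        )
        X = _design(coh[idx], grp[idx])
        beta, *_ = np.linalg.lstsq(X, perf[idx], rcond=None)
        slopes[b] = beta[1]
    df_resid = perf.size - X_full.shape[1]
    q = sps.t.ppf(1 - (1 - level) / 2, df_resid)
    half = q * slopes.std(ddof=1)
    return (float(beta_full[1] - half), float(beta_full[1] + half))


def fractional_change_table(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Assemble the regression input from per-animal phase coherences.

    Expects columns (animal_id, group, performance, sample, choice); adds a
    ``frac_change`` predictor ((choice - sample)/sample).  Animals missing
    either phase (NaN) are dropped with a log entry.
    """
    needed = {"animal_id", "group", "performance", "sample", "choice"}
    missing = needed - set(per_animal.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    ok = per_animal.dropna(subset=["sample", "choice", "performance"]).copy()
    dropped = set(per_animal["animal_id"]) - set(ok["animal_id"])
    if dropped:
        logger.info("dropped animals with missing phases: %s", sorted(dropped))
    ok["frac_change"] = [
        fractional_change(c, s) for c, s in zip(ok["choice"], ok["sample"])
    ]
    return ok.reset_index(drop=True)
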