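"""Statistical layer: t tests, two-way ANOVA, and post hoc procedures.

Conventions follow common practice in the experimental literature this
pipeline serves: two-tailed Student (pooled-variance) t tests by default —
the pooled convention is what reproduces printed degrees of freedom such
as df = 20 for 11 vs 11 animals and df = 18 for 11 vs 9 — with Welch as an
option; two-way ANOVA with interaction (Type III sums of squares with
sum-to-zero contrasts when the design is unbalanced); and Tukey HSD
(studentized range) or Bonferroni multiple-comparison corrections.

:func:`t_from_summary` reconstructs a t statistic from printed
mean ± SEM / n summaries, which is how worked examples from published group
tables are checked without raw data.

Degenerate zero-variance inputs return flagged, defined results (t = 0,
p = 1 for identical samples; p → 0 for a pure constant shift) rather than
NaN, so pipelines never silently propagate invalid values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TestResult",
    "t_unpaired",
    "t_paired",
    "t_from_summary",
    "anova2",
    "posthoc",
]


@dataclass
class SummaryStats:
    """A printed group summary: mean ± SEM with group size."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class TestResult:
    """A test statistic with df and two-tailed p, per effect.

    For t tests there is a single effect (``effects=("t",)``); a two-way
    ANOVA reports exactly three: the two main effects and the interaction.
    """

    kind: str  # t_unpaired | t_paired | anova2
    effects: tuple
    statistic: dict
    df: dict
    p: dict
    degenerate: bool = False
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eff in self.effects:
            if not (0.0 <= self.p[eff] <= 1.0):
                raise ValueError(f"p for {eff!r} outside [0, 1]")


def _t_result(kind, t, df, degenerate=False, notes=None) -> TestResult:
    p = 1.0 if degenerate and t == 0 else float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(kind=kind, effects=("t",), statistic={"t": float(t)},
                      df={"t": float(df)}, p={"t": p}, degenerate=degenerate,
                      notes=notes or {})


def t_unpaired(x, y, pooled: bool = True) -> TestResult:
    """Two-tailed unpaired t test (Student by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        df = len(x) + len(y) - 2
        if x.mean() == y.mean():
            return _t_result("t_unpaired", 0.0, df, degenerate=True,
                            notes={"reason": "zero variance, equal means"})
        return _t_result("t_unpaired", np.inf, df, degenerate=True,
                        notes={"reason": "zero variance, unequal means"})
    t, p = sps.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else _welch_df(x, y)
    res = _t_result("t_unpaired", t, df)
    res.p["t"] = float(p)
    return res


def _welch_df(x, y) -> float:
    vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
    return (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))


def t_paired(x, y) -> TestResult:
    """Two-tailed paired t test: one-sample t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    df = len(d) - 1
    if np.var(d, ddof=1) == 0:
        if d.mean() == 0:
            return _t_result("t_paired", 0.0, df, degenerate=True,
                            notes={"reason": "identical pairs"})
        return _t_result("t_paired", np.inf, df, degenerate=True,
                        notes={"reason": "constant nonzero shift"})
    t, p = sps.ttest_rel(x, y)
    res = _t_result("t_paired", t, df)
    res.p["t"] = float(p)
    return res


def t_from_summary(a: SummaryStats, b: SummaryStats, pooled: bool = True) -> TestResult:
    """Student t reconstructed from two mean ± SEM / n summaries.

    SDs are recovered as sem·√n; with ``pooled`` (default) the classic
    pooled-variance t with df = n_a + n_b − 2 is applied, matching how
    printed group comparisons are computed from printed summaries.
    """
    sa, sb = a.sd, b.sd
    if pooled:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * sa ** 2 + (b.n - 1) * sb ** 2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = sa ** 2 / a.n, sb ** 2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    if se == 0:
        if a.mean == b.mean:
            return _t_result("t_unpaired", 0.0, df, degenerate=True)
        return _t_result("t_unpaired", np.inf, df, degenerate=True)
    t = (a.mean - b.mean) / se
    return _t_result("t_unpaired", t, df,
                     notes={"groups": (a.label, b.label), "from_summary": True})


def _is_balanced(df: pd.DataFrame, a: str, b: str) -> bool:
    counts = df.groupby([a, b], observed=True).size()
    full = df[a].nunique() * df[b].nunique()
    return len(counts) == full and counts.nunique() == 1


def anova2(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factorA",
    factor_b: str = "factorB",
) -> TestResult:
    """Two-way ANOVA with interaction on a tidy table.

    Balanced designs use the standard sequential sums of squares (all
    types coincide); unbalanced designs use Type III sums of squares with
    sum-to-zero contrasts. An empty cell in the design is an error naming
    the missing combination.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].copy()
    for col in (factor_a, factor_b):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    levels_a = df[factor_a].unique()
    levels_b = df[factor_b].unique()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty design cell: ({factor_a}={la!r}, {factor_b}={lb!r})")
    df = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    balanced = _is_balanced(df, "_a", "_b")
    if balanced:
        model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        ss_type = "II (== I/III, balanced)"
    else:
        model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=3).drop(index="Intercept")
        ss_type = "III (sum-to-zero contrasts)"
    rows = [r for r in tab.index if r != "Residual"]
    name_map = dict(zip(rows, (factor_a, factor_b, "interaction")))
    resid_df = float(tab.loc["Residual", "df"])
    zero_between = all(
        np.isclose(tab.loc[r, "sum_sq"], 0.0, atol=1e-12) for r in rows
    )
    statistic, dfs, ps = {}, {}, {}
    for r in rows:
        eff = name_map[r]
        F = float(tab.loc[r, "F"])
        p = float(tab.loc[r, "PR(>F)"])
        if zero_between or not np.isfinite(F):
            F, p = 0.0, 1.0
        statistic[eff] = F
        dfs[eff] = (float(tab.loc[r, "df"]), resid_df)
        ps[eff] = p
    return TestResult(kind="anova2", effects=(factor_a, factor_b, "interaction"),
                      statistic=statistic, df=dfs, p=ps,
                      notes={"ss_type": ss_type, "residual_df": resid_df,
                             "balanced": balanced})


def posthoc(
    table: pd.DataFrame,
    method: str = "tukey",
    value: str = "value",
    group: str = "group",
    comparisons: list | None = None,
) -> pd.DataFrame:
    """Pairwise post hoc comparisons after an ANOVA.

    ``method="tukey"`` applies Tukey's HSD on group means (studentized
    range distribution, pooled within-group variance); ``method=
    "bonferroni"`` multiplies each pairwise Student-t p-value by the
    number of comparisons (capped at 1). ``comparisons`` restricts the
    output to the listed (group1, group2) pairs; for Bonferroni the
    correction factor is the number of comparisons actually made.
    Returns a DataFrame with columns group1, group2, mean_diff, p_adj.
    """
    if method not in ("tukey", "bonferroni"):
        raise ValueError(f"unknown post hoc method {method!r}")
    groups = {g: np.asarray(sub[value], dtype=float) for g, sub in table.groupby(group, observed=True)}
    names = sorted(groups)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    k = len(groups)
    N = sum(len(v) for v in groups.values())
    df_within = N - k
    ms_within = sum(((len(v) - 1) * np.var(v, ddof=1)) for v in groups.values()) / df_within
    rows = []
    for g1, g2 in comparisons:
        x, y = groups[g1], groups[g2]
        diff = x.mean() - y.mean()
        if method == "tukey":
            se = np.sqrt(ms_within / 2.0 * (1.0 / len(x) + 1.0 / len(y)))
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        else:
            res = t_unpaired(x, y)
            p_adj = min(1.0, len(comparisons) * res.p["t"])
        rows.append({"group1": g1, "group2": g2, "mean_diff": float(diff), "p_adj": p_adj})
    return pd.DataFrame(rows)
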