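"""Caption-level statistics.

Welch's heteroscedastic ANOVA, the Brown-Forsythe test (ANOVA on absolute
deviations from group medians), two-way ANOVA with type II sums of squares
for unbalanced layouts, multiple Welch t-tests with the two-stage linear
step-up false-discovery procedure (Benjamini-Krieger-Yekutieli) at
discovery threshold Q, and the small design-arithmetic summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "welch_anova",
    "brown_forsythe",
    "two_way_anova",
    "multiple_t_fdr",
    "summarize_design",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float
    groups: list[str] = field(default_factory=list)
    discovery: bool | None = None

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": "/".join(f"{d:g}" for d in self.df),
            "pvalue": self.pvalue,
            "groups": ";".join(self.groups),
            "discovery": self.discovery,
        }


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    return out


def welch_anova(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> StatResult:
    """Welch's F test for equal means under unequal variances.

    Uses the precision weights w_i = n_i / s_i^2 and the Welch-Satterthwaite
    denominator degrees of freedom; with two groups it reduces to the
    squared Welch t statistic.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.all(v == 0):
        raise ValueError("all groups have zero variance")
    w = n / v
    w_sum = w.sum()
    grand = (w * m).sum() / w_sum
    between = (w * (m - grand) ** 2).sum() / (k - 1)
    lam = (3.0 / (k * k - 1.0)) * ((1.0 - w / w_sum) ** 2 / (n - 1.0)).sum()
    f_stat = between / (1.0 + 2.0 * (k - 2.0) * lam / 3.0)
    df1 = k - 1.0
    df2 = 1.0 / lam
    p = float(sps.f.sf(f_stat, df1, df2))
    return StatResult("welch_anova", float(f_stat), (df1, df2), p,
                      groups=list(labels or map(str, range(k))))


def brown_forsythe(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> StatResult:
    """Brown-Forsythe test: one-way ANOVA on |x - group median|.

    Degenerate (all-constant) inputs are reported with NaN statistic and a
    p-value of 1 rather than raising, so batch summaries keep running.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    if all(g.var(ddof=1) == 0 for g in gs):
        return StatResult("brown_forsythe", float("nan"), (k - 1.0, float(n_total - k)), 1.0,
                          groups=list(labels or map(str, range(k))))
    stat, p = sps.levene(*gs, center="median")
    return StatResult("brown_forsythe", float(stat), (k - 1.0, float(n_total - k)), float(p),
                      groups=list(labels or map(str, range(k))))


def two_way_anova(values: Sequence[float], factor_a: Sequence, factor_b: Sequence) -> list[StatResult]:
    """Two-way ANOVA (type II sums of squares) for A, B and A x B.

    Type II SS keep main-effect tests well defined in the unbalanced
    layouts the experiments produce (3-4 wells per condition).  When every
    cell has a single observation the interaction is dropped (no residual
    df otherwise) and only main effects are returned.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=np.float64),
        "a": pd.Categorical(factor_a),
        "b": pd.Categorical(factor_b),
    })
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cell_n = df.groupby(["a", "b"], observed=True).size()
    formula = "value ~ C(a) * C(b)" if (cell_n > 1).any() else "value ~ C(a) + C(b)"
    fit = ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    name_map = {"C(a)": "factor_a", "C(b)": "factor_b", "C(a):C(b)": "interaction"}
    results = []
    resid_df = float(table.loc["Residual", "df"])
    for term, name in name_map.items():
        if term not in table.index:
            continue
        results.append(StatResult(
            f"two_way_anova:{name}",
            float(table.loc[term, "F"]),
            (float(table.loc[term, "df"]), resid_df),
            float(table.loc[term, "PR(>F)"]),
        ))
    return results


def multiple_t_fdr(
    pairs: Sequence[tuple[str, Sequence[float], Sequence[float]]],
    q: float = 0.05,
) -> list[StatResult]:
    """Per-comparison Welch t-tests with two-stage step-up FDR discoveries.

    ``pairs`` are (label, sample_x, sample_y) two-sample comparisons; each
    gets a two-sided Welch t p-value, then the Benjamini-Krieger-Yekutieli
    two-stage procedure at level ``q`` marks discoveries.
    """
    if not 0 < q < 1:
        raise ValueError("Q must be in (0, 1)")
    if not pairs:
        raise ValueError("no comparisons supplied")
    results = []
    pvals = []
    for label, x, y in pairs:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"comparison {label!r} needs n >= 2 per arm")
        t = sps.ttest_ind(x, y, equal_var=False)
        results.append(StatResult("welch_t", float(t.statistic), (float(t.df),), float(t.pvalue), groups=[label]))
        pvals.append(float(t.pvalue))
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_tsbky")
    for res, flag in zip(results, reject):
        res.discovery = bool(flag)
    return results


def summarize_design(values: Sequence[float]) -> float:
    """Percent reduction from the largest to the smallest value,
    100 * (max - min) / max; a single value reduces by 0%."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty list")
    if np.any(arr <= 0):
        raise ValueError("values must be positive")
    return float(100.0 * (arr.max() - arr.min()) / arr.max())
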