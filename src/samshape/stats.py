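"""Comparative statistics for SAM morphospaces.

The group comparisons used throughout the analysis: Wilcoxon rank-sum tests
with a Hodges–Lehmann location-shift estimate (e.g., teosinte vs maize-inbred
SAM height/radius), Pearson correlation with Fisher-transformation p-values
(parabolic estimators vs shape PCs), the full estimator × PC correlation
matrix, and one-way ANOVA across evolutionary clades on the parabolic
coefficient.

The "estimated shift between medians" accompanying a rank-sum test is the
Hodges–Lehmann estimate — the median of all pairwise between-group
differences, which is what R's ``wilcox.test(conf.int=TRUE)`` reports — not
the literal difference of group medians; both are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ShiftTestResult",
    "CorrelationMatrix",
    "wilcoxon_shift",
    "pearson_fisher",
    "correlation_matrix",
    "clade_anova",
]

_EXACT_LIMIT = 10_000  # n1*n2 above which the normal approximation is used


@dataclass(frozen=True)
class ShiftTestResult:
    """Rank-sum test with Hodges–Lehmann shift estimate (x relative to y)."""

    shift_estimate: float
    median_difference: float
    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r / Fisher p between two phenotype tables.

    ``r``/``p`` are DataFrames (rows = left-table columns, columns =
    right-table columns); ``significant`` flags cells with p < alpha (no
    multiple-testing correction is applied).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_lines: int


def _as_clean_array(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError(f"{name} has no finite values")
    return a


def wilcoxon_shift(x, y, alternative: str = "two-sided") -> ShiftTestResult:
    """Wilcoxon (Mann–Whitney) rank-sum test with Hodges–Lehmann shift estimate.

    The p-value uses exact enumeration when n1·n2 ≤ 10,000 and there are no
    cross-sample ties, otherwise the normal approximation with continuity and
    tie correction.  ``shift_estimate`` is the median of all pairwise
    differences x_i − y_j; ``alternative`` refers to x relative to y.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    diffs = xa[:, None] - ya[None, :]
    hl = float(np.median(diffs))
    ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    method = "exact" if (xa.size * ya.size <= _EXACT_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative=alternative, method=method)
    return ShiftTestResult(
        shift_estimate=hl,
        median_difference=float(np.median(xa) - np.median(ya)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n1=int(xa.size),
        n2=int(ya.size),
    )


def pearson_fisher(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a Fisher-transformation p-value.

    z = atanh(r)·√(n−3); the two-sided p comes from the standard normal.
    Requires n ≥ 4 and non-constant inputs.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 4:
        raise ValueError("Fisher-transformation test needs n >= 4")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = 2.0 * sps.norm.sf(abs(z))
    return r, float(p)


def correlation_matrix(
    estimators: pd.DataFrame,
    pc_scores: pd.DataFrame,
    on: str = "line_id",
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """All pairwise Pearson/Fisher correlations between two tables joined on line id.

    Rows of the result are the estimator columns, columns the PC-score
    columns.  Cells with p ≥ alpha are flagged non-significant; no
    multiple-testing correction is applied.
    """
    left = estimators.set_index(on) if on in estimators.columns else estimators
    right = pc_scores.set_index(on) if on in pc_scores.columns else pc_scores
    shared = left.index.intersection(right.index)
    if shared.size < 4:
        raise ValueError(f"need >= 4 shared ids, got {shared.size}")
    left = left.loc[shared].select_dtypes("number")
    right = right.loc[shared].select_dtypes("number")

    r = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    p = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    for a in left.columns:
        for b in right.columns:
            r.loc[a, b], p.loc[a, b] = pearson_fisher(left[a], right[b])
    return CorrelationMatrix(r=r, p=p, significant=p < alpha, alpha=alpha,
                             n_lines=int(shared.size))


def clade_anova(values, groups, second_factor=None) -> tuple[float, float, tuple[int, int]]:
    """One-way fixed-effects ANOVA of a trait across groups -> (F, p, (df1, df2)).

    With ``second_factor`` an additive two-way ANOVA is fitted and the F test
    for the primary grouping is returned.  Degenerate inputs (fewer than two
    groups with two values, or zero within-group variance everywhere) raise.
    """
    v = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    if v.size != g.size:
        raise ValueError("values and groups must have equal length")
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    labels, idx = np.unique(g, return_inverse=True)
    counts = np.bincount(idx)
    if labels.size < 2 or np.sum(counts >= 2) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")

    if second_factor is not None:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": v, "g": g, "f2": np.asarray(second_factor).ravel()[keep]})
        fit = smf.ols("y ~ C(g) + C(f2)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        row = tab.loc["C(g)"]
        return (float(row["F"]), float(row["PR(>F)"]),
                (int(row["df"]), int(tab.loc["Residual", "df"])))

    n = v.size
    grand = v.mean()
    group_means = np.bincount(idx, weights=v) / counts
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((v - group_means[idx]) ** 2))
    df1, df2 = labels.size - 1, n - labels.size
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F undefined")
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return F, p, (df1, df2)
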