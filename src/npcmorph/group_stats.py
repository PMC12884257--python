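"""Two-group comparison machinery: assumption-gated test selection,
t / Welch / Mann-Whitney tests, effect sizes, and Benjamini-Hochberg FDR.

The gate mirrors common clinical-statistics practice: Shapiro-Wilk per
group decides normality, Levene (mean-centred) decides homoscedasticity,
and the chosen test is recorded so the decision is auditable. Effect
sizes follow the two-family convention: Cohen's d for mean comparisons,
r = Z/sqrt(N) for rank comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

TestKind = Literal["pooled_t", "welch_t", "mann_whitney"]

__all__ = [
    "GateReport",
    "ComparisonResult",
    "select_test",
    "pooled_t_test",
    "welch_t_test",
    "t_from_summary",
    "cohens_d",
    "mann_whitney_u",
    "effect_size_r",
    "fdr_bh",
    "compare_groups",
]


@dataclass(frozen=True)
class GateReport:
    """Record of the assumption checks behind a test choice."""

    shapiro_p_x: float
    shapiro_p_y: float
    levene_p: float
    alpha_gate: float
    test_kind: TestKind


@dataclass
class ComparisonResult:
    """One variable's two-group comparison, as reported in results tables."""

    variable: str
    test_kind: TestKind
    statistic: float
    p_raw: float
    effect_size: float
    z_approx: float | None = None
    p_adjusted: float | None = None
    family: str | None = None
    gate: GateReport | None = None


def _as_clean_array(sample: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def select_test(x: Sequence[float], y: Sequence[float], alpha_gate: float = 0.05) -> GateReport:
    """Choose between pooled t, Welch t and Mann-Whitney U.

    Either group non-normal (Shapiro-Wilk p < ``alpha_gate``) -> rank test;
    normal but heteroscedastic (Levene p < ``alpha_gate``) -> Welch;
    otherwise the classical pooled-variance t-test.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if len(x) < 3 or len(y) < 3:
        raise ValueError("select_test needs n >= 3 per group (Shapiro-Wilk undefined below)")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    # center='mean' is the classical Levene statistic (SPSS's default),
    # not scipy's Brown-Forsythe default.
    lev = stats.levene(x, y, center="mean").pvalue
    if sw_x < alpha_gate or sw_y < alpha_gate:
        kind: TestKind = "mann_whitney"
    elif lev < alpha_gate:
        kind = "welch_t"
    else:
        kind = "pooled_t"
    return GateReport(float(sw_x), float(sw_y), float(lev), alpha_gate, kind)


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Equal-variance two-sample t-test; returns (t, df, two-sided p).

    Direction convention: first argument minus second.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples degenerate with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    res = stats.ttest_ind(x, y, equal_var=False)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    kind: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from printed summary statistics (means, SDs, ns).

    Matches the corresponding raw-data test on any dataset with those
    summaries; used to reproduce published comparison tables.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if kind == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif kind == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        t = (m1 - m2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Cohen's d = (m1 - m2) / pooled SD, with (n-1)-weighted pooling."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((m1 - m2) / math.sqrt(sp2))


def cohens_d_from_data(x: Sequence[float], y: Sequence[float]) -> float:
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    return cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Mann-Whitney U test; returns (U, z, two-sided p).

    U is the count-based statistic for the first sample (ties count 1/2).
    z uses the tie-corrected normal approximation without continuity
    correction; for min(n) <= 8 with no ties the two-sided p comes from
    exact enumeration instead.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("need n >= 1 per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return n1 * n2 / 2.0, 0.0, 1.0

    u1 = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)

    # tie-corrected variance of U under the null
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var_u == 0 else (u1 - n1 * n2 / 2.0) / math.sqrt(var_u)

    has_ties = np.any(counts > 1)
    if min(n1, n2) <= 8 and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        # continuity-corrected p (the reported z stays uncorrected, as the
        # r = Z/sqrt(N) convention expects)
        dev = max(abs(u1 - n1 * n2 / 2.0) - 0.5, 0.0)
        zc = 0.0 if var_u == 0 else dev / math.sqrt(var_u)
        p = float(2 * stats.norm.sf(zc))
    return u1, float(z), min(p, 1.0)


def effect_size_r(U: float, n1: int, n2: int) -> float:
    """Rank effect size r = Z/sqrt(N) from a U statistic.

    The normal approximation here deliberately omits tie correction:
    printed U summaries carry no tie structure, so the untied variance
    n1*n2*(n1+n2+1)/12 is the only reproducible choice.
    """
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U = {U} outside [0, {n1 * n2}]")
    z = (U - n1 * n2 / 2.0) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return float(z / math.sqrt(n1 + n2))


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adjusted[i] = min over j with p[j] >= p[i] of m*p[j]/rank(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def compare_groups(
    x: Sequence[float], y: Sequence[float], variable: str = "",
    alpha_gate: float = 0.05, family: str | None = None,
) -> ComparisonResult:
    """Gate-selected two-group comparison with the matching effect size.

    d accompanies t-tests; r = Z/sqrt(N) accompanies the U test, with z
    taken tie-corrected from the raw data.
    """
    gate = select_test(x, y, alpha_gate=alpha_gate)
    x_arr = _as_clean_array(x, "x")
    y_arr = _as_clean_array(y, "y")
    n = len(x_arr) + len(y_arr)
    if gate.test_kind == "mann_whitney":
        u, z, p = mann_whitney_u(x_arr, y_arr)
        return ComparisonResult(variable, "mann_whitney", u, p,
                                effect_size=z / math.sqrt(n), z_approx=z,
                                family=family, gate=gate)
    if gate.test_kind == "welch_t":
        t, _, p = welch_t_test(x_arr, y_arr)
    else:
        t, _, p = pooled_t_test(x_arr, y_arr)
    d = cohens_d_from_data(x_arr, y_arr)
    return ComparisonResult(variable, gate.test_kind, t, p, effect_size=d,
                            family=family, gate=gate)
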