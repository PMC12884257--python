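"""Kendall tau-b association screens with FDR, and LMS-based BMI-SDS.

BMI-SDS converts a raw BMI into an age- and sex-specific z-score through
the LMS (lambda-mu-sigma) method: with L the Box-Cox power, M the median
and S the coefficient of variation interpolated at the subject's age,

    z = ((BMI/M)**L - 1) / (L*S)      (L != 0)
    z = ln(BMI/M) / S                 (L == 0)

The national growth reference used clinically (e.g. KiGGS for German
adolescents) is licensed and not redistributable, so the package reads
any user-supplied LMS table and ships a clearly-labelled *synthetic*
reference for tests and demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import fdr_bh

__all__ = [
    "CorrelationMatrix",
    "LMSReference",
    "kendall_tau_b",
    "correlation_screen",
    "bmi_sds",
    "bmi_from_sds",
    "synthetic_lms_reference",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    tau: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: int


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with tie corrections in both margins.

    p-value from exact enumeration for n <= 10 without ties, otherwise
    from the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for a constant variable")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def correlation_screen(frame: pd.DataFrame, family: str = "screen") -> CorrelationMatrix:
    """All-pairs Kendall tau-b over the columns of ``frame``.

    FDR is applied over the unique off-diagonal cells (one family per
    screen). Pairs are complete-case; cells with fewer than 3 complete
    pairs, or with a constant margin, are reported as missing.
    """
    cols = list(frame.columns)
    k = len(cols)
    tau = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_raw = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    pairs: list[tuple[int, int]] = []
    p_list: list[float] = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = frame[[cols[i], cols[j]]].dropna()
            if len(sub) < 3:
                tau.iloc[i, j] = tau.iloc[j, i] = np.nan
                continue
            try:
                t, p = kendall_tau_b(sub.iloc[:, 0], sub.iloc[:, 1])
            except ValueError:
                tau.iloc[i, j] = tau.iloc[j, i] = np.nan
                continue
            tau.iloc[i, j] = tau.iloc[j, i] = t
            p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
            pairs.append((i, j))
            p_list.append(p)
    p_adj = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    if p_list:
        adj = fdr_bh(p_list)
        for (i, j), a in zip(pairs, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
    return CorrelationMatrix(variables=cols, tau=tau, p_raw=p_raw,
                             p_adjusted=p_adj, n=len(frame))


@dataclass
class LMSReference:
    """Age grid of L/M/S parameters, one stratum per sex.

    ``table`` columns: sex, age (years), L, M (kg/m^2), S.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        for sex, sub in self.table.groupby("sex"):
            ages = sub["age"].to_numpy(float)
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"age grid not strictly increasing for sex {sex!r}")
            if np.any(sub["M"] <= 0) or np.any(sub["S"] <= 0):
                raise ValueError("M and S must be positive")

    @classmethod
    def from_tsv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def interpolate(self, age: float, sex: str) -> tuple[float, float, float]:
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no LMS stratum for sex {sex!r}")
        ages = sub["age"].to_numpy(float)
        if age < ages[0] or age > ages[-1]:
            raise ValueError(
                f"age {age} outside reference grid [{ages[0]}, {ages[-1]}] (no extrapolation)"
            )
        L = float(np.interp(age, ages, sub["L"]))
        M = float(np.interp(age, ages, sub["M"]))
        S = float(np.interp(age, ages, sub["S"]))
        return L, M, S


def bmi_sds(bmi: float, age: float, sex: str, ref: LMSReference) -> float:
    """BMI standard-deviation score through the LMS transform."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    L, M, S = ref.interpolate(age, sex)
    if abs(L) < 1e-8:
        return float(np.log(bmi / M) / S)
    return float(((bmi / M) ** L - 1.0) / (L * S))


def bmi_from_sds(z: float, age: float, sex: str, ref: LMSReference) -> float:
    """Inverse LMS transform: the BMI whose SDS equals ``z``."""
    L, M, S = ref.interpolate(age, sex)
    if abs(L) < 1e-8:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def bmi_percentile(z: float) -> float:
    """Percentile corresponding to an SDS value, 0-100 scale."""
    return float(stats.norm.cdf(z) * 100.0)


def synthetic_lms_reference(age_min: float = 5.0, age_max: float = 20.0,
                            step: float = 0.5) -> LMSReference:
    """SYNTHETIC LMS growth reference for tests and demos.

    Not a published growth standard: smooth curves qualitatively shaped
    like adolescent BMI-for-age references (median BMI rising from ~15.5
    to ~21.5 kg/m^2 between ages 5 and 20, mild left-skew via L < 1,
    CV around 10-13%), one stratum per sex with a small sex offset.
    """
    ages = np.arange(age_min, age_max + step / 2, step)
    rows = []
    for sex, m_off in (("f", 0.0), ("m", 0.3)):
        # logistic rise of the median through puberty
        M = 15.5 + 6.0 / (1.0 + np.exp(-(ages - 13.0) / 2.2)) + m_off
        L = -1.6 + 0.04 * (ages - age_min)          # skewness power
        S = 0.10 + 0.03 * np.exp(-((ages - 12.0) ** 2) / 40.0)
        for a, l, m, s in zip(ages, L, M, S):
            rows.append({"sex": sex, "age": round(float(a), 2),
                         "L": round(float(l), 4), "M": round(float(m), 4),
                         "S": round(float(s), 4)})
    return LMSReference(pd.DataFrame(rows))
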