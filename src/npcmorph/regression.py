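"""OLS with standardized coefficients, VIF screening and SPSS-style
backward elimination (remove while max p > POUT; no re-entry)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionModel", "fit_ols", "vif", "backward_eliminate"]


@dataclass
class RegressionModel:
    """Fitted OLS model in the layout of a clinical regression table.

    ``coefficients`` rows (one per predictor plus ``(Intercept)``):
    B, SE, beta, t, p, VIF, ci_low, ci_high. VIF and beta are NaN for
    the intercept.
    """

    outcome: str
    coefficients: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    n: int
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return [name for name in self.coefficients.index if name != "(Intercept)"]


def _check_design(X: pd.DataFrame) -> None:
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(float)]))
    if rank < X.shape[1] + 1:
        # name the aliased columns by checking each against the rest
        aliased = []
        for col in X.columns:
            others = X.drop(columns=[col])
            design = np.column_stack([np.ones(len(X)), others.to_numpy(float)])
            resid = X[col].to_numpy(float) - design @ np.linalg.lstsq(
                design, X[col].to_numpy(float), rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(X[col]).max())):
                aliased.append(col)
        raise ValueError(f"design matrix rank-deficient; aliased columns: {aliased}")


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    R^2_j is from regressing predictor j on the remaining predictors
    (with intercept). Perfect collinearity yields ``inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(float))
        r2 = sm.OLS(X[col].to_numpy(float), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def fit_ols(y: pd.Series, X: pd.DataFrame, outcome: str | None = None) -> RegressionModel:
    """Ordinary least squares with the classical covariance.

    beta (standardized slope) = B * sd(x)/sd(y) with (n-1)-denominator
    sample SDs; 95% CI of B at the t critical value with n-p-1 df.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    _check_design(X)
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    n, p = len(y), X.shape[1]
    tcrit = stats.t.ppf(0.975, n - p - 1)
    sd_y = y.std(ddof=1)
    vifs = vif(X) if p >= 2 else pd.Series({X.columns[0]: np.nan})

    rows = {}
    rows["(Intercept)"] = {
        "B": fit.params["const"], "SE": fit.bse["const"], "beta": np.nan,
        "t": fit.tvalues["const"], "p": fit.pvalues["const"], "VIF": np.nan,
        "ci_low": fit.params["const"] - tcrit * fit.bse["const"],
        "ci_high": fit.params["const"] + tcrit * fit.bse["const"],
    }
    for col in X.columns:
        b = fit.params[col]
        rows[col] = {
            "B": b, "SE": fit.bse[col],
            "beta": b * X[col].std(ddof=1) / sd_y,
            "t": fit.tvalues[col], "p": fit.pvalues[col],
            "VIF": vifs.get(col, np.nan),
            "ci_low": b - tcrit * fit.bse[col],
            "ci_high": b + tcrit * fit.bse[col],
        }
    coef = pd.DataFrame.from_dict(rows, orient="index")
    return RegressionModel(
        outcome=outcome or (y.name if y.name is not None else "y"),
        coefficients=coef,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
    )


def backward_eliminate(
    y: pd.Series,
    X: pd.DataFrame,
    p_out: float = 0.10,
    p_in: float = 0.05,
    allow_reentry: bool = False,
) -> RegressionModel:
    """Backward elimination from the full model.

    At each step the predictor with the largest p-value is removed if it
    exceeds ``p_out``; the loop stops when every retained predictor has
    p <= ``p_out`` (or none remain). ``p_in`` exists for SPSS-interface
    parity; pure backward never re-enters a predictor unless
    ``allow_reentry`` is set, in which case a removed predictor whose
    add-back p-value would fall below ``p_in`` is re-admitted.
    """
    if p_out < p_in:
        raise ValueError("p_out must be >= p_in")
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    _check_design(X)

    kept = list(X.columns)
    removed: list[str] = []
    trace: list[tuple[str, float]] = []
    while kept:
        model = fit_ols(y, X[kept])
        pvals = model.coefficients.loc[kept, "p"]
        worst = pvals.sort_values(ascending=False, kind="mergesort").index[0]
        if pvals[worst] <= p_out:
            break
        kept.remove(worst)
        removed.append(worst)
        trace.append((worst, float(pvals[worst])))
        if allow_reentry and kept:
            for cand in list(removed):
                trial = fit_ols(y, X[kept + [cand]])
                if trial.coefficients.loc[cand, "p"] < p_in:
                    kept.append(cand)
                    removed.remove(cand)

    if kept:
        final = fit_ols(y, X[kept])
    else:
        # intercept-only model
        const = sm.OLS(y.to_numpy(), np.ones((len(y), 1))).fit()
        ci = np.asarray(const.conf_int())
        coef = pd.DataFrame.from_dict({"(Intercept)": {
            "B": const.params[0], "SE": const.bse[0], "beta": np.nan,
            "t": const.tvalues[0], "p": const.pvalues[0], "VIF": np.nan,
            "ci_low": ci[0, 0], "ci_high": ci[0, 1],
        }}, orient="index")
        final = RegressionModel(outcome=y.name or "y", coefficients=coef,
                                r_squared=0.0, adj_r_squared=0.0, n=len(y))
    final.elimination_trace = trace
    return final
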