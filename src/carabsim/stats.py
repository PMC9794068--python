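"""Regression stage: correlation-filter predictors, then backward-stepwise
AIC selection of ordinary-least-squares models of endpoints (or endpoint
changes) on landscape/farmland heterogeneity metrics.

Candidate predictors with pairwise Pearson |r| above a threshold (default
0.7) are removed greedily before modelling; model search starts from the
full OLS fit and repeatedly drops the term whose removal lowers the AIC
the most, stopping when no single removal lowers it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

SMALL_SAMPLE_N = 30


@dataclass
class RegressionResult:
    """Selected model for one response variable."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    adjusted_r2: float
    model_pvalue: float
    aic: float
    full_model_aic: float
    n_obs: int
    small_sample: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "coefficient": list(self.coefficients.values()),
                "pvalue": [self.pvalues[t] for t in self.coefficients],
            }
        )


def correlation_filter(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Drop correlated predictor columns until no pair exceeds |threshold|.

    Greedy rule: while any pair's Pearson |r| exceeds the threshold, take
    the worst pair and drop the member with the higher mean absolute
    correlation to all remaining columns; ties break alphabetically (the
    later name is dropped).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two columns to filter")
    cols = list(table.columns)
    while len(cols) > 1:
        corr = table[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= threshold or not np.isfinite(worst):
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = cols[i], cols[j]
        mean_a = corr[a].drop([a, b]).mean() if len(cols) > 2 else 0.0
        mean_b = corr[b].drop([a, b]).mean() if len(cols) > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        logger.info("correlation filter: dropping %r (|r|=%.2f with %r)", drop, worst,
                    a if drop == b else b)
        cols.remove(drop)
    return table[cols]


def stepwise_fit(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    response_name: str | None = None,
) -> RegressionResult:
    """Backward-stepwise AIC selection of an OLS multiple regression.

    Starts from the model with all predictors; at each step the term whose
    removal lowers the AIC the most is dropped, until no removal lowers
    it. Reports coefficients and p-values of the retained terms, adjusted
    R-squared and the overall model (F-test) p-value.
    """
    y = np.asarray(response, dtype=float)
    name = response_name or getattr(response, "name", None) or "response"
    n, k = len(y), predictors.shape[1]
    if n <= k + 2:
        raise ValueError("need more observations than predictors + 2")
    X = predictors.astype(float)
    rank = np.linalg.matrix_rank(sm.add_constant(X).to_numpy())
    if rank < k + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            "rank-deficient design; most collinear columns: "
            f"{corr.columns[i]!r} and {corr.columns[j]!r}"
        )
    small = n < SMALL_SAMPLE_N
    if small:
        warnings.warn(
            f"only {n} observations: model selection is unstable at small n",
            stacklevel=2,
        )

    def _fit(cols: list[str]):
        design = sm.add_constant(X[cols]) if cols else pd.DataFrame(
            {"const": np.ones(n)}, index=X.index
        )
        return sm.OLS(y, design).fit()

    current = list(X.columns)
    model = _fit(current)
    full_aic = model.aic
    while current:
        candidates = [(c, _fit([x for x in current if x != c])) for c in current]
        best_col, best_model = min(candidates, key=lambda t: t[1].aic)
        if best_model.aic < model.aic:
            current.remove(best_col)
            model = best_model
        else:
            break

    coeffs = {t: float(model.params[t]) for t in model.params.index}
    pvals = {t: float(model.pvalues[t]) for t in model.params.index}
    model_p = float(model.f_pvalue) if current else 1.0
    if not np.isfinite(model_p):
        model_p = 1.0
    return RegressionResult(
        response=str(name),
        predictors=current,
        coefficients=coeffs,
        pvalues=pvals,
        adjusted_r2=float(model.rsquared_adj) if current else 0.0,
        model_pvalue=model_p,
        aic=float(model.aic),
        full_model_aic=float(full_aic),
        n_obs=n,
        small_sample=small,
    )


class CorrelationFilter:
    """sklearn-style transformer wrapper around :func:`correlation_filter`.

    ``fit`` learns which columns survive the greedy filter on the training
    table; ``transform`` selects those columns.
    """

    def __init__(self, threshold: float = 0.7):
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "CorrelationFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationFilter":
        self.columns_ = list(correlation_filter(X, self.threshold).columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "columns_"):
            raise RuntimeError("CorrelationFilter must be fitted before transform")
        return X[self.columns_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
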