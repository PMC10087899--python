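"""Shared OLS plumbing for the substitution and coordinate regressions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    """A fitted linear model with both covariance estimators retained."""

    params: pd.Series
    cov_model: pd.DataFrame          # classical (sigma^2 (X'X)^-1)
    cov_sandwich: pd.DataFrame       # heteroskedasticity-consistent (HC1)
    resid_var: float
    n: int
    fitted: np.ndarray
    design_info: dict

    def se(self, which: str = "model") -> pd.Series:
        cov = self.cov_model if which == "model" else self.cov_sandwich
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def var(self, name: str, which: str = "model") -> float:
        cov = self.cov_model if which == "model" else self.cov_sandwich
        return float(cov.loc[name, name])


def covariate_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric covariates pass through; object/categorical columns are
    dummy-coded dropping the first level."""
    pieces = []
    for col in covariates:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float).to_frame(col))
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


def complete_cases(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    mask = df[columns].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("complete-case filter: excluded %d of %d rows with "
                    "missing values", n_drop, len(df))
    return df.loc[mask]


def fit_ols(y: np.ndarray, X: pd.DataFrame, design_info: dict | None = None
            ) -> RegressionFit:
    model = sm.OLS(np.asarray(y, dtype=float), X.astype(float))
    res = model.fit()
    robust = res.get_robustcov_results(cov_type="HC1")
    cov_model = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    cov_sand = pd.DataFrame(np.asarray(robust.cov_params()),
                            index=X.columns, columns=X.columns)
    return RegressionFit(
        params=pd.Series(res.params, index=X.columns),
        cov_model=cov_model,
        cov_sandwich=cov_sand,
        resid_var=float(res.mse_resid),
        n=int(res.nobs),
        fitted=np.asarray(res.fittedvalues),
        design_info=design_info or {},
    )
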