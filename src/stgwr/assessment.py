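"""Goodness-of-fit metrics and local-coefficient summary tables.

Model families are compared on corrected AIC, adjusted R2, RMSE and
MAE.  The adjusted coefficient of determination

    Ra2 = 1 - (n - 1)(1 - R2) / (n - p)

discounts R2 by the number of fitted parameters; for the local families
p is the hat-matrix trace (effective parameters), for the global fit the
coefficient count.  Local coefficients are summarized per regressor by
min/mean/max, standard deviation, excess (Fisher) kurtosis and sample
skewness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bandwidth import aicc_of_fit
from .models import LocalFit


@dataclass(frozen=True)
class FitAssessment:
    family: str
    n: int
    p_model: int           # regressors excluding intercept
    trace_S: float
    aicc: float
    r2: float
    adjusted_r2: float
    rmse: float
    mae: float

    def to_dict(self) -> dict:
        return {"family": self.family, "n": self.n, "p_model": self.p_model,
                "trace_S": self.trace_S, "AICc": self.aicc, "R2": self.r2,
                "Ra2": self.adjusted_r2, "RMSE": self.rmse, "MAE": self.mae}


def adjusted_r2(r2: float, n: int, p: float) -> float:
    """Ra2 = 1 - (n-1)(1-R2)/(n-p); p counts all coefficients incl. intercept."""
    if n <= p:
        raise ValueError(f"n={n} must exceed parameter count p={p}")
    return float(1.0 - (n - 1) * (1.0 - r2) / (n - p))


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return float(np.mean(np.abs(y - yhat)))


def assess(fit: LocalFit) -> FitAssessment:
    """All comparison metrics for one fitted model family."""
    y, yhat = fit.y, fit.fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance")
    rss = float(np.sum(fit.residuals**2))
    r2 = 1.0 - rss / tss
    p_eff = fit.trace_S if fit.family != "OLS" else float(fit.p)
    try:
        aicc = aicc_of_fit(fit)
    except ValueError:
        aicc = -np.inf if fit.sigma_hat == 0 else np.nan
    return FitAssessment(family=fit.family, n=fit.n, p_model=fit.p - 1,
                         trace_S=fit.trace_S, aicc=aicc, r2=r2,
                         adjusted_r2=adjusted_r2(r2, fit.n, p_eff),
                         rmse=rmse(y, yhat), mae=mae(y, yhat))


def summarize_coefficients(fit: LocalFit) -> pd.DataFrame:
    """Tables of per-regressor local-coefficient statistics.

    Columns: Min, Mean, Max, SD, Kurtosis (excess/Fisher), Skewness.
    Constant coefficient columns get SD = 0 and undefined (NaN) shape
    statistics.
    """
    if fit.family == "OLS":
        raise ValueError("coefficient summaries are for local families")
    rows = []
    for j, name in enumerate(fit.names):
        c = fit.coef[:, j]
        sd = float(np.std(c, ddof=1))
        if sd == 0:
            kurt, skew = np.nan, np.nan
        else:
            kurt = float(stats.kurtosis(c, fisher=True, bias=False))
            skew = float(stats.skew(c, bias=False))
        rows.append({"variable": name, "Min": float(c.min()), "Mean": float(c.mean()),
                     "Max": float(c.max()), "SD": sd, "Kurtosis": kurt,
                     "Skewness": skew})
    return pd.DataFrame(rows)


def comparison_table(assessments) -> pd.DataFrame:
    """One row per model family, in the schema used for model comparison."""
    return pd.DataFrame([a.to_dict() for a in assessments])
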