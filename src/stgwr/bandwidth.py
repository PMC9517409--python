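"""Adaptive-bandwidth selection by corrected AIC or leave-one-out CV.

The neighbor count k (and, for the spatio-temporal family, the
space-time balance ratio tau = mu/lambda) is chosen by exhaustive grid
search.  The corrected Akaike criterion for a local fit is

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + trS) / (n - 2 - trS),

with sigma_hat = sqrt(RSS/n) and trS the hat-matrix trace, so smaller k
(more flexible fits) is penalized through trS.  The cross-validation
score sums squared prediction errors with the focal observation's own
weight zeroed out of its local fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import KernelSpec, STDistanceParams, adaptive_bandwidth, kernel_weight
from .models import LocalFit, _distance_matrix, _local_solve, add_intercept, fit_model


@dataclass
class SearchResult:
    family: str
    criterion_name: str
    table: pd.DataFrame          # columns: k, tau, criterion
    best_k: int
    best_tau: float

    @property
    def best_criterion(self) -> float:
        mask = (self.table["k"] == self.best_k) & (self.table["tau"] == self.best_tau)
        return float(self.table.loc[mask, "criterion"].iloc[0])


def aicc_of_fit(fit: LocalFit) -> float:
    """Corrected AIC of a fitted model from sigma_hat and trace(S)."""
    n, tr = fit.n, fit.trace_S
    if n - 2 - tr <= 0:
        raise ValueError(f"over-parameterized fit: trace(S)={tr:.1f} >= n-2={n - 2}")
    if fit.sigma_hat <= 0:
        raise ValueError("zero residual scale; AICc undefined")
    return float(2 * n * np.log(fit.sigma_hat) + n * np.log(2 * np.pi)
                 + n * (n + tr) / (n - 2 - tr))


def loocv_score(lon, lat, time, X, y, family: str, kernel: KernelSpec,
                st: STDistanceParams | None = None) -> float:
    """Sum of squared leave-one-out prediction errors.

    Each observation is predicted from a local fit in which its own
    weight is set to zero; the kernel bandwidth is still the k-th
    neighbor distance among the other points.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    time = np.asarray(time, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = add_intercept(X)
    n, p = Xd.shape
    st = st or STDistanceParams()
    D = _distance_matrix(lon, lat, time, family.upper(), st)
    idx = np.arange(n)
    sse = 0.0
    for i in range(n):
        d = D[i]
        h = (adaptive_bandwidth(d[idx != i], kernel.neighbors)
             if kernel.adaptive else kernel.bandwidth)
        if h is None or h <= 0:
            raise ValueError(f"observation {i}: non-positive bandwidth in leave-one-out fit")
        w = kernel_weight(d, h, kernel.family)
        w[i] = 0.0
        if np.count_nonzero(w > 0) < p:
            raise ValueError(f"observation {i}: too few positive-weight neighbors "
                             "for a leave-one-out fit; increase the neighbor count")
        try:
            beta, _ = _local_solve(Xd, Xd * w[:, None], y, Xd[i])
        except ValueError as exc:
            raise ValueError(f"observation {i}: {exc}") from exc
        sse += (y[i] - Xd[i] @ beta) ** 2
    return float(sse)


def default_k_grid(n: int, p_model: int, size: int = 20) -> list[int]:
    """Log-spaced neighbor counts between p_model + 2 and n - 1."""
    lo, hi = p_model + 2, n - 1
    if lo >= hi:
        return [hi]
    ks = np.unique(np.round(np.geomspace(lo, hi, size)).astype(int))
    return [int(k) for k in ks if lo <= k <= hi]


def default_tau_grid(size: int = 7, lo: float = 1e-3, hi: float = 10.0) -> list[float]:
    """Log-spaced space-time balance ratios mu/lambda."""
    return [float(t) for t in np.geomspace(lo, hi, size)]


def search_neighbors(lon, lat, time, X, y, family: str,
                     kernel_family: str | None = None,
                     k_grid=None, tau_grid=None,
                     criterion: str = "aicc",
                     coordinate_mode: str = "planar") -> SearchResult:
    """Exhaustive (k, tau) grid search minimizing AICc or the CV score.

    tau matters only for the GTWR family (GWR and TWR fix it); ties are
    broken toward larger k, i.e. the smoother model.
    """
    family = family.upper()
    if criterion not in ("aicc", "cv"):
        raise ValueError(f"unknown criterion {criterion!r}")
    Xarr = np.asarray(X, dtype=float)
    p_model = 1 if Xarr.ndim == 1 else Xarr.shape[1]
    n = len(np.asarray(y))
    if kernel_family is None:
        kernel_family = "bisquare" if family == "GWR" else "gaussian"
    if k_grid is None:
        k_grid = default_k_grid(n, p_model)
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ValueError("empty neighbor grid")
    if family == "GTWR":
        tau_grid = sorted(float(t) for t in (tau_grid if tau_grid is not None
                                             else default_tau_grid()))
    else:
        tau_grid = [1.0]

    rows = []
    for tau in tau_grid:
        st = STDistanceParams(lambda_scale=1.0, mu_scale=tau,
                              coordinate_mode=coordinate_mode)
        for k in k_grid:
            spec = KernelSpec(family=kernel_family, adaptive=True, neighbors=k)
            try:
                if criterion == "aicc":
                    fit = fit_model(lon, lat, time, X, y, family,
                                    kernel=spec, st=st)
                    value = aicc_of_fit(fit)
                else:
                    value = loocv_score(lon, lat, time, X, y, family,
                                        kernel=spec, st=st)
            except ValueError:
                value = np.inf
            rows.append({"k": k, "tau": tau, "criterion": value})

    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["criterion"])]
    if finite.empty:
        raise ValueError("no feasible point on the (k, tau) grid")
    best_value = finite["criterion"].min()
    ties = finite[finite["criterion"] == best_value]
    best = ties.sort_values(["k", "tau"]).iloc[-1]
    return SearchResult(family=family, criterion_name=criterion, table=table,
                        best_k=int(best["k"]), best_tau=float(best["tau"]))
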