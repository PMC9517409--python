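"""Global OLS and locally weighted (GWR / TWR / GTWR) model fits.

All four families share one estimator: at each focal observation i the
coefficient vector solves the weighted normal equations

    beta_i = (X' W_i X)^-1 X' W_i y,

where W_i is diagonal with kernel weights decaying in the family's
distance metric — spatial for GWR, temporal for TWR, the combined
space-time metric for GTWR, and uniform weights (the global OLS limit)
for the OLS family.  The hat row of observation i is
x_i' (X' W_i X)^-1 X' W_i, whose diagonal accumulates into trace(S), the
effective number of parameters used by AICc and adjusted R2.

Solves use Cholesky factorization of the weighted cross-product (QR for
the global fit), never explicit inversion; a condition number above
1e12 for the weighted design is treated as singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .kernels import (KernelSpec, STDistanceParams, adaptive_bandwidth,
                      kernel_weight)

FAMILIES = ("OLS", "GWR", "TWR", "GTWR")

#: condition-number threshold for the weighted design matrix
MAX_CONDITION = 1e12


@dataclass
class LocalFit:
    """Per-observation coefficients and hat-matrix diagnostics."""

    family: str
    names: tuple                      # regressor names incl. "intercept"
    coef: np.ndarray                  # n x (p_model + 1)
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    trace_S: float
    sigma_hat: float                  # sqrt(RSS / n)
    y: np.ndarray
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None
    time: np.ndarray | None = None
    station_id: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        """Number of coefficients including the intercept."""
        return self.coef.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Coefficients keyed by station and time, with fit diagnostics."""
        out = pd.DataFrame(self.coef, columns=list(self.names))
        if self.station_id is not None:
            out.insert(0, "station_id", self.station_id)
        for name, arr in (("lon", self.lon), ("lat", self.lat), ("time", self.time)):
            if arr is not None:
                out[name] = arr
        out["fitted"] = self.fitted
        out["residual"] = self.residuals
        out["hat_diag"] = self.hat_diag
        return out


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(X: np.ndarray, y: np.ndarray, names=None, **meta) -> LocalFit:
    """Global least squares via QR; coefficients replicated per record.

    ``X`` must already carry its intercept column.  Rank deficiency is
    an error naming the offending (dependent) columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    names = tuple(names) if names is not None else _default_names(p)

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag.max() * n * np.finfo(float).eps))
    if rank < p:
        dep = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"rank-deficient design; dependent column(s): {dep}")
    beta = linalg.solve_triangular(R, Q.T @ y)
    beta = beta[np.argsort(piv)]

    fitted = X @ beta
    resid = y - fitted
    hat = np.sum(Q**2, axis=1)
    return LocalFit(family="OLS", names=names, coef=np.tile(beta, (n, 1)),
                    fitted=fitted, residuals=resid, hat_diag=hat,
                    trace_S=float(p), sigma_hat=float(np.sqrt(resid @ resid / n)),
                    y=y, **meta)


def _default_names(p: int) -> tuple:
    return tuple(["intercept"] + [f"X{k}" for k in range(1, p)])


def fit_local_point(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    i: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares for one focal observation.

    Returns ``(beta, hat_row)`` with hat_row = x_i'(X'WX)^-1 X'W; when
    ``i`` is None the hat row is omitted (returned as None).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = X.shape[1]
    if np.count_nonzero(w > 0) < p:
        raise ValueError(f"only {np.count_nonzero(w > 0)} positive-weight observations "
                         f"for {p} coefficients; increase the neighbor count")
    Xw = X * w[:, None]
    beta, hat_row = _local_solve(X, Xw, y, X[i if i is not None else 0])
    return beta, (hat_row if i is not None else None)


def _local_solve(X, Xw, y, xi):
    """beta and hat row at one point given precomputed Xw = X * w."""
    A = X.T @ Xw
    eig = np.linalg.eigvalsh(A)
    if eig[0] <= 0 or eig[-1] / max(eig[0], 0.0) > MAX_CONDITION**2:
        raise ValueError("singular weighted cross-product; increase the neighbor count")
    c, low = linalg.cho_factor(A)
    beta = linalg.cho_solve((c, low), Xw.T @ y)
    hat_row = Xw @ linalg.cho_solve((c, low), xi)
    return beta, hat_row


def _distance_matrix(lon, lat, time, family: str, st: STDistanceParams) -> np.ndarray:
    """Pairwise distances in the metric of the requested model family."""
    n = len(lon)
    if family == "TWR":
        dt = np.abs(time[:, None] - time[None, :])
        return np.sqrt(st.mu_scale) * dt if st.mu_scale != 1.0 else dt
    if st.coordinate_mode == "planar":
        ds = np.hypot(lon[:, None] - lon[None, :], lat[:, None] - lat[None, :])
    else:
        from .kernels import haversine_km
        ds = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    if family == "GWR":
        return ds
    dt = np.abs(time[:, None] - time[None, :])
    return np.sqrt(st.lambda_scale * ds**2 + st.mu_scale * dt**2)


def fit_model(lon, lat, time, X, y, family: str,
              kernel: KernelSpec | None = None,
              st: STDistanceParams | None = None,
              names=None, station_id=None) -> LocalFit:
    """Fit one model family over every observation.

    ``X`` is the regressor matrix WITHOUT intercept (scores); the
    intercept column is added here.  Kernel defaults follow the study
    design: adaptive bisquare for GWR, adaptive Gaussian for TWR/GTWR.
    """
    family = family.upper()
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    time = np.asarray(time, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = add_intercept(X)
    n, p = Xd.shape
    if not (len(lon) == len(lat) == len(time) == len(y) == n):
        raise ValueError("inputs must be row-aligned")
    names = tuple(names) if names is not None else _default_names(p)
    meta = dict(lon=lon, lat=lat, time=time,
                station_id=None if station_id is None else np.asarray(station_id))

    if family == "OLS":
        return fit_ols(Xd, y, names=names, **meta)

    if kernel is None:
        kernel = KernelSpec(family="bisquare" if family == "GWR" else "gaussian",
                            adaptive=True, neighbors=max(30, p + 2))
    st = st or STDistanceParams()
    D = _distance_matrix(lon, lat, time, family, st)

    coef = np.empty((n, p))
    fitted = np.empty(n)
    hat_diag = np.empty(n)
    trace = 0.0
    idx = np.arange(n)
    for i in range(n):
        d = D[i]
        if kernel.adaptive:
            h = adaptive_bandwidth(d[idx != i], kernel.neighbors)
            if h <= 0:
                raise ValueError(
                    f"adaptive bandwidth is zero at observation {i}: more than "
                    f"{kernel.neighbors} observations share its location in this metric; "
                    "increase the neighbor count")
        else:
            h = kernel.bandwidth
        w = kernel_weight(d, h, kernel.family)
        if np.count_nonzero(w > 0) < p:
            raise ValueError(f"observation {i}: only {np.count_nonzero(w > 0)} "
                             f"positive-weight observations for {p} coefficients; "
                             "increase the neighbor count")
        try:
            beta, hat_row = _local_solve(Xd, Xd * w[:, None], y, Xd[i])
        except ValueError as exc:
            raise ValueError(f"observation {i}: {exc}") from exc
        coef[i] = beta
        fitted[i] = Xd[i] @ beta
        hat_diag[i] = hat_row[i]
        trace += hat_row[i]

    resid = y - fitted
    return LocalFit(family=family, names=names, coef=coef, fitted=fitted,
                    residuals=resid, hat_diag=hat_diag, trace_S=float(trace),
                    sigma_hat=float(np.sqrt(resid @ resid / n)), y=y, **meta)
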