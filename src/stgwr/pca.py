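"""Correlation-matrix PCA with varimax rotation and adequacy tests.

The 20 covariates mix hPa, deg C, m/s and unitless indices, so
components are extracted from the correlation matrix (equivalently,
from standardized data).  Components are retained up to a cumulative
explained-variance threshold (default 85%), varimax-rotated for
interpretability, and converted to standardized, mutually uncorrelated
scores that serve as regressors downstream.

Sampling adequacy is screened with the Kaiser-Meyer-Olkin (KMO)
statistic — the ratio of summed squared simple correlations to the same
sum plus summed squared anti-image partial correlations — and with
Bartlett's sphericity test,

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R),   dof = p(p - 1)/2.

KMO > 0.5 with a small Bartlett p-value indicates the variables share
enough common variance for PCA to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass(frozen=True)
class AdequacyReport:
    kmo: float
    bartlett_statistic: float
    bartlett_dof: int
    bartlett_p: float


@dataclass(frozen=True)
class PCAModel:
    """Fitted correlation-matrix PCA.

    ``loadings`` are variable-component correlations (eigenvector *
    sqrt(eigenvalue)) for the selected components; ``rotation`` is the
    orthogonal varimax transform applied to them.  ``scores`` are the
    rotated, standardized scores on the fit sample: unit variance,
    identity covariance.
    """

    columns: tuple
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray          # all p, non-increasing
    eigenvectors: np.ndarray         # p x p
    proportions: np.ndarray          # all p, sums to 1
    cumulative: np.ndarray
    n_selected: int
    loadings: np.ndarray             # p x m, unrotated
    rotation: np.ndarray             # m x m orthogonal
    rotated_loadings: np.ndarray     # p x m
    scores: np.ndarray               # n x m, rotated standardized

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_selected)]


def standardize(data, columns=None):
    """Center and scale columns to mean 0, sd 1 (ddof=1).

    Accepts a DataFrame (with ``columns`` naming the covariates) or a
    plain array.  Returns ``(Z, means, sds)``.  A zero-variance column
    is an error naming the column.
    """
    if isinstance(data, pd.DataFrame):
        cols = list(columns) if columns is not None else list(data.columns)
        X = data[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        cols = list(columns) if columns is not None else [f"x{i}" for i in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s): {[cols[i] for i in bad]}")
    return (X - means) / sds, means, sds


def destandardize(Z, means, sds):
    return Z * sds + means


def _correlation(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[0]
    Zc = Z - Z.mean(axis=0)
    sd = Zc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in correlation computation")
    Zc = Zc / sd
    return (Zc.T @ Zc) / (n - 1)


def kmo_statistic(Z) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    Anti-image partial correlations are computed from the inverse
    correlation matrix: q_ij = -S_ij / sqrt(S_ii S_jj) with S = R^-1.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 records")
    R = _correlation(Z)
    try:
        S = linalg.inv(R)
    except linalg.LinAlgError as exc:  # pragma: no cover - scipy raises generic
        raise ValueError("singular correlation matrix") from exc
    if not np.all(np.isfinite(S)) or np.linalg.cond(R) > 1e12:
        raise ValueError("singular correlation matrix")
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(Z) -> AdequacyReport:
    """Bartlett's test that the correlation matrix is the identity."""
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if n <= p:
        raise ValueError("need more records than variables")
    R = _correlation(Z)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(statistic, dof))
    return AdequacyReport(kmo=kmo_statistic(Z), bartlett_statistic=float(statistic),
                          bartlett_dof=int(dof), bartlett_p=pval)


def varimax_criterion(L: np.ndarray, normalize: bool = True) -> float:
    """Sum over components of the variance of squared (row-normalized) loadings."""
    L = np.asarray(L, dtype=float)
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(loadings: np.ndarray, max_iter: int = 1000,
                   tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser normalization.

    Returns ``(rotated, T)`` with ``rotated = loadings @ T`` and T
    orthogonal.  Columns are sign-flipped so the largest-|loading|
    variable of each component loads positively, then ordered by
    explained variance.  A single component is returned unchanged.
    """
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L.copy(), np.eye(m)

    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    T = np.eye(m)
    obj_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        G = A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(G)
        T = U @ Vt
        obj = s.sum()
        if obj_old > 0 and (obj - obj_old) < tol * obj:
            break
        obj_old = obj

    R = (A @ T) * h[:, None]
    # sign convention: dominant variable of each component loads positively
    flips = np.sign(R[np.argmax(np.abs(R), axis=0), np.arange(m)])
    flips[flips == 0] = 1.0
    R = R * flips
    T = T * flips
    # order by explained variance, descending
    order = np.argsort(-(R**2).sum(axis=0), kind="stable")
    return R[:, order], T[:, order]


def fit_pca(Z, threshold: float = 0.85, columns=None, rotate: bool = True) -> PCAModel:
    """Eigendecompose the correlation matrix and select components.

    The smallest m whose cumulative variance proportion reaches
    ``threshold`` is retained; loadings are eigenvectors scaled by
    sqrt(eigenvalue) so each entry is a variable-component correlation.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(Z, pd.DataFrame):
        columns = columns or list(Z.columns)
        Z = Z.to_numpy(dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if n <= p:
        raise ValueError("need more records than variables")
    cols = tuple(columns) if columns is not None else tuple(f"x{i}" for i in range(p))

    means = Z.mean(axis=0)
    sds = Z.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [cols[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance column(s): {bad}")
    Zs = (Z - means) / sds

    R = (Zs.T @ Zs) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic eigenvector sign: largest-|entry| positive
    flips = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(p)])
    flips[flips == 0] = 1.0
    eigvecs = eigvecs * flips

    proportions = eigvals / eigvals.sum()
    cumulative = np.cumsum(proportions)
    m = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    m = min(m, p)

    loadings = eigvecs[:, :m] * np.sqrt(eigvals[:m])
    if rotate and m >= 2:
        rotated, T = varimax_rotate(loadings)
    else:
        rotated, T = loadings.copy(), np.eye(m)

    # standardized scores: Zs V_m diag(1/sqrt(lambda)) T  -> identity covariance
    std_scores = Zs @ eigvecs[:, :m] / np.sqrt(eigvals[:m])
    scores = std_scores @ T

    return PCAModel(columns=cols, means=means, sds=sds, eigenvalues=eigvals,
                    eigenvectors=eigvecs, proportions=proportions,
                    cumulative=cumulative, n_selected=m, loadings=loadings,
                    rotation=T, rotated_loadings=rotated, scores=scores)


def compute_scores(model: PCAModel, Z, rotated: bool = True,
                   standardized: bool = True) -> np.ndarray:
    """Project (already standardized) data onto the selected components.

    With ``rotated`` and ``standardized`` (the defaults, used as
    regressors downstream) scores have identity covariance on the fit
    sample.  Unrotated, unstandardized scores have variance equal to
    the eigenvalues and are exactly uncorrelated.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != len(model.columns):
        raise ValueError(f"expected {len(model.columns)} columns, got {Z.shape[1]}")
    m = model.n_selected
    V = model.eigenvectors[:, :m]
    raw = Z @ V
    if standardized:
        raw = raw / np.sqrt(model.eigenvalues[:m])
    return raw @ model.rotation if rotated else raw


def label_components(rotated_loadings: np.ndarray, columns, groups: dict,
                     threshold: float = 0.7) -> list[dict]:
    """Name each component after the variable group dominating it.

    A variable belongs to a component when its |rotated loading| is at
    least ``threshold``; the component takes the group label holding the
    majority of those variables, or "unlabeled" when none qualify.
    """
    R = np.asarray(rotated_loadings, dtype=float)
    columns = list(columns)
    var_group = {v: g for g, vs in groups.items() for v in vs}
    out = []
    for j in range(R.shape[1]):
        hits = [columns[i] for i in np.flatnonzero(np.abs(R[:, j]) >= threshold)]
        counts: dict[str, int] = {}
        for v in hits:
            g = var_group.get(v)
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        label = max(counts, key=counts.get) if counts else "unlabeled"
        out.append({"component": f"PC{j + 1}", "label": label, "variables": hits})
    return out
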