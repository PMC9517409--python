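"""Distance metrics, kernel weight functions and adaptive bandwidths.

Local regression weights observations by their separation from a focal
observation.  Purely spatial separation gives geographically weighted
regression (GWR), purely temporal separation gives temporally weighted
regression (TWR), and a scaled combination

    d_ST^2 = lambda * d_S^2 + mu * d_T^2

gives the spatio-temporal (GTWR) metric.  Two kernel families are
provided: the compact-support bisquare ``(1 - (d/h)^2)^2`` and the
Gaussian ``exp(-d^2/h^2)``; the latter factorises over space and time,
``exp(-d_ST^2/h_ST^2) = exp(-d_S^2/h_S^2) * exp(-d_T^2/h_T^2)`` when the
bandwidths are tied to the scaling factors.

Bandwidths are adaptive by default: ``h_i`` is the distance from the
focal observation to its k-th nearest neighbour, so kernel support
shrinks where stations are dense and widens where they are sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088

KERNEL_FAMILIES = ("bisquare", "gaussian")
COORDINATE_MODES = ("planar", "sphere")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus bandwidth rule for one local-model fit.

    Parameters
    ----------
    family : {"bisquare", "gaussian"}
    adaptive : bool
        If True, ``neighbors`` is the neighbour count k and the
        bandwidth is the k-th nearest-neighbour distance per focal
        point; if False, ``bandwidth`` is a fixed scale shared by all
        points.
    neighbors : int, optional
    bandwidth : float, optional
    """

    family: str = "bisquare"
    adaptive: bool = True
    neighbors: int | None = None
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.adaptive:
            if self.neighbors is None or self.neighbors < 1:
                raise ValueError("adaptive kernel requires neighbors >= 1")
        else:
            if self.bandwidth is None or self.bandwidth <= 0:
                raise ValueError("fixed kernel requires bandwidth > 0")


@dataclass(frozen=True)
class STDistanceParams:
    """Scaling of the combined space-time metric.

    ``lambda_scale`` multiplies squared spatial distance and
    ``mu_scale`` squared temporal distance (days).  Setting ``mu_scale``
    to 0 recovers the purely spatial metric, ``lambda_scale = 0`` the
    purely temporal one; both zero is degenerate.
    """

    lambda_scale: float = 1.0
    mu_scale: float = 1.0
    coordinate_mode: str = "planar"

    def __post_init__(self) -> None:
        if self.lambda_scale < 0 or self.mu_scale < 0:
            raise ValueError("scaling factors must be non-negative")
        if self.lambda_scale == 0 and self.mu_scale == 0:
            raise ValueError("lambda_scale and mu_scale cannot both be zero")
        if self.coordinate_mode not in COORDINATE_MODES:
            raise ValueError(f"unknown coordinate mode {self.coordinate_mode!r}")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in kilometres between points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def spatial_distance(a, b, mode: str = "planar"):
    """Distance between coordinate pairs ``a = (u, v)`` and ``b``.

    ``planar`` treats coordinates as Euclidean; ``sphere`` treats them
    as (longitude, latitude) degrees and returns great-circle km.
    Broadcasts over array inputs.
    """
    au, av = np.asarray(a[0], dtype=float), np.asarray(a[1], dtype=float)
    bu, bv = np.asarray(b[0], dtype=float), np.asarray(b[1], dtype=float)
    if not (np.all(np.isfinite(au)) and np.all(np.isfinite(av))
            and np.all(np.isfinite(bu)) and np.all(np.isfinite(bv))):
        raise ValueError("coordinates must be finite")
    if mode == "planar":
        return np.hypot(au - bu, av - bv)
    if mode == "sphere":
        return haversine_km(au, av, bu, bv)
    raise ValueError(f"unknown coordinate mode {mode!r}")


def temporal_distance(t_i, t_j, mu_scale: float = 1.0):
    """Scaled temporal separation ``sqrt(mu) * |t_i - t_j|``."""
    if mu_scale < 0:
        raise ValueError("mu_scale must be non-negative")
    return np.sqrt(mu_scale) * np.abs(np.asarray(t_i, dtype=float) - np.asarray(t_j, dtype=float))


def st_distance(a, b, params: STDistanceParams):
    """Combined space-time distance between ``(u, v, t)`` triples."""
    d_s = spatial_distance((a[0], a[1]), (b[0], b[1]), params.coordinate_mode)
    d_t = np.abs(np.asarray(a[2], dtype=float) - np.asarray(b[2], dtype=float))
    return np.sqrt(params.lambda_scale * d_s**2 + params.mu_scale * d_t**2)


def bisquare_weight(d, h):
    """Compact-support bisquare weight ``(1 - (d/h)^2)^2`` for d < h, else 0."""
    if np.any(np.asarray(h) <= 0):
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    u = d / h
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w if w.ndim else float(w)


def gaussian_weight(d, h):
    """Gaussian distance-decay weight ``exp(-(d/h)^2)``; strictly positive."""
    if np.any(np.asarray(h) <= 0):
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    w = np.exp(-((d / h) ** 2))
    return w if w.ndim else float(w)


def gaussian_st_weight(d_s, d_t, h_s, h_t):
    """Product of spatial and temporal Gaussian kernels.

    Equal to the single-kernel form exp(-d_ST^2 / h_ST^2) when the
    combined metric uses lambda = (h_ST/h_S)^2 and mu = (h_ST/h_T)^2.
    """
    if h_s <= 0 or h_t <= 0:
        raise ValueError("bandwidths must be positive")
    d_s = np.asarray(d_s, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    w = np.exp(-((d_s / h_s) ** 2)) * np.exp(-((d_t / h_t) ** 2))
    return w if w.ndim else float(w)


def kernel_weight(d, h, family: str):
    if family == "bisquare":
        return bisquare_weight(d, h)
    if family == "gaussian":
        return gaussian_weight(d, h)
    raise ValueError(f"unknown kernel family {family!r}")


def adaptive_bandwidth(distances_from_i, k: int) -> float:
    """Distance to the k-th nearest of the other points.

    ``distances_from_i`` excludes the focal point itself.  Ties are
    handled naturally by the order statistic: equidistant points share
    the common k-th distance.
    """
    d = np.asarray(distances_from_i, dtype=float)
    n = d.size
    if not 1 <= k <= n:
        raise ValueError(f"neighbor count k={k} out of range [1, {n}]")
    return float(np.partition(d, k - 1)[k - 1])
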