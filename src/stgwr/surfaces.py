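"""Spatial and temporal products of the local fits.

Per-station local coefficients are interpolated onto a regular
longitude/latitude grid by inverse distance weighting (IDW), a convex
combination with weights d^(-power), so interpolated values never leave
the range of the station values and coincide with them at the stations.
Temporal products are cross-station mean coefficient series and annual
mean concentration maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import LocalFit


@dataclass(frozen=True)
class GridSpec:
    bounds: tuple  # (lon_min, lon_max, lat_min, lat_max)
    nx: int = 50
    ny: int = 50

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        lon_min, lon_max, lat_min, lat_max = self.bounds
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError(f"degenerate bounds {self.bounds}")
        return (np.linspace(lon_min, lon_max, self.nx),
                np.linspace(lat_min, lat_max, self.ny))


@dataclass(frozen=True)
class CoefficientSurface:
    label: str
    grid_lon: np.ndarray     # nx
    grid_lat: np.ndarray     # ny
    values: np.ndarray       # ny x nx
    bounds: tuple

    def to_frame(self) -> pd.DataFrame:
        lon, lat = np.meshgrid(self.grid_lon, self.grid_lat)
        return pd.DataFrame({"lon": lon.ravel(), "lat": lat.ravel(),
                             "value": self.values.ravel()})


def idw_interpolate(points: np.ndarray, values: np.ndarray, grid: GridSpec,
                    power: float = 2.0, label: str = "value",
                    snap_tol: float = 1e-9) -> CoefficientSurface:
    """Inverse-distance-weighted surface from scattered (lon, lat) values.

    A grid cell within ``snap_tol`` of a data point takes that point's
    value exactly.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array of lon/lat")
    if len(vals) != len(pts):
        raise ValueError("values must align with points")
    if power <= 0:
        raise ValueError("power must be positive")
    glon, glat = grid.axes()
    lon, lat = np.meshgrid(glon, glat)
    cells = np.column_stack([lon.ravel(), lat.ravel()])
    d = np.hypot(cells[:, None, 0] - pts[None, :, 0],
                 cells[:, None, 1] - pts[None, :, 1])
    out = np.empty(len(cells))
    exact = d < snap_tol
    has_exact = exact.any(axis=1)
    for i in np.flatnonzero(has_exact):
        out[i] = vals[np.argmax(exact[i])]
    rest = ~has_exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w @ vals) / w.sum(axis=1)
    return CoefficientSurface(label=label, grid_lon=glon, grid_lat=glat,
                              values=out.reshape(lat.shape), bounds=grid.bounds)


def _station_coefficients(frame: pd.DataFrame, regressor: str,
                          epoch=None) -> pd.DataFrame:
    """Per-station mean of one coefficient over the selected epoch."""
    if regressor not in frame.columns:
        raise KeyError(f"unknown regressor {regressor!r}")
    df = frame
    if epoch is not None:
        lo, hi = epoch
        df = df[(df["time"] >= lo) & (df["time"] <= hi)]
        if df.empty:
            raise ValueError(f"no observations in epoch {epoch}")
    return (df.groupby("station_id", sort=True)
              .agg(lon=("lon", "first"), lat=("lat", "first"),
                   value=(regressor, "mean"))
              .reset_index())


def coefficient_surface(fit: LocalFit, regressor: str, grid: GridSpec,
                        epoch=None, power: float = 2.0) -> CoefficientSurface:
    """IDW map of one local coefficient, station-averaged over an epoch.

    ``epoch`` is an optional (t_min, t_max) window in panel time units;
    by default coefficients are averaged over all time points.
    """
    if fit.family == "OLS":
        raise ValueError("coefficient surfaces are for local families")
    frame = fit.to_frame()
    if "station_id" not in frame.columns:
        raise ValueError("fit carries no station identifiers")
    per_station = _station_coefficients(frame, regressor, epoch)
    return idw_interpolate(per_station[["lon", "lat"]].to_numpy(),
                           per_station["value"].to_numpy(), grid,
                           power=power, label=regressor)


def temporal_series(fit: LocalFit) -> pd.DataFrame:
    """Cross-station mean local coefficient at each distinct time point.

    Only meaningful for families whose coefficients vary in time
    (TWR/GTWR); GWR and OLS coefficients are constant in time by
    construction and are rejected.
    """
    if fit.family not in ("TWR", "GTWR"):
        raise ValueError(f"temporal series undefined for family {fit.family}")
    frame = fit.to_frame()
    return (frame.groupby("time", sort=True)[list(fit.names)]
                 .mean()
                 .reset_index())


def heating_season_mask(time_days: np.ndarray, origin_month: int = 1,
                        period_days: float = 365.25) -> np.ndarray:
    """True where a record falls in the October-April heating season.

    ``time_days`` counts days from an origin falling in ``origin_month``
    (default January).
    """
    elapsed = np.floor((np.asarray(time_days, dtype=float) % period_days)
                       / period_days * 12)
    month = (elapsed + origin_month - 1) % 12 + 1
    return (month >= 10) | (month <= 4)


def annual_mean_map(panel: pd.DataFrame, response: str, grid: GridSpec,
                    year: int | None = None, power: float = 2.0,
                    period_days: float = 365.25):
    """Annual mean concentration surface plus the regional annual series.

    Years are indexed from the panel time origin (year 0 covers days
    [0, period)).  Returns ``(surface, annual_series)`` where the
    surface maps per-station means for the selected year (all years
    pooled when ``year`` is None) and the series holds the regional
    mean per year.
    """
    if response not in panel.columns:
        raise KeyError(f"unknown response {response!r}")
    df = panel.copy()
    df["year"] = np.floor(df["time"].to_numpy(dtype=float) / period_days).astype(int)
    annual = (df.groupby("year", sort=True)[response].mean()
                .rename("regional_mean").reset_index())
    sel = df if year is None else df[df["year"] == year]
    if sel.empty:
        raise ValueError(f"no records for year {year}")
    per_station = (sel.groupby("station_id", sort=True)
                      .agg(lon=("lon", "first"), lat=("lat", "first"),
                           value=(response, "mean"))
                      .reset_index())
    surface = idw_interpolate(per_station[["lon", "lat"]].to_numpy(),
                              per_station["value"].to_numpy(), grid,
                              power=power, label=response)
    return surface, annual
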