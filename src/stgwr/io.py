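"""CSV / GeoJSON / YAML input-output with schema validation.

Panels travel as long-format CSV with the canonical column names
(station_id, lon, lat, time, the 20 covariate abbreviations, pm25,
pm10).  Surfaces are written both as CSV and as GeoJSON point features
with a ``value`` property.  Writes are round-trip lossless at full
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pca import PCAModel
from .surfaces import CoefficientSurface
from .synthetic import COVARIATE_COLUMNS

KEY_COLUMNS = ["station_id", "lon", "lat", "time"]
RESPONSE_COLUMNS = ["pm25", "pm10"]

#: canonical order used by the CSV writer
PANEL_COLUMNS = KEY_COLUMNS + COVARIATE_COLUMNS + RESPONSE_COLUMNS

#: maps the published abbreviations (PM2.5, PM10, SO2, ...) onto file columns
RESPONSE_ALIASES = {"PM2.5": "pm25", "PM10": "pm10"}


def read_panel_csv(path, require_responses: bool = False,
                   require_covariates: bool = True) -> pd.DataFrame:
    """Load and validate a long-format station panel.

    Checks required columns, missing values in modelled columns,
    non-negative PM, and uniqueness of (station_id, time); errors name
    the offending column or row index.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=RESPONSE_ALIASES)
    required = list(KEY_COLUMNS)
    if require_covariates:
        required += COVARIATE_COLUMNS
    if require_responses:
        required += RESPONSE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    check_cols = [c for c in required if c != "station_id"]
    check_cols += [c for c in RESPONSE_COLUMNS if c in df.columns and c not in check_cols]
    for col in check_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(f"column {col!r}: unparseable or missing value at row {bad[0]}")
        df[col] = vals
    for col in RESPONSE_COLUMNS:
        if col in df.columns and (df[col] < 0).any():
            row = int(np.flatnonzero(df[col].to_numpy() < 0)[0])
            raise ValueError(f"column {col!r}: negative concentration at row {row}")
    dup = df.duplicated(subset=["station_id", "time"])
    if dup.any():
        raise ValueError(f"duplicate (station_id, time) pair at row {int(np.flatnonzero(dup)[0])}")
    return df


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    """Write a panel using the published abbreviations (PM2.5, PM10, ...)."""
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    cols += [c for c in panel.columns if c not in cols]
    inverse = {v: k for k, v in RESPONSE_ALIASES.items()}
    panel[cols].rename(columns=inverse).to_csv(path, index=False, float_format="%.17g")


def write_loadings_csv(model: PCAModel, path, rotated: bool = True) -> None:
    """Loading table: variables in rows, selected components in columns."""
    L = model.rotated_loadings if rotated else model.loadings
    out = pd.DataFrame(L, index=list(model.columns), columns=model.component_names)
    out.index.name = "variable"
    out.to_csv(path, float_format="%.17g")


def write_adequacy_csv(report, path) -> None:
    pd.DataFrame([{
        "KMO": report.kmo,
        "bartlett_statistic": report.bartlett_statistic,
        "bartlett_dof": report.bartlett_dof,
        "bartlett_p": report.bartlett_p,
    }]).to_csv(path, index=False, float_format="%.17g")


def write_scores_csv(panel: pd.DataFrame, scores: np.ndarray, path,
                     names=None) -> None:
    names = list(names) if names is not None else [f"PC{i+1}" for i in range(scores.shape[1])]
    out = panel[KEY_COLUMNS].copy()
    for j, name in enumerate(names):
        out[name] = scores[:, j]
    out.to_csv(path, index=False, float_format="%.17g")


def read_scores_csv(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    score_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    if not score_cols:
        raise ValueError("no score columns found")
    return df, df[score_cols].to_numpy(dtype=float), score_cols


def write_surface_csv(surface: CoefficientSurface, path) -> None:
    surface.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_surface_geojson(surface: CoefficientSurface, path) -> None:
    """Grid cells as GeoJSON point features with a ``value`` property."""
    frame = surface.to_frame()
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [row.lon, row.lat]},
        "properties": {"value": row.value, "label": surface.label},
    } for row in frame.itertuples()]
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj))


def read_surface_geojson(path) -> pd.DataFrame:
    obj = json.loads(Path(path).read_text())
    rows = [{"lon": f["geometry"]["coordinates"][0],
             "lat": f["geometry"]["coordinates"][1],
             "value": f["properties"]["value"]} for f in obj["features"]]
    return pd.DataFrame(rows)


def read_config(path) -> dict:
    """Key-value configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key-value mapping")
    return cfg
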