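import json

import numpy as np
import pandas as pd
import pytest

from stgwr import io as stio
from stgwr.kernels import KernelSpec
from stgwr.models import fit_model
from stgwr.surfaces import (GridSpec, annual_mean_map, coefficient_surface,
                            heating_season_mask, idw_interpolate,
                            temporal_series)
from stgwr.synthetic import (generate_coefficient_surfaces,
                             generate_covariate_panel, generate_pm_response,
                             generate_station_network, simulate_study_panel)

UNIT_GRID = GridSpec(bounds=(0.0, 1.0, 0.0, 1.0), nx=12, ny=10)


def _local_fit(rng, preset="constant", n_stations=12, n_periods=15,
               family="GTWR", **truth_kwargs):
    st = generate_station_network(n_stations, (0, 1, 0, 1), seed=21)
    lon = np.repeat(st["lon"].to_numpy(), n_periods)
    lat = np.repeat(st["lat"].to_numpy(), n_periods)
    t = np.tile(7.0 * np.arange(n_periods, dtype=float), n_stations)
    n = len(lon)
    X = rng.standard_normal((n, 2))
    truth_kwargs.setdefault("base", (40.0, -5.0, 4.0))
    truth_kwargs.setdefault("bounds", (0.0, 1.0, 0.0, 1.0))
    truth_kwargs.setdefault("noise_sd", 0.0)
    truth = generate_coefficient_surfaces(preset, **truth_kwargs)
    betas = truth.evaluate(lon, lat, t)
    y = betas[:, 0] + np.einsum("ij,ij->i", betas[:, 1:], X)
    if truth.noise_sd > 0:
        y = y + rng.normal(0, truth.noise_sd, n)
    fit = fit_model(lon, lat, t, X, y, family,
                    kernel=KernelSpec(family="gaussian", adaptive=True,
                                      neighbors=max(20, n // 8)),
                    station_id=np.repeat(st["station_id"].to_numpy(), n_periods))
    return fit, truth


class TestIDW:
    def test_single_point_fills_surface(self):
        surf = idw_interpolate(np.array([[0.5, 0.5]]), np.array([7.0]), UNIT_GRID)
        assert np.allclose(surf.values, 7.0)

    def test_equidistant_cell_averages(self):
        grid = GridSpec(bounds=(-1.0, 1.0, -1.0, 1.0), nx=3, ny=3)
        surf = idw_interpolate(np.array([[-1.0, 0.0], [1.0, 0.0]]),
                               np.array([0.0, 10.0]), grid)
        centre = surf.values[1, 1]  # cell at (0, 0)
        assert centre == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(0, 1, (7, 2))
        vals = rng.normal(size=7)
        surf = idw_interpolate(pts, vals, UNIT_GRID, power=2.0)
        glon, glat = UNIT_GRID.axes()
        for iy in range(0, UNIT_GRID.ny, 3):
            for ix in range(0, UNIT_GRID.nx, 4):
                num = den = 0.0
                for (px, py), v in zip(pts, vals):
                    d = np.hypot(glon[ix] - px, glat[iy] - py)
                    num += v / d**2
                    den += 1.0 / d**2
                assert surf.values[iy, ix] == pytest.approx(num / den, abs=1e-10)

    def test_exact_at_data_sites_and_bounded(self, rng):
        glon, glat = UNIT_GRID.axes()
        pts = np.array([[glon[2], glat[3]], [glon[8], glat[6]]])
        vals = np.array([-4.0, 9.0])
        surf = idw_interpolate(pts, vals, UNIT_GRID)
        assert surf.values[3, 2] == -4.0
        assert surf.values[6, 8] == 9.0
        assert surf.values.min() >= vals.min() - 1e-12
        assert surf.values.max() <= vals.max() + 1e-12

    def test_empty_points_error(self):
        with pytest.raises(ValueError):
            idw_interpolate(np.empty((0, 2)), np.empty(0), UNIT_GRID)

    def test_nonpositive_power_error(self):
        with pytest.raises(ValueError, match="power"):
            idw_interpolate(np.array([[0.5, 0.5]]), np.array([1.0]),
                            UNIT_GRID, power=0.0)


class TestCoefficientSurface:
    def test_constant_truth_gives_flat_surface(self, rng):
        fit, _ = _local_fit(rng, "constant")
        surf = coefficient_surface(fit, "intercept", UNIT_GRID)
        assert np.allclose(surf.values, 40.0, atol=1e-6)
        assert surf.bounds == UNIT_GRID.bounds

    def test_space_gradient_recovered(self, rng):
        fit, truth = _local_fit(rng, "space-only", n_stations=25, n_periods=20,
                                space_amp=(10.0, -4.0, 3.0), noise_sd=1.0,
                                family="GWR")
        surf = coefficient_surface(fit, "intercept", UNIT_GRID)
        glon, glat = UNIT_GRID.axes()
        lon_mesh, lat_mesh = np.meshgrid(glon, glat)
        true_field = truth.evaluate(lon_mesh.ravel(), lat_mesh.ravel(),
                                    np.zeros(lon_mesh.size))[:, 0]
        r = np.corrcoef(surf.values.ravel(), true_field)[0, 1]
        assert r > 0.9

    def test_unknown_regressor_error(self, rng):
        fit, _ = _local_fit(rng, "constant")
        with pytest.raises(KeyError, match="PC9"):
            coefficient_surface(fit, "PC9", UNIT_GRID)

    def test_epoch_selection(self, rng):
        fit, _ = _local_fit(rng, "constant")
        surf = coefficient_surface(fit, "intercept", UNIT_GRID, epoch=(0.0, 35.0))
        assert np.allclose(surf.values, 40.0, atol=1e-6)
        with pytest.raises(ValueError, match="epoch"):
            coefficient_surface(fit, "intercept", UNIT_GRID, epoch=(1e6, 2e6))

    def test_ols_rejected(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.normal(size=40)
        st = generate_station_network(8, (0, 1, 0, 1), seed=2)
        fit = fit_model(np.repeat(st["lon"], 5), np.repeat(st["lat"], 5),
                        np.tile(np.arange(5.0), 8), X, y, "OLS")
        with pytest.raises(ValueError, match="local"):
            coefficient_surface(fit, "intercept", UNIT_GRID)


class TestTemporalSeries:
    def test_constant_truth_gives_flat_series(self, rng):
        fit, _ = _local_fit(rng, "constant")
        series = temporal_series(fit)
        assert len(series) == 15
        assert np.allclose(series["intercept"], 40.0, atol=1e-6)

    def test_sinusoidal_truth_peaks_at_generating_period(self, rng):
        period = 182.0   # half-year cycle; the panel spans two full cycles
        fit, _ = _local_fit(rng, "time-only", n_stations=15, n_periods=52,
                            time_amp=(12.0, -4.0, 3.0), noise_sd=1.0,
                            family="TWR", period_days=period)
        series = temporal_series(fit)
        sig = series["intercept"].to_numpy() - series["intercept"].mean()
        power = np.abs(np.fft.rfft(sig)) ** 2
        freqs = np.fft.rfftfreq(len(sig), d=7.0)
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(1.0 / period, rel=0.35)

    def test_series_length_is_number_of_distinct_times(self, rng):
        fit, _ = _local_fit(rng, "constant", n_periods=9)
        assert len(temporal_series(fit)) == 9

    def test_gwr_rejected(self, rng):
        fit, _ = _local_fit(rng, "constant", family="GWR")
        with pytest.raises(ValueError, match="undefined"):
            temporal_series(fit)


class TestAnnualMeanMap:
    @staticmethod
    def _pm_panel(rng, n_stations=10, n_periods=60):
        st = generate_station_network(n_stations, (0, 1, 0, 1), seed=13)
        panel = generate_covariate_panel(st, n_periods, seed=14)
        X = rng.standard_normal((len(panel), 2))
        truth = generate_coefficient_surfaces("constant", base=(50.0, 2.0, -1.0),
                                              noise_sd=3.0)
        return generate_pm_response(panel, X, truth, seed=15)

    def test_per_station_means_match_groupby_oracle(self, rng):
        panel = self._pm_panel(rng)
        # grid whose lower-left corner sits exactly on one station, so the
        # surface there equals that station's annual mean (IDW exactness)
        first = panel.iloc[0]
        grid = GridSpec(bounds=(first["lon"], 1.5, first["lat"], 1.5), nx=4, ny=4)
        surf, annual = annual_mean_map(panel, "pm25", grid, year=0)
        sel = panel[panel["time"] < 365.25]
        oracle = sel[sel["station_id"] == first["station_id"]]["pm25"].mean()
        assert surf.values[0, 0] == pytest.approx(oracle, abs=1e-12)
        expected_regional = panel.assign(
            year=np.floor(panel["time"] / 365.25).astype(int)
        ).groupby("year")["pm25"].mean()
        np.testing.assert_allclose(annual["regional_mean"].to_numpy(),
                                   expected_regional.to_numpy(), atol=1e-12)

    def test_doubling_second_year_doubles_its_regional_mean(self, rng):
        panel = self._pm_panel(rng)
        grid = GridSpec(bounds=(0.0, 1.0, 0.0, 1.0), nx=4, ny=4)
        _, base = annual_mean_map(panel, "pm25", grid)
        doubled = panel.copy()
        mask = doubled["time"] >= 365.25
        doubled.loc[mask, "pm25"] *= 2.0
        _, out = annual_mean_map(doubled, "pm25", grid)
        assert out.loc[1, "regional_mean"] == pytest.approx(
            2.0 * base.loc[1, "regional_mean"])
        assert out.loc[0, "regional_mean"] == pytest.approx(
            base.loc[0, "regional_mean"])

    def test_constant_panel_is_flat(self, rng):
        panel = self._pm_panel(rng)
        panel["pm25"] = 33.0
        grid = GridSpec(bounds=(0.0, 1.0, 0.0, 1.0), nx=4, ny=4)
        surf, annual = annual_mean_map(panel, "pm25", grid)
        assert np.allclose(surf.values, 33.0)
        assert np.allclose(annual["regional_mean"], 33.0)

    def test_empty_selection_error(self, rng):
        panel = self._pm_panel(rng)
        grid = GridSpec(bounds=(0.0, 1.0, 0.0, 1.0), nx=4, ny=4)
        with pytest.raises(ValueError, match="year"):
            annual_mean_map(panel, "pm25", grid, year=99)

    def test_heating_season_mask_cycles(self):
        t = np.array([0.0, 100.0, 200.0, 320.0])   # Jan, Apr, mid-Jul, late Nov
        mask = heating_season_mask(t)
        assert mask.tolist() == [True, True, False, True]


class TestIO:
    def test_panel_round_trip_lossless(self, tmp_path, rng):
        panel, *_ = simulate_study_panel(6, 8, seed=3)
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(panel, path)
        back = stio.read_panel_csv(path, require_responses=True)
        for col in panel.columns:
            np.testing.assert_allclose(back[col].to_numpy() if col != "station_id"
                                       else 0, panel[col].to_numpy() if col != "station_id"
                                       else 0, atol=0)
        assert (back["station_id"] == panel["station_id"]).all()

    def test_published_abbreviations_in_header(self, tmp_path):
        panel, *_ = simulate_study_panel(6, 8, seed=3)
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(panel, path)
        header = path.read_text().splitlines()[0].split(",")
        assert "PM2.5" in header and "PM10" in header
        assert {"SO2", "NO2", "CO", "O3", "NDVI", "MaxT", "AWS"} <= set(header)

    def test_missing_column_error_names_it(self, tmp_path):
        panel, *_ = simulate_study_panel(6, 8, seed=3)
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(panel.drop(columns=["lat"]), path)
        with pytest.raises(ValueError, match="lat"):
            stio.read_panel_csv(path)

    def test_duplicate_station_time_error(self, tmp_path):
        panel, *_ = simulate_study_panel(6, 8, seed=3)
        dup = pd.concat([panel, panel.iloc[[0]]], ignore_index=True)
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(dup, path)
        with pytest.raises(ValueError, match="duplicate"):
            stio.read_panel_csv(path)

    def test_unparseable_value_reports_row(self, tmp_path):
        panel, *_ = simulate_study_panel(6, 8, seed=3)
        panel.loc[2, "AT"] = np.nan
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(panel, path)
        with pytest.raises(ValueError, match="row 2"):
            stio.read_panel_csv(path)

    def test_study_scale_load_smoke(self, tmp_path):
        panel, *_ = simulate_study_panel(57, 104, seed=3)
        path = tmp_path / "panel.csv"
        stio.write_panel_csv(panel, path)
        back = stio.read_panel_csv(path, require_responses=True)
        assert len(back) == 5928

    def test_surface_geojson_round_trip(self, tmp_path, rng):
        surf = idw_interpolate(rng.uniform(0, 1, (5, 2)), rng.normal(size=5),
                               GridSpec(bounds=(0, 1, 0, 1), nx=4, ny=3))
        path = tmp_path / "surface.geojson"
        stio.write_surface_geojson(surf, path)
        obj = json.loads(path.read_text())
        assert obj["type"] == "FeatureCollection"
        back = stio.read_surface_geojson(path)
        np.testing.assert_allclose(np.sort(back["value"]),
                                   np.sort(surf.values.ravel()), atol=0)

    def test_config_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("noise_scale: 0.5\ncadence_days: 3.5\n")
        cfg = stio.read_config(path)
        assert cfg == {"noise_scale": 0.5, "cadence_days": 3.5}
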