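# stgwr

Principal-component-reduced global and locally weighted regression for
station-panel air-quality data.

Regional PM2.5/PM10 concentrations respond to a score of correlated
drivers — gaseous pollutants, temperature, wind, pressure, humidity,
vegetation cover — and the strength of each relationship drifts across
space and through the seasons. Regressing PM on twenty raw covariates is
hopeless (severe multicollinearity), and a single global fit hides the
spatiotemporal heterogeneity that air-quality managers actually care
about. `stgwr` implements the two-stage remedy: collapse the covariates
into a handful of interpretable, mutually orthogonal principal
components, then regress PM on the component scores with four nested
model families of increasing local flexibility.

## The model

Stage 1 — dimension reduction. The p = 20 covariates are standardized
and eigendecomposed via their correlation matrix. Components are kept up
to ≥ 85 % cumulative explained variance, varimax-rotated so that each
aligns with one physical variable block, and converted to standardized
scores X₁…X_m used as regressors. Sampling adequacy is screened with the
KMO statistic and Bartlett's sphericity test beforehand.

Stage 2 — regression. With scores X_ik and response Y_i at station
location (u_i, v_i) and time t_i:

- **OLS** (global): Y_i = β₀ + Σ_k β_k X_ik + ε_i, β̂ = (XᵀX)⁻¹XᵀY.
- **GWR**: β_k = β_k(u_i, v_i), estimated at every observation by
  weighted least squares, β̂(u_i,v_i) = (XᵀW_iX)⁻¹XᵀW_iY, with kernel
  weights decaying in spatial distance.
- **TWR**: β_k = β_k(t_i), weights decay in temporal distance
  √μ·|t_i − t_j|.
- **GTWR**: β_k = β_k(u_i, v_i, t_i), weights decay in the combined
  metric d²_ST = λ·d²_S + μ·d²_T.

Kernels are the compact-support bisquare (1 − (d/h)²)² or the Gaussian
exp(−d²/h²), with adaptive bandwidth h_i equal to the distance of the
k-th nearest neighbour. The neighbour count k (and the space–time ratio
τ = μ/λ for GTWR) is selected by minimizing the corrected Akaike
criterion

    AICc = 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S),

where S is the hat matrix and tr S the effective number of parameters;
leave-one-out cross-validation is available as an alternative. Models
are compared on AICc, adjusted R², RMSE and MAE, and local coefficients
are summarized (min/mean/max/SD/kurtosis/skewness), mapped by inverse
distance weighting, and traced through time as cross-station means.

Because the monitoring records this kind of study uses are rarely
redistributable, the package ships a first-class synthetic generator
that emulates the study design — 57 stations, ~104 dates, 20 covariates
in six correlated seasonal blocks — with PM drawn from *known* smooth
coefficient fields, so every stage is verifiable by parameter recovery.

## Worked example

```python
from stgwr import (simulate_study_panel, standardize, bartlett_sphericity,
                   label_components, fit_model, assess, KernelSpec,
                   STDistanceParams, BLOCKS, COVARIATE_COLUMNS)

panel, scores, truth, _, model = simulate_study_panel(
    n_stations=20, n_periods=40, seed=3, preset="space-time")

Z, _, _ = standardize(panel, COVARIATE_COLUMNS)
report = bartlett_sphericity(Z)
print(f"KMO = {report.kmo:.2f}")
print(f"components: {model.n_selected}, cumulative variance = "
      f"{model.cumulative[model.n_selected - 1]:.1%}")

y = panel["pm25"].to_numpy()
coords = (panel["lon"], panel["lat"], panel["time"])
ols = fit_model(*coords, scores, y, "OLS")
gtwr = fit_model(*coords, scores, y, "GTWR",
                 kernel=KernelSpec(family="gaussian", adaptive=True, neighbors=80),
                 st=STDistanceParams(lambda_scale=1.0, mu_scale=25.0,
                                     coordinate_mode="sphere"))
for fit in (ols, gtwr):
    a = assess(fit)
    print(f"{a.family}: Ra2 = {a.adjusted_r2:.2f}, AICc = {a.aicc:.1f}, "
          f"RMSE = {a.rmse:.2f}")
```

prints

```
KMO = 0.89
components: 6, cumulative variance = 86.9%
OLS: Ra2 = 0.60, AICc = 7001.6, RMSE = 19.05
GTWR: Ra2 = 0.86, AICc = 6217.7, RMSE = 10.93
```

The six rotated components label one-to-one as temperature, wind,
pressure, pollutants, humidity and vegetation blocks. Because the
response was generated with coefficients varying in both space and time,
the spatio-temporally weighted fit roughly halves the RMSE of the global
model and lifts adjusted R² from 0.60 to 0.86. With centered score
regressors the OLS intercept equals the PM2.5 sample mean exactly
(46.61 µg/m³ here) — a useful internal check.

The same pipeline is scriptable from the shell:

```bash
stgwr simulate --stations 57 --periods 104 --seed 1 --out panel.csv
stgwr pca --panel panel.csv --out-loadings loadings.csv --out-scores scores.csv
stgwr fit --panel panel.csv --scores scores.csv --family gtwr --auto --out coef.csv
stgwr assess --panel panel.csv --scores scores.csv --neighbors 300 --out table.csv
stgwr surface --coefficients coef.csv --regressor PC1 \
      --bounds 121,135,43,54 --out-csv pc1_map.csv --out-geojson pc1_map.geojson
stgwr series --coefficients coef.csv --out series.csv
```

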