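# Methods

## Model families and estimation

All four families share one estimator: at observation i the coefficient
vector solves the weighted normal equations
β̂_i = (XᵀW_iX)⁻¹XᵀW_iY with W_i diagonal. The families differ only in
the metric that generates the weights — none (OLS, all weights 1),
spatial (GWR), temporal (TWR), or the combined metric
d²_ST = λ·d²_S + μ·d²_T (GTWR). GWR and TWR are exact special cases of
GTWR (μ = 0 and λ = 0 respectively), and all three collapse to OLS as
the kernel flattens; the test suite asserts this reduction chain to
1e-8.

Local solves use a Cholesky factorization of XᵀW_iX (QR with column
pivoting for the global fit), never explicit inversion. A weighted
cross-product whose eigenvalue ratio exceeds 1e24 (condition number
above 1e12 for the weighted design) is treated as singular, and the
error names the failing observation and advises a larger neighbour
count. The focal observation keeps its own weight in its local fit
(standard practice); it is excluded only inside leave-one-out
cross-validation.

Spatial distances are great-circle kilometres (haversine) by default,
because a provincial station network spans ~14° of longitude and planar
degrees would distort the east–west scale; a planar mode is used for
unit-box simulations. Temporal distances are in days. λ and μ are
reparameterized as λ = 1 and a ratio τ = μ/λ searched on a log grid —
only the ratio affects adaptive-bandwidth fits.

### Kernels and bandwidths

Two kernels: bisquare (1 − (d/h)²)², exactly zero for d ≥ h, and
Gaussian exp(−d²/h²), strictly positive (down to floating-point
underflow at d/h ≈ 27). Defaults follow the study design: adaptive
bisquare for GWR, adaptive Gaussian for TWR/GTWR; both are available
for every family because the source design is ambiguous on this point.
The adaptive bandwidth h_i is the distance from observation i to its
k-th nearest other observation; for the Gaussian kernel it is used as
the scale with no truncation, which is the most common reading of
"adaptive Gaussian". With station panels many observations share a
location or a date, so small k can give h_i = 0 in the purely temporal
or purely spatial metric; this is raised as an error advising larger k
rather than silently regularized.

### Bandwidth selection

k (and τ for GTWR) minimizes AICc = 2n·ln σ̂ + n·ln 2π +
n(n + trS)/(n − 2 − trS), with σ̂ = √(RSS/n) and trS accumulated from
the hat rows x_iᵀ(XᵀW_iX)⁻¹XᵀW_i. The search is an exhaustive grid —
default 20 log-spaced k between p+2 and n−1 and 7 log-spaced τ between
1e-3 and 10 — with ties broken toward larger k (the smoother model).
Infeasible grid points (singular local fits, trS ≥ n−2) score +inf; an
all-infeasible grid is an error. A leave-one-out CV score
Σ(y_i − ŷ_{≠i})² is provided as an alternative criterion; only the
focal observation's weight is zeroed, not its whole station, which is
the standard CV definition for this model class.

## PCA stage

PCA is computed from the correlation matrix (standardized covariates,
ddof = 1) because the covariates mix hPa, °C, m/s and unitless indices;
covariance PCA would be dominated by pressure. Loadings are eigenvector
× √eigenvalue, i.e. variable–component correlations. Components are
retained up to the smallest m whose cumulative variance proportion
reaches the threshold (default 0.85).

Varimax rotation uses Kaiser normalization and the SVD-based ascent
iteration, stopping when the relative criterion change falls below
1e-10 or after 1000 sweeps; columns are sign-flipped so the
dominant variable of each component loads positively and re-ordered by
explained variance. Scores entering the regressions are rotated and
standardized: Z V_m diag(1/√λ) T, which has exactly identity covariance
on the fit sample. Centered unit-variance scores make the global
intercept equal the response mean and make slope magnitudes comparable
across components. Unrotated, unstandardized scores (variance λ_k,
exactly uncorrelated) remain available.

KMO is reported as the overall measure of sampling adequacy,
Σr²/(Σr² + Σq²) over off-diagonal simple correlations r and anti-image
partial correlations q computed from the inverse correlation matrix.
Bartlett's statistic is −(n − 1 − (2p+5)/6)·ln det R against χ² with
p(p−1)/2 degrees of freedom. Component labelling assigns each rotated
component to the variable block holding the majority of its
|loading| ≥ 0.7 variables, or "unlabeled".

## Synthetic data generator

The generator emulates a provincial monitoring network: ~57 stations
uniform in a 121–135°E × 43–54°N box, ~104 dates at a 7-day cadence
(optionally jittered), 20 covariates and PM2.5/PM10 responses. Covariates
are built from six latent block signals — temperature (six temperature
variables plus O₃ at a weaker loading of 0.6), wind (3 variables),
pressure (3), gaseous pollutants (3), humidity (3, sun hours loading
negatively), vegetation (NDVI) — then placed on realistic marginal
scales (hPa, °C, m/s, µg/m³).

Each latent is 45 % seasonal harmonic, 15 % station offset and 40 %
noise by variance. The six blocks take the first six orthogonal Fourier
harmonics of the annual cycle (sin/cos at one, two and three cycles per
year), so every covariate is strongly seasonal while blocks stay
near-uncorrelated — the property that makes PCA block recovery
assertable. Within-block correlations default to 0.93 for the
temperature block and 0.78 elsewhere; with these values the default
panel puts the cumulative explained variance of five components just
below 85 % and six components at ~86–87 %, so the threshold rule selects
exactly six interpretable components. A `noise_scale` of 0 makes blocks
perfectly collinear (the degenerate limit used in tests).

PM responses follow Y = β₀(u,v,t) + Σ β_k(u,v,t)X_k + N(0, σ) with
σ = 5 µg/m³ by default and known coefficient fields in four presets:
constant, space-only (east–west linear gradients), time-only (annual
sinusoids with staggered phases), space-time (sum of both). Default
amplitudes are smaller than the base values, so every field keeps a
fixed sign — the regime in which global and mean-local coefficient signs
agree. Negative PM draws are truncated at zero and counted; at the
default signal-to-noise level truncation is rare and does not
materially perturb the linear model.

What the generator does **not** emulate: spatially correlated noise
fields beyond the block structure, missing records, measurement-device
changes, or the skewed heavy-tailed marginals of real pollutant data
(covariates are Gaussian on their scale). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to real-data pathologies.

## Recovery benchmark

`stgwr.benchmark` fixes the study conditions used by the acceptance
script and the end-to-end tests: 30 stations × 50 weekly dates
(n = 1500), three standard-normal regressors, base coefficients
(40, −5, 4, 6), spatial amplitudes (8, −3, 2.5, 4), temporal amplitudes
(12, −4, 3, 5), noise 5 µg/m³. Responses are drawn directly from the
linear model (no zero-truncation) because the benchmark scores
estimator recovery. Bandwidths are AICc-selected on
k ∈ {40, 80, 160, 320, 640} and τ ∈ {0.1, 1, 10, 100}. These sizes keep
a full three-regime benchmark under a minute on one CPU while leaving
wide margins on the expected orderings: the matched family's
coefficient RMSE is typically 2–5× smaller than the mismatched ones.

## Surfaces and temporal products

Coefficient maps use inverse distance weighting with power 2 (the
power is configurable; the source design does not state one). IDW is a
convex combination, so surfaces never leave the range of the station
values and are exact at stations (cells within 1e-9 of a data point
snap to it). Per-station coefficients are averaged over all time points
by default before mapping; an epoch window (e.g. one season or year) is
selectable because the choice of mapping epoch is genuinely open.
Temporal series are cross-station means per time point and are defined
only for TWR/GTWR. A heating-season selector (October–April) supports
seasonal aggregation. Annual mean maps aggregate the response per
station and year (years indexed from the panel time origin).

## Degenerate inputs and numerical conventions

- Zero-variance covariate columns, singular correlation matrices,
  rank-deficient designs, over-parameterized fits (trS ≥ n − 2) and
  zero-variance responses are errors, with the offending column,
  observation or quantity named.
- Coefficient summaries use sample SD (ddof = 1), bias-corrected
  skewness and excess (Fisher) kurtosis — the convention under which
  near-uniform variables show negative kurtosis; constant columns get
  SD = 0 and NaN shape statistics.
- Eigenvector and rotation signs follow a deterministic
  largest-entry-positive convention so repeated runs are bit-identical.
- All random generation flows through `numpy.random.default_rng`
  seeded from explicit arguments; every generator is a pure function of
  its inputs.

## Known limitations

- The purely spatial distance in the source design is printed
  identically to the spatio-temporal metric; we implement spatial
  distance as plain Euclidean/great-circle and treat the combined form
  as belonging to GTWR only.
- MAE is computed exactly as Σ|y−ŷ|/n; no attempt is made to reproduce
  published MAE values that are inconsistent with their companion RMSE.
- No mixed/semiparametric GWR, oblique rotations, robust standard
  errors, spatial-autocorrelation tests, kriging, or hot-spot
  statistics; LOO CV is the only out-of-sample check.
- Grid-search bandwidth selection is exhaustive; no golden-section or
  gradient refinement, and no per-observation bandwidths.
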