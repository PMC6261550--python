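# Methods

This note records the statistical model behind `spatvax`, the conventions
and numerical choices the implementation commits to, what the synthetic
data generator does and does not emulate, and the known limitations.

## Spatial weights

Areal units are polygons with stable order; that order defines the row
order of every matrix and vector. First-order queen contiguity declares two
units neighbours when their boundaries come within a coordinate tolerance
`tol` (default 1e-9 layer units) of sharing a point — an edge or a single
vertex both count. The tolerance exists because census shapefiles contain
snapped but imperfect vertices; detection is by exact boundary distance
after a bounding-box prefilter, so it is O(n) in practice on district maps.
A rook builder (shared edge of positive length) exists for fixtures and for
the queen-⊇-rook sanity property; higher-order contiguity, distance-band
and k-nearest-neighbour weights are out of scope.

Units with no neighbour (islands) are kept as all-zero rows and reported
with a warning rather than dropped silently: real district maps contain
them (islands in the administrative sense too), and each downstream
statistic defines their handling explicitly — they contribute to means and
variances, their spatial lag is 0, they are never significant in LISA, and
they are excluded (with a warning) from the spatial-model estimation set.
Row standardization divides each non-island row by its sum, after which
`S0 = n − #islands` and the spatial lag is a neighbourhood average; the
operation is idempotent. Weights serialize to the GAL neighbour-list
format (binary form); the round trip is the identity on neighbour sets.

## Moran statistics and permutation inference

Global Moran's I is computed literally as `(n/S0)·z'Wz / z'z`, which is
well defined for binary and row-standardized weights alike (under row
standardization without islands the prefactor is 1). The bivariate
statistic correlates one variable with the spatial lag of another. Both
variables are z-standardized (population sd) before the bivariate statistic
is formed. This is a deliberate convention choice: the raw form with the
denominator in y alone is not invariant under separate positive affine
rescalings of x and y (it scales by the ratio of the two slopes), whereas
district indicators arrive in arbitrary percentage scalings; the
standardized form is the one desktop ESDA tools compute, reduces exactly to
the univariate statistic at y = x, and preserves the local-to-global
identity below.

Local statistics are `I_i = n·z_i·(Wz)_i / Σz²` (partner variable in the
lag for the bivariate case). For row-standardized weights they satisfy
`Σ_i I_i = n·I` exactly; the test suite asserts this to 1e-10 and checks
both global and local values against explicit double-loop oracles to 1e-12.

Inference is by permutation. Global statistics use full random relabelling
(for the bivariate case x stays at its locations and y is permuted — the
choice is documented here because the convention is not universal, and it
is seed-controlled). Local statistics use the standard conditional
scheme: unit i's own value is held fixed and the remaining n−1 values are
shuffled onto its neighbours. The pseudo-p is `(M+1)/(R+1)` with R
permutations (default 999) and M the permuted statistics at least as
extreme as the observed one — ties inclusive, one-sided toward the observed
direction (relative to `−1/(n−1)` globally, to the permutation mean
locally). Two consequences worth knowing:

* the smallest attainable pseudo-p is `1/(R+1)`, so a 0.001 significance
  tier requires R ≥ 999 and strict comparison `p < 0.001` requires more;
* because the tail is chosen after seeing the statistic's direction, a true
  null is rejected at roughly 2α, not α. The calibration tests budget for
  this; users comparing pseudo-p to α should know they are buying the
  desktop-ESDA convention, not an exact size-α test.

Cluster classification follows the Moran-scatterplot quadrants: significant
HH = hotspot, LL = coldspot, HL/LH = spatial outliers; `p = α` exactly is
*not* significant (strict inequality); zero deviations count as "low".
Significance tiers 0.05/0.01/0.001 are reported for the significance map.
No multiple-testing correction is applied across units, matching common
ESDA practice; the per-unit significant fraction under a null field is
therefore ≈ 2α, as the type-I property test documents. Quantile choropleth
classes use sample quantiles with ties sharing a class; heavily tied data
degrade gracefully with a warning.

## Regression chain

**OLS** is the baseline (`statsmodels` under the hood). Its log-likelihood
is the Gaussian likelihood at the ML variance `ε'ε/n`, so the AIC is
commensurable with the spatial models'.

**LM diagnostics** are the standard score tests built from OLS residuals:
with `T = tr(W'W + WW)`, `d_ρ = e'Wy/σ̂²`, `d_λ = e'We/σ̂²` and
`J = [(WXβ̂)'M(WXβ̂) + Tσ̂²]/σ̂²`,
`LM_lag = d_ρ²/J`, `LM_error = d_λ²/T`, robust variants
`(d_ρ−d_λ)²/(J−T)` and `(d_λ−TJ⁻¹d_ρ)²/(T−T²/J)`, all against χ²(1). The
published description of the workflow names these tests without printing
the forms; these are the canonical ones. Monte-Carlo calibration on an 8×8
lattice gives empirical size ≈ 0.048 (lag) and ≈ 0.039 (error) at the 5%
level — LM-error is mildly conservative at n = 64 (its null mean is ≈ 0.94
against the χ²(1) mean of 1) and converges to nominal size on larger
lattices.

**Spatial lag and error models** are estimated by maximum likelihood. The
log-Jacobian `ln|I − ρW|` is evaluated as `Σ ln(1 − ρω_i)` from the
eigenvalues ω of the row-standardized W; since W = D⁻¹A with A symmetric,
it is similar to the symmetric D^(−1/2)AD^(−1/2) and the spectrum is real
(computed once per weights object and cached). The feasible interval is
`(1/ω_min, 1/ω_max)`, shrunk by 1e-5 at each end. For a candidate spatial
parameter the coefficients and variance have closed forms — the SLM uses
the two auxiliary regressions of y and Wy on X, the SEM a spatially
filtered (GLS) regression of `y − λWy` on `X − λWX` — leaving a
one-dimensional concentrated likelihood maximized by bounded Brent search
with tolerance 1e-8. At ρ = 0 (or λ = 0) the concentrated likelihood
equals the OLS Gaussian likelihood to machine precision, a property the
tests assert.

Standard errors come from the numeric Hessian of the *full* log-likelihood
in (β, spatial parameter, σ²) at the optimum — central differences, step
`1e-5·(1+|θ|)` — inverted by pseudo-inverse; Wald z and normal p-values are
reported. Predicted values for the pseudo-R² are the reduced form
`(I − ρ̂W)⁻¹Xβ̂` for the SLM and `Xβ̂` for the SEM; the "fit" column
reported next to the spatial models is this squared correlation of y and
ŷ, because the classical adjusted R² is undefined for ML spatial models —
the two measures are not comparable across model families and are reported
for orientation only.

**AIC** is `2k − 2·loglik` with k = number of regression coefficients
(intercept included) plus one for the spatial parameter; σ² is excluded in
all three models. Conventions for k differ across packages; only relative
AIC matters here and consistency is what the comparison needs. Selection is
argmin with ties broken toward the simpler model in the order OLS, SLM,
SEM. Listwise deletion handles missing values before any statistic is
computed, and the weight structure is re-subset (dropped units vanish from
neighbour lists; rows are re-standardized); islands created by the deletion
are dropped from the whole analysis so all three models share one
estimation set.

## Synthetic data

The generator emulates the *structure* the analysis assumes, not any real
geography: `nrows × ncols` unit squares as pseudo-districts; nine predictor
columns drawn as independent Gaussians at the NFHS-4 national means (PNC
62.4, full ANC 21.0, institutional births 78.9, adequate diet 8.7, MCP
card 89.3, neonatal tetanus 89.0, JSY 36.4, schooling 10+ 35.7, insurance
28.7 percent), optionally smoothed once with W so bivariate statistics have
spatial signal (off for null tests); five outcome columns sharing slope
vector β with per-outcome intercepts chosen so expected outcomes hit the
NFHS-4 means (BCG 91.9, polio 72.8, DPT 78.4, measles 81.1, full
immunization 62.0). Outcomes follow
`y = (I−ρW)⁻¹(Xβ+ε)` (lag process) or `y = Xβ + (I−λW)⁻¹ζ` (error
process), ε, ζ ~ N(0, σ²) with σ = 10 percentage points by default — the
residual spread implied by district-level coverage regressions of this
kind. The default study condition is the error process at λ = 0.59, the
dependence strength a national-scale full-immunization error model
estimates.

Choices that matter:

* **Clipping, not transformation.** Values are clipped to [0, 100], keeping
  the linear model literally true away from the bounds. Predictor sds
  default to `min(15, mean/3, (100−mean)/3)` so clipping is rare and the
  calibrated means hold (verified to ±2 points in the tests). A logit-scale
  generator is deliberately out of scope.
* **Determinism.** One integer seed reproduces a dataset bit-exactly;
  written tables are rounded to 6 decimals so files are platform-stable.
* **Feasibility.** ρ/λ are validated against the eigenvalue interval of the
  concrete W before simulation.

What passing tests on this generator do **not** show: behaviour under
survey noise (NFHS factsheet values are themselves estimates with sampling
error), irregular district geometry and highly unequal neighbour counts,
spatially structured missingness, or joint dependence among predictors.
Results on real district tables inherit those caveats.

Calibration experiments use two predictors (means 50 and 40, sd 3) with
β = (1, 2) and σ = 1 on 20×20 lattices, sized so that a 50-seed recovery
experiment and the 500-replicate LM calibration run in seconds while
keeping the clipping bounds inactive. On a single small lattice (8×8) the
sampling spread of Moran's I for a λ = 0.5 error field is large (sd ≈ 0.11
around a mean ≈ 0.18), so individual small-grid draws can look
unremarkable; calibration claims are always about averages over seeds.

## Pipeline and reproducibility

The pipeline runs, per outcome: quantile classes → global Moran → LISA with
cluster/significance labelling → bivariate Moran against each predictor →
OLS → residual Moran + LM diagnostics → SLM and SEM → AIC selection, then
writes coefficient tables (CSV), model summaries (JSON), a bivariate Moran
matrix in "statistic (p)" cell format, and per-outcome GeoJSON with
quantile class, quadrant, pseudo-p, cluster label and significance tier.
The global seed expands into named substreams per (outcome, stage) via
`SeedSequence`, so adding an outcome never perturbs another outcome's
permutation draws; a rerun with the same config is byte-identical.

## Limitations

* Polygon input is GeoJSON (planar coordinates); geometry is not validated
  or repaired, and spherical geometry is not handled.
* Spatial Durbin / combined SAC models, GM/IV estimators,
  heteroskedasticity-robust inference and Bayesian estimation are out of
  scope; the eigenvalue log-determinant targets district-scale n (hundreds
  to a few thousand), not massive lattices.
* The LM tests' χ²(1) reference and the ML standard errors are asymptotic;
  on lattices below ~100 units both are approximate (the conservativeness
  measured above is the visible symptom).
* Bivariate Moran measures spatial cross-correlation, not causation, and
  inherits the in-sample correlation of x and y.
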