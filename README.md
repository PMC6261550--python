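# spatvax

District-level spatial analysis of immunization coverage.

Vaccination coverage is not spatially random: districts with low coverage of
BCG, polio, DPT or measles vaccination tend to neighbour other low-coverage
districts, and the maternal-health services that drive coverage (postnatal
care, institutional delivery, women's schooling, ...) cluster the same way.
`spatvax` implements the standard spatial-epidemiology toolchain for
percentage indicators on areal units (districts), for analysts who have a
polygon layer and a per-district attribute table and want defensible answers
to "where are the coldspots?" and "which district-level factors are
associated with coverage once spatial dependence is accounted for?".

## What it computes

Given a weight matrix **W** from first-order queen contiguity (districts are
neighbours when they share an edge or a vertex), row-standardized so the
spatial lag `(Wx)_i` is the neighbourhood average:

* **Global Moran's I** — `I = (n/S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²`, with
  `z = x − x̄`; expectation `−1/(n−1)` under spatial randomness; inference by
  random permutation, pseudo-p `(M+1)/(R+1)`.
* **Bivariate Moran's I** — the correlation between a predictor at a
  district and the spatial lag of the outcome around it (both variables
  z-standardized).
* **LISA** — the local decomposition `I_i = n · z_i · (Wz)_i / Σ z²`, with
  conditional-permutation pseudo-p per district and Moran-quadrant
  classification into High-High hotspots, Low-Low coldspots, and High-Low /
  Low-High spatial outliers, plus a 0.05/0.01/0.001 significance-tier map.
* **Spatial regression** — OLS `y = α + Xβ + ε` as the baseline; Moran's I
  of the residuals and Lagrange-multiplier score tests (LM-lag, LM-error,
  robust forms) for the type of dependence; maximum-likelihood spatial lag
  (`y = ρWy + Xβ + ε`) and spatial error (`y = Xβ + u, u = λWu + ζ`) models
  with the log-Jacobian `ln|I − ρW|` from the eigenvalues of W; AIC
  selection of the final model.
* **Synthetic data** — lattices of pseudo-districts with outcomes generated
  under known ρ/λ/β and indicator means calibrated to the NFHS-4 national
  district profile, so the whole chain is testable without any download.

## Worked example

Simulate a 20×20 lattice of pseudo-districts with spatial-error dependence
(λ = 0.59, the strength typical of full-immunization coverage at national
scale), then run the full pipeline on the files it writes:

```python
import tempfile, pathlib
import spatvax as sv

spec = sv.nfhs_like_defaults(nrows=20, ncols=20, seed=42)
layer = sv.generate_grid_layer(20, 20)
w = sv.row_standardize(sv.build_queen_weights(layer))
ds = sv.simulate_field(spec, w)

tmp = pathlib.Path(tempfile.mkdtemp())
sv.write_polygon_layer(ds.layer, tmp / "districts.geojson")
ds.attributes.to_csv(tmp / "indicators.csv")

cfg = sv.PipelineConfig(
    layer_path=str(tmp / "districts.geojson"),
    attributes_csv=str(tmp / "indicators.csv"),
    outcomes=["full_immunization"],
    permutations=999,
    seed=1,
)
rep = sv.run_pipeline(cfg).outcomes["full_immunization"]
print(f"global Moran's I = {rep.moran.statistic:.3f} (p_sim = {rep.moran.pseudo_p:.3f})")
print(f"hotspots = {rep.clusters['hotspots']}, coldspots = {rep.clusters['coldspots']}, "
      f"outliers = {rep.clusters['outliers']}")
print(f"rho (SLM) = {rep.slm.spatial_param:.3f}, lambda (SEM) = {rep.sem.spatial_param:.3f}")
print(f"AIC: OLS {rep.ols.aic:.1f}, SLM {rep.slm.aic:.1f}, SEM {rep.sem.aic:.1f} "
      f"-> selected {rep.comparison.selected}")
```

Output:

```
global Moran's I = 0.227 (p_sim = 0.001)
hotspots = 28, coldspots = 37, outliers = 15
rho (SLM) = 0.555, lambda (SEM) = 0.587
AIC: OLS 3034.4, SLM 2978.9, SEM 2973.3 -> selected SEM
```

Coverage clusters strongly (I = 0.227, far above the null expectation of
−1/400), 65 of 400 districts fall in significant hotspots or coldspots, the
error model recovers a spatial parameter (0.587) close to the generating
λ = 0.59, and AIC selects the spatial error model — the behaviour expected
when dependence enters through spatially correlated omitted variables.

The same stages are available as shell commands (`spatvax simulate`,
`weights`, `moran`, `lisa`, `ols`, `slm`, `sem`, `diagnose`, `pipeline`);
`spatvax --help` lists them. Real data enter as a GeoJSON polygon layer plus
a CSV whose first column is the district id.

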