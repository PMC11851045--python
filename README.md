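# sppanel

Spatiotemporal analysis of regional web-search attention, built for
infodemiology panels: province-level search-volume indices observed over
several years, linked to demographic and economic covariates, and analysed
for seasonal concentration, spatial clustering, and spatially mediated
associations.

The package provides, end to end:

- **Rook-contiguity spatial weights** — built from edge lists, polygon
  geometries (shared boundary *segment*, not corner contact), or GAL files;
  island regions are patched by explicit pairs (the packaged 31-province
  mainland-China fixture ties the island province Hainan to Guangdong);
  row-standardization makes the spatial lag a neighbor average.
- **Temporal concentration** — with monthly shares `r_1..r_12` of a year's
  search volume, the dispersion `R = sqrt(Σ_i (r_i − 1/12)²)` and the
  concentration ratio `M = R / sqrt(11/12) ∈ [0, 1]`; `M = 0` at a uniform
  within-year distribution, `M = 1` when all volume falls in one month,
  `M < 0.3` conventionally read as relatively uniform.
- **Spatial autocorrelation** — global Moran's
  `I = (n/S0) Σ_ij w_ij z_i z_j / Σ_i z_i²` with analytic
  (normality/randomization) z-scores and permutation pseudo p-values, and
  local Moran's `I_i = (z_i/m2) Σ_j w_ij z_j` with conditional-permutation
  inference and HH/LL/HL/LH quadrant labels.
- **Spatial panel econometrics** — maximum-likelihood SAR, SEM and spatial
  Durbin (SDM) models

      y_t = ρ W y_t + X_t β + W X_t θ + μ + ν_t 1 + ε_t

  with pooled / unit / time / two-way fixed effects or random effects;
  LM-lag/LM-error (+robust) battery, Wald and LR reduction tests, Hausman
  FE-vs-RE, LR tests of the fixed-effect structure, VIF diagnostics, and the
  LeSage–Pace direct/indirect/total effect decomposition through the spatial
  multiplier `(I − ρW)^{-1}`.
- **A selection cascade** mirroring standard practice (LM battery → SDM
  reduction tests → Hausman → LR effect-structure tests) with a full
  machine-readable decision trace.
- **Synthetic data generators** for all of the above, each emitting a truth
  record so estimator-recovery claims are testable.

## Worked example

```python
import sppanel as sp

w = sp.china_provinces()                      # 31-province rook weights
cfg = sp.default_study_config(seed=7)         # 31 units x 8 years, 5 covariates
panel, truth = sp.simulate_sdm_panel(w, cfg)

# spatial clustering of the per-capita index, most recent year
res = sp.global_moran(panel.y[:, -1], w, inference="permutation",
                      n_perm=999, seed=7)
print(f"I = {res.I:.3f}, z = {res.z:.2f}, pseudo p = {res.p_perm:.3f}")

# selection cascade and effect decomposition
trace, fit = sp.run_selection_cascade(panel, w, alpha=0.1)
print(trace.final_model, trace.final_effects, f"rho = {fit.rho:.3f}")
eff = sp.decompose_effects(fit, w, n_draws=1000, seed=7)
print(eff.to_frame().head(3).to_string(index=False))
```

Output:

```
I = 0.130, z = 1.37, pseudo p = 0.171
SDM random rho = 0.374
effect               variable  estimate       se        p    ci_low   ci_high
direct      male_female_ratio  0.152104 0.548957 0.795106 -0.948034  1.210449
direct gross_dependency_ratio -0.113893 0.307755 0.687921 -0.703313  0.472169
direct      urbanization_rate -0.167295 0.001887 0.000000 -0.170974 -0.163585
```

A 31-unit cross-section has modest power, and this draw shows it honestly:
the final year's Moran's I of 0.13 is positive but not significant at the
5% level (pseudo p = .17). The cascade still detects the spatial lag in the
panel as a whole and keeps the spatial Durbin model (ρ ≈ 0.37); the Hausman
test cannot reject random effects at this sample size, so the trace reports
`SDM random`. The decomposition splits each covariate's impact into local
(direct) and neighboring-region (indirect) parts; the strongly identified
high-variance covariate (urbanization, in percentage points) shows the
negative direct association the generator encodes. At the 10×10-lattice
sizes used in the validation suite the cascade recovers `SDM both` in ~90%
of replicates.

The same workflow is scriptable from a shell:

```sh
sppanel simulate --out demo --seed 7 --lattice 10 10
sppanel select --panel demo/panel.csv --gal demo/weights.gal --out demo/trace.csv
sppanel report --config config.yaml   # full study: all result tables
```

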