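# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Spatial weights

Adjacency is rook contiguity: two regions are neighbors iff they share a
boundary segment of positive length (tolerance 1e-9 in coordinate units
when derived from polygons); point contact does not count. The binary
matrix `W0` is symmetric with zero diagonal. Downstream analyses use the
row-standardized `W` (rows sum to 1), so the spatial lag `Wx` is a neighbor
average; binary weights remain available behind a flag. Row standardization
is applied before all Moran and panel computations: it is the GeoDa/Stata
default, and the closed form for the total effect in the decomposition
(`Σ_k row sums of (I−ρW)^{-1}` collapsing to `(β+θ)/(1−ρ)`) assumes unit
row sums.

Island regions are patched with an explicit pair list rather than an
automatic nearest-neighbor rule — a deliberately manual step, because such
links are substantive modeling decisions; a helper ranks centroid-distance
candidates for the user to confirm. The packaged 31-province adjacency is
reconstructed by the maintainers from public provincial geography (land
borders, with the island province Hainan tied to Guangdong); it is a
fixture for demonstrations and tests, not an authoritative gazetteer.

## Temporal concentration

For a year with monthly shares `r_1..r_12`, the dispersion is the Euclidean
deviation from uniform, `R = sqrt(Σ (r_i − 1/12)²)`, and the concentration
ratio is `M = R / sqrt(11/12)`. The normalization anchors the two extremes:
`M = 0` iff the year is exactly uniform and `M = 1` iff all volume falls in
a single month (the vector `(1,0,…,0)` has `R = sqrt(11/12)`). `M` depends
only on shares, hence is invariant to rescaling of raw counts. The 0.3
threshold separating "relatively uniform" from "aggregated" follows the
common infodemiology convention and is configurable. Years with missing
months are dropped from the concentration analysis with a warning — no
imputation. Concentration indices of this family differ in their exact
normalizations across the literature; the statistic is isolated behind one
function (`temporal.concentration`) so an alternative form can be swapped
in without touching the pipeline.

## Moran statistics and inference

Global Moran's I uses the standard cross-product form with
`E[I] = −1/(n−1)`. Analytic z-scores offer both the normality- and the
randomization-assumption variance (Cliff–Ord moments); randomization is the
default. The permutation test is two-sided by folding around `E[I]`:
`p = (1 + #{|I_perm − E[I]| ≥ |I_obs − E[I]|}) / (n_perm + 1)`, with 999
permutations by default and a mandatory seed. Local Moran's I uses the
`m2 = Σ z²/n` scaling, under which `Σ_i I_i = S0 · I_global` exactly;
significance is by conditional permutation (the unit's own value held
fixed, the remaining `n−1` values permuted over its neighbor positions).
Quadrant labels come from the signs of the unit's deviation and of its
spatial lag; a unit with exactly zero deviation gets "L" on its own axis
with the lag deciding the neighbor axis, and is flagged (a measure-zero
event for continuous attributes). No multiple-testing correction is applied
to the local statistics by default, matching common practice in the applied
literature; Bonferroni/FDR are available as options. LISA significance
defaults to α = 0.05; the pipeline's decision logic uses a two-sided
α = 0.1 throughout, both configurable.

## Spatial panel models

The spatial Durbin model is

    y_t = ρ W y_t + X_t β + W X_t θ + μ + ν_t 1 + ε_t ,   ε_t ~ N(0, σ² I),

nesting the SAR (θ = 0) and, through the common-factor restriction
θ = −ρβ, the SEM. Estimation is by concentrated ML: fixed effects are
removed by within-demeaning, (β, θ) and σ² are profiled out, and the scalar
spatial parameter is maximized over `(1/ω_min, 1/ω_max)` (the extreme
eigenvalues of `W`, shrunk by 1e-6), with a 50-point coarse grid guarding
the bounded Brent refinement against local optima. The log-Jacobian
`T ln|I − ρW|` uses eigenvalues computed once from the symmetric similarity
transform of `W0`.

**Incidental-parameter correction.** Plain demeaned QML carries O(1/T) and
O(1/n) biases from the estimated fixed effects. The estimates reported here
maximize the likelihood of the orthonormally transformed data instead:
eliminating unit effects loses one time period (effective T−1), eliminating
time effects loses one cross-sectional dimension and — because `1` is an
eigenvector of the row-standardized `W` — drops the unit eigenvalue from
the Jacobian, `|I_n − ρW| = (1−ρ)|I_{n−1} − ρW*|`. The two-way
transformation has effective sample `(n−1)(T−1)`. The residual sum of
squares is unchanged by the transformations (they are orthonormal bases of
the demeaned subspaces), so only the likelihood's dimension constants and
Jacobian change; in the validation suite this removes the coefficient bias
visible at T = 10. The reported σ² uses the effective-sample denominator.
The `loglik` field, used by all LR tests, is the *plain demeaned* QML
maximum, so that likelihoods are on one common `nT` scale across models and
effect structures and the nesting inequalities (SDM ≥ SAR ≥ within-OLS)
hold exactly.

Variance estimates come from the analytic information matrix of the
SAR/SDM (and SEM) likelihood, evaluated with the df-corrected σ². A
numerical-Hessian cross-check is part of the test suite: slope standard
errors agree within a few percent; the ρ cell, mixing trace terms where
expected and observed information differ more in finite samples, is looser.

**Random effects** (SAR/SDM) are estimated by ML with the quasi-demeaning
weight `φ = σ_ε / sqrt(T σ_μ² + σ_ε²)` profiled jointly with ρ
(L-BFGS-B after a coarse grid); the specification retains time dummies so
that the Hausman comparison against a two-way FE fit contrasts like with
like. The RE vcov is a numerical Hessian of the full likelihood in
(slopes, ρ, log φ, log σ²). A random-effects SEM is not provided; when the
cascade's reduction stage lands on SEM, the Hausman comparison runs on the
SDM and the trace says so.

**Specification tests.** The LM battery uses the pooled panel forms on the
within residuals: `LM_err = [e'(I⊗W)e/σ̂²]²/(T·T_W)` with
`T_W = tr(W'W + WW)`, `LM_lag = [e'(I⊗W)y/σ̂²]²/J` with
`J = [(WXβ̂)'M(WXβ̂) + T·T_W σ̂²]/σ̂²`, plus the standard robust variants;
all are χ²(1). Wald reductions test θ = 0 (to SAR) and, by the delta
method over (β, θ, ρ), θ + ρβ = 0 (to SEM), each χ²(k). The Hausman
statistic is `d'(V_FE − V_RE)^{-1} d` on the common slope vector (β and θ;
ρ excluded); a non-positive-definite difference falls back to a
pseudo-inverse with a flag. In simulation at n = 100, T = 10 the Wald and
Hausman tests run somewhat hot (empirical size ≈ 0.08–0.10 at nominal
0.05) — the familiar finite-sample behavior of asymptotic χ² tests; the
validation suite encodes the band [0.01, 0.12], fixed in advance, as its
operationalization of "approximately nominal".

**Effect decomposition.** For covariate k,
`S_k(W) = (I − ρW)^{-1}(I β_k + W θ_k)`; the direct effect is the mean
diagonal, the total the mean row sum, the indirect their difference (the
additivity is definitional and holds to machine precision). Inference
simulates (β, θ, ρ) from the fit's asymptotic normal (1,000 draws by
default, seeded) and summarizes per draw; p-values use the simulated
mean/sd normal ratio, intervals are percentile-based.

**Other conventions.** Per-capita indices divide the raw search index by
year-end population; per-capita product enters in natural logs. Unbalanced
panels are rejected, not imputed. Two-sided α = 0.1 is the pipeline's
default decision threshold, per the applied convention the package targets.

## Selection cascade

Order: (1) LM battery on the two-way within residuals — if nothing is
significant, keep the within regression; (2) fit the SDM and test both
reductions with Wald *and* LR — the SDM is kept unless both tests of a
reduction fail to reject (if both reductions qualify, the restricted model
with the higher log-likelihood wins); (3) Hausman FE vs RE on the selected
model; (4) under FE, LR tests of two-way effects against space-only
(df = T) and time-only (df = n); if neither rejects, two-way effects are
retained conservatively. Every decision is recorded with its statistic in a
trace whose final specification is reachable from the recorded decisions;
an integration test asserts the trace equals manual stage-by-stage
invocation.

## Synthetic data

`simulate_sdm_panel` draws from the reduced form
`y_t = (I − ρW)^{-1}(α + X_t β + W X_t θ + μ + ν_t 1 + ε_t)`. Covariates
are Gaussian around unit-level means (optionally AR(1) within unit over
time, φ = 0.8, since real regional covariates are slow-moving); the
unit-mean channel lets unit effects correlate with the covariates
(`fe_x_corr`), which is precisely the regime where pooled OLS is biased and
the within estimator is not — the generator's core purpose. The default
study-scale configuration is 31 units × 8 years with five covariates whose
roles, scales and effect signs echo a sex ratio, a dependency ratio, an
urbanization rate (negative effect), an education share and log per-capita
product (positive effects) — no claim is made about real-world magnitudes.
Validation simulations use 10×10 rook lattices with T = 10 (recovery, test
calibration) or smaller lattices for closed-form checks, sizes at which the
asymptotic approximations are informative while a full 200-replicate study
runs in seconds.

The monthly generator modulates a base level by a circular bump
`exp(κ cos(2π(m − peak)/12))` with lognormal noise (cv 0.05); κ = 0 makes
months exchangeable, and the concentration ratio M is monotone in κ on a
fixed-seed grid.

What the generator does *not* emulate: measurement error and censoring of
real search indices (platform thresholds), spatially correlated covariates,
heteroskedastic or temporally dependent disturbances, and unbalanced
panels. Passing recovery tests therefore show the estimators are correct
for their stated model, not that the model is right for any particular
real dataset.

## Known limitations

- SEM has no random-effects variant; the cascade substitutes the SDM for
  the Hausman stage and records the substitution.
- The analytic vcov is expected information; no heteroskedasticity-robust
  or clustered alternatives are provided.
- Dynamic panels, GMM/IV estimation, higher-order/distance-based weights
  and Getis–Ord statistics are out of scope.
- The Wald/Hausman tests' mild finite-sample oversizing (above) should be
  kept in mind when α is taken literally at small n.
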