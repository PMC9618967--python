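# Methods

## Demographic model

*r*<sub>max</sub> is the real root of the modified Euler–Lotka equation

l<sub>α</sub>·b = e^(rα) − e^(−M)·e^(r(α−1)),  l<sub>α</sub> = e^(−M·α),

equivalent to the discrete renewal sum 1 = Σ<sub>x=α</sub><sup>∞</sup>
b·e^(−(M+r)x). The model assumes exponential adult survival, knife-edge
maturity at age α (treated as real-valued, since published maturity ages
are fractional), reproduction every year from α onward, and no density
dependence. Natural mortality M is input data; `mortality_from_lifespan`
(M = 1/ω) is offered only as one published convention.

Numerically the geometric closed form 1 − b·e^(−sα)/(1 − e^(−s)) with
s = M + r is strictly increasing in r on r > −M, so the root is unique; it
is bracketed on [−M + 10⁻⁶, 5] with geometric upper-end expansion and
refined by Brent's method to a residual below 10⁻¹⁰. Negative roots are
legitimate (the population cannot replace itself) and raise a warning, with
a 10⁻¹² tolerance so the analytically forced replacement point reports
exactly zero. `renewal_series_rmax` solves the truncated sum directly
(default horizon 10 000 years) and is used as the independent oracle;
solver and oracle agree to 10⁻⁶ across the tested parameter space.

## Thermal habitat

The pipeline is: core mask (occurrence probability ≥ 0.9, inclusive) →
nearest depth level to the species' median depth → median of the present
temperature cells at that level → +3.5 °C if mesothermic. Choices worth
stating:

* **Depth levels.** The default set has 27 levels spanning 0–2000 m with
  100 m and 150 m adjacent, so a median depth of 130 m maps to the 150 m
  layer. The exact level values are a package choice; any strictly
  increasing set can be passed instead.
* **Ties** between two equally near levels break toward the shallower one —
  the conservative choice for data coverage.
* **Missing cells** are excluded from the median, never imputed; if every
  core cell is missing at the selected layer the species is reported as a
  failure (`NoOverlapError`) and the batch continues.
* **Even-count medians** are the mean of the two central values, making
  test expectations exact.
* Distribution rasters and temperature grids must share cell registration;
  no silent regridding is performed.

## Regression engine

The model is y = Xβ + ε with ε ~ N(0, σ²C<sub>λ</sub>), y = ln r_max, and
C the Brownian-motion covariance of the tree (C[i,j] = root-to-MRCA path
length). Pagel's λ multiplies the off-diagonal of C; λ = 0 is OLS, λ = 1
pure Brownian motion. For fixed λ, β̂ and σ̂² (ML, divisor n) are closed
form through a Cholesky factorization of C<sub>λ</sub> (no explicit
inverse); λ̂ maximizes the profile log-likelihood over [0, 1] by bounded
scalar search (tolerance 10⁻⁸) with both endpoints evaluated, and its 95%
interval is the 1.92 log-likelihood-unit drop region found by bisection.

Everything is ML rather than REML because the ten candidate models differ
in their fixed effects, and AICc comparison across fixed-effect structures
requires ML likelihoods. In AICc = −2LL + 2k + 2k(k+1)/(n−k−1), k counts
regression coefficients only (λ and σ² excluded); the alternative
convention is available via `k_convention="coefficients+variance"`.
Coefficient CIs are estimate ± 1.96·SE with SEs from σ̂²(XᵀC⁻¹X)⁻¹ —
note the ML σ̂² is biased low by factor (n−k)/n, a deliberate convention
recorded here; its effect on CI coverage at the tested sample sizes is
under half a percentage point. R² compares the model's GLS residual sum of
squares with that of an intercept-only fit, both whitened by the model's
own λ̂-covariance; adjusted R² applies the usual (n−1)/(n−k) correction.
VIFs are computed on the ordinary (unwhitened) design excluding the
intercept, matching the standard collinearity diagnostic; perfectly
collinear columns report infinity. Parameters whose addition to a nested
model improves AICc by less than 2 are flagged as uninformative.

Covariate conventions: natural logs for mass and r_max; temperature enters
only as inverse temperature 1/(k_B·T) in eV⁻¹ (k_B = 8.617×10⁻⁵ eV/K);
inverse temperature and depth are centered and scaled (sd with n−1) by
default, with a center-only mode (`scale=False`) for reading slopes as
activation energies on the natural eV scale; log mass is never scaled so
the mass slope compares directly to metabolic-theory exponents.
Interactions are products of the transformed main-effect columns. The
centering constants are stored in the fit and reused for prediction, so
predictions at training covariates equal fitted values to 10⁻¹⁰.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes —
not the texture of real data:

* **Trees**: Yule (pure-birth) with the root splitting at time zero,
  rescaled to unit tip depth. Real phylogenies have non-ultrametric error
  structure and topology uncertainty; the multi-tree sensitivity tool
  accepts any tree set.
* **Traits**: log mass uniform over 0.1–1000 kg (in grams); depth and
  inverse temperature jointly Gaussian with Pearson correlation 0.6
  (deeper is colder), mapped to −2–30 °C and 5–2000 m; residuals exactly
  multivariate normal with covariance σ²C<sub>λ</sub>. Defaults: the
  five-coefficient mass × inverse-temperature + depth structure with
  coefficients (0.07, −0.31, −1.55, −0.48, 0.41), λ = 0.8, σ² = 0.35,
  n = 63. With these broad covariate ranges the synthetic signal-to-noise
  (and hence R²) is much higher than in the empirical study, so passing
  recovery tests demonstrates correctness of the estimator, not expected
  real-data precision.
* **Ocean**: closed-form surface field (warm equator, cold poles) relaxing
  toward a 2 °C abyss with a 400 m e-folding scale, mild noise, a
  cumulative minimum enforcing monotone cooling with depth, and
  independent per-cell missingness (default 5%).
* **Rasters**: Gaussian bumps with the nearest-to-center cell pinned to
  probability 1 so a core distribution always exists.
* **Life histories**: maturity age rises with mass and falls with
  temperature; mortality falls with mass (large elasmobranchs are
  long-lived) and rises with temperature; fecundity falls weakly with
  mass. These rules make essentially every simulated species viable and
  give a mean log r_max–log mass slope near −¼.

All randomness flows through one seeded numpy generator per call; fixed
seeds give bit-identical trees, tables and grids.

## Known limitations

* λ̂ is imprecise at study-sized samples (n ≈ 63): profile intervals
  commonly span half the unit interval. Multi-tree and replicate tools are
  provided for exactly this reason.
* AICc model selection has an irreducible error rate: a superset model
  with one spurious term outranks the generating model whenever its
  likelihood-ratio statistic exceeds the ≈2.1-unit penalty, which happens
  with probability ≈0.15 asymptotically regardless of signal strength. A
  "best model" identity should always be read together with the weights.
* The thermal module assumes shared grid registration and a single annual
  mean field; no seasonality, no bathymetry masking, no distribution-model
  fitting.
* No branch-length transforms beyond λ (no κ, δ, OU), no measurement-error
  models, no nonlinear terms.

## Problem sizes

Recovery experiments in the test suite and acceptance script use 200-tip
trees with 500 replicates (coefficient bias and coverage) and 100
replicates (model identity); endpoint λ recovery uses 150 tips and 40
replicates per endpoint. These sizes put Monte-Carlo error comfortably
below the tested tolerances.
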