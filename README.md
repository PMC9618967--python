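# phylormax

Body mass, temperature, and depth shape how fast populations of sharks,
rays, and chimaeras can grow. `phylormax` implements the full comparative
pipeline for studying that variation:

1. **Demography** — the maximum intrinsic rate of population increase,
   *r*<sub>max</sub> (yr⁻¹), solved per species from a modified Euler–Lotka
   equation with exponential survival, knife-edge maturity at age *α*, and
   indefinite adult reproduction:

   *l*<sub>α</sub>·*b* = e^(*r*·*α*) − e^(−*M*)·e^(*r*(*α*−1)),  with
   *l*<sub>α</sub> = e^(−*M*·*α*),

   where *b* is annual female fecundity and *M* instantaneous natural
   mortality. An independent truncated renewal-series solver cross-checks
   every root.

2. **Thermal habitat** — each species' characteristic temperature is the
   median of a depth-layered mean-annual ocean temperature grid over its
   core distribution (occurrence probability ≥ 0.9), read at the grid depth
   level closest to the species' median depth, with a fixed +3.5 °C
   correction for mesotherms.

3. **Phylogenetic regression** — metabolic scaling theory predicts
   log *r*<sub>max</sub> = β₀ + β₁·log *M* + β₂·(1/*k*<sub>B</sub>*T*),
   with mass slope β₁ ≈ −¼ and β₂ = −*E* (activation energy, ≈ −1.0 to
   −0.6 eV). Ten candidate structures built from log mass, inverse
   temperature and depth (main effects plus pairwise interactions) are fit
   by maximum-likelihood phylogenetic GLS with Pagel's λ scaling the
   off-diagonal of the Brownian covariance matrix, and compared by AICc and
   Akaike weights. Variance-inflation factors, profile-likelihood λ
   intervals, multi-tree sensitivity, and prediction curves round out the
   engine.

A seeded synthetic-data module generates pure-birth trees, trait tables
with λ-structured residuals around known coefficients, depth-cooling
temperature grids, and unimodal occurrence rasters, so the whole pipeline
is testable against known ground truth.

## Worked example

```python
import phylormax as pm

tree  = pm.simulate_tree(63, seed=1)
cfg   = pm.SimulationConfig(n_species=63, seed=1)   # truth: logM*invtemp + depth
table = pm.simulate_pgls_dataset(tree, cfg)

comp = pm.compare_models(pm.enumerate_models(), table, tree)
print(comp.best_fit.summary())
```

```
Phylogenetic GLS (ML), model: logrmax~logM*1/kBT+depth
n = 63, k = 5, logLik = -25.095, AICc = 61.24
Pagel's lambda = 0.204 (95% CI 0.00, 0.73)
sigma^2 (ML) = 0.1402, adj. R^2 = 0.978

term                        coef        se   ci95_lo   ci95_hi
intercept                 -0.470     0.185    -0.833    -0.107
log_mass                  -0.291     0.017    -0.324    -0.258
invtemp                   -1.263     0.203    -1.660    -0.865
depth                     -0.530     0.066    -0.659    -0.401
log_mass:invtemp           0.384     0.021     0.344     0.425
```

The generating structure (mass × inverse-temperature interaction plus a
main depth effect, true coefficients 0.07, −0.31, −1.55, −0.48, 0.41) is
ranked first with Akaike weight 0.69; the fitted mass slope −0.29 sits near
the metabolic-theory expectation of −¼, the depth effect is negative
(deeper species grow slower), and the positive interaction says the mass
scaling steepens in warmer water. λ is imprecise at 63 species — its 95%
profile interval spans 0–0.73 — which is exactly why the multi-tree and
replicate machinery exists.

The same objects drive file-based analyses: `PhyloGLS.from_formula`
accepts any of the ten formula labels with a trait table and a Newick
tree, and the `phylormax` command line exposes each stage
(`simulate`, `solve-rmax`, `extract-thermal`, `compare`, `sensitivity`,
`run`).

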