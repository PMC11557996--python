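# carapace

Phylogenetic evolutionary allometry of turtle body size: how straight
carapace length (SCL, the standard turtle body-size proxy) scales with
humerus and femur length across the turtle tree of life, and how to use
those scaling relationships to predict the shell lengths and body masses
of fossil turtles known only from limb bones.

The package is aimed at vertebrate palaeontologists and comparative
biologists.  It implements, end to end:

* **PGLS with jointly estimated Pagel's λ.**  For species-mean log10
  traits `y` and design `X` on a time-scaled phylogeny,

      y = Xβ + ε,   ε ~ MVN(0, σ² C_λ),

  where `C` is the Brownian-motion covariance (entries = shared
  branch-length time; fossil tips simply have shorter root-to-tip paths)
  and `C_λ` multiplies its off-diagonal by λ ∈ [0, 1].  Estimation is by
  maximum likelihood, profiling λ over a fine grid with bounded
  refinement; the engine is validated against brute-force dense-algebra
  oracles and against R's `nlme::gls(correlation = corPagel(...))`.
* **AICc model selection with binary covariates** (terrestrial ecology,
  softshell clade membership), using the rule "lowest AICc among models
  whose every coefficient is significant at p < 0.05", plus likelihood
  R², Akaike weights, and a t-test comparing PGLS and OLS slopes.
* **Bootstrap coefficient intervals** (B = 1000; parametric by default,
  species-row resampling available), and slope classification into
  weak/moderate/strong negative or positive allometry bands around
  isometry (slope 1 on log–log axes).
* **Specimen maturity filtering**: keep only specimens at ≥ 60% of their
  species' (sex-specific) maximum SCL — with the larger-sex rule for
  unsexed museum specimens — so ontogenetic allometry cannot leak into
  the evolutionary regressions; every exclusion is logged with its rule.
* **Brownian-motion rate estimation** (σ², with measurement error) for
  single traits and for regression residuals, and Welch t-tests between
  bootstrap σ² distributions.
* **Fossil prediction equations**: the published global and
  clade-specific formulas for SCL from humerus/femur length (e.g.,
  `log10 SCL = 0.64 + 0.96 · log10 FL`), and the body-mass regression
  `log10 BM = 2.73 · log10 SCL − 3.18` (BM in g, SCL in mm).
* **A synthetic-data generator** (Yule trees, Brownian traits,
  λ-structured residuals, specimen-level ontogeny/sex structure) so the
  whole pipeline runs and is tested without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each prints what it found and writes tables under `results/`):

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_filter_aggregate.py
python analysis/03_fit_allometry.py --seed 1
```

which prints

```
simulated 200 species, 574 specimens (seed 1); truth: b=0.96, lambda=0.94
kept 292/574 specimens across 167 species; exclusions by rule:
  {'below_60pct_max_larger_sex_unsexed': 107, 'below_60pct_max_female': 83,
   'below_60pct_max_male': 67, 'somatically_immature': 25}
best model: log10_scl ~ log10_hl + ecology_terrestrial (fallback=False)
slope = 0.9491 [0.9213, 0.9772] -> weak negative; lambda = 0.816, R2 = 0.9645
```

Half the raw specimens are juveniles or unsexable small individuals and
are removed by the 60% rule; the refit on the surviving species means
recovers the generating slope (0.96) inside its bootstrap CI, detects
the −0.05 terrestrial offset via AICc + significance, and classifies
the slope as weak negative allometry.  `04_evolution_rates.py` then
shows individual traits accumulating variance ~100× faster than the
shell–limb *relationship* (σ² ≈ 0.23–0.27 vs 0.0038 per unit tree
height), which is exactly why limb bones are good shell-size predictors,
and `05_predict_fossils.py` turns stylopodial lengths into shell lengths
and body masses, e.g. a 400 mm protostegid humerus → 1628 mm SCL via the
sea-turtle equation.

In code, single predictions are one-liners:

```python
>>> import carapace as cp
>>> cp.predict_scl(100.0, "femur", "Testudinata").point   # mm
363.078...
>>> cp.predict_bm(519.0).kg                               # Proganochelys
17.08...
```

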