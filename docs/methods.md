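# Methods

## Model

All regressions act on species-mean traits, log10-transformed after
averaging raw measurements in mm (means are arithmetic on the raw scale;
a geometric-mean option exists behind a flag).  For response `y`,
design `X` (intercept, a stylopodial log-length, and optional 0/1
covariates) and a time-scaled phylogeny,

    y = Xβ + ε,   ε ~ MVN(0, σ² C_λ)

`C` is the Brownian-motion expectation: `C[i,j]` equals the depth of the
most recent common ancestor of tips i and j, and `C[i,i]` the root-to-tip
path length.  Trees need not be ultrametric — fossil tips have shorter
paths and hence smaller variances.  When a tree retains a stem (root)
edge, that edge is counted in all entries, which makes "prune, then build
the covariance" exactly equal to subsetting the full covariance.  The
synthetic Yule generator emits crown trees (no stem edge), matching the
convention of `ape::vcv`.

Pagel's λ multiplies the off-diagonal of `C` only; λ = 1 is pure
Brownian structure, λ = 0 independent residuals.  σ² is the rate of
residual variance accumulation per unit branch-length time.

## Estimation

Maximum likelihood throughout (not REML): AICc comparisons across models
with different fixed effects require ML.  β and σ² have closed forms
given λ; λ is profiled over the grid {0, 0.01, …, 1} and the best grid
point is refined by bounded scalar minimization (xatol 1e-6), ties going
to the smaller λ.  Two linear-algebra routes evaluate the identical
profile likelihood:

* general: one Cholesky factorization of `C_λ` per λ (any tree);
* fast: when all tip variances are equal (ultrametric case),
  `C_λ = λC + (1−λ)hI` shares C's eigenvectors for every λ, so one
  eigendecomposition turns each λ into a weighted least squares.  This
  is what makes 1000-replicate bootstraps and 100-replicate coverage
  studies affordable on one CPU.

Reported SEs use the unbiased scaling n/(n−k); p-values use Student's t
with df = n − k.  The PGLS-vs-OLS slope t-test uses
df = n − k − 1 (reproducing re-df = 198 at n = 201, k = 2).  AICc
counts k = coefficients + 1 (σ²) + 1 more when λ is estimated (0 for
OLS); the convention is stored in every fit so comparisons are
internally consistent.  Likelihood R² is the unrescaled
1 − exp(−2Δ lnL / n) against an intercept-only null that carries its own
λ̂.  Zero-residual (exactly collinear) data return the exact
coefficients with σ² = 0, λ at the lower bound, and a degeneracy flag
rather than an error.

The univariate Brownian rate with relative measurement error `m`
maximizes the MVN likelihood with covariance σ²C + diag((m·x_i)²),
profiling the root state and searching σ² on the log scale; m = 0 uses
the closed form.

## Model sets and selection

For each dataset the candidate set is {y ~ x, y ~ x + covariate (one per
available binary covariate), y ~ 1 (null, for R²)} fitted as PGLS, plus
the purely allometric model as OLS for the slope comparison.  Covariates
constant within a subset are dropped with a warning.  Selection: rank by
AICc and take the best model whose every non-intercept coefficient has
p < 0.05; if none qualifies the purely allometric PGLS model is returned
with a fallback flag.  Akaike weights are reported over the whole set.

Slope classification bands (log–log): weak/moderate/strong negative
allometry at 0.99–0.85 / 0.84–0.70 / < 0.70, positive at 1.01–1.15 /
1.16–1.30 / > 1.30, the open interval (0.99, 1.01) labelled
near-isometric; band edges are inclusive toward their named band.

## Bootstrap

`bootstrap_cis` defaults to a **parametric** bootstrap: simulate
y* = Xβ̂ + ε*, ε* ~ MVN(0, σ̂²C_λ̂), refit with λ re-estimated, take
2.5/97.5 percentiles of the B = 1000 coefficient draws.  This matches
the behaviour of the R phylogenetic-regression tooling the field uses
and, at the package's study conditions, covers the true slope in ~93%
of replicates.  Species-row resampling (`method="rows"`) is retained for
comparison: duplicated rows make the covariance exactly singular at
λ = 1 (handled as likelihood −inf, so λ̂ stays below 1) and measured
coverage was ~87% with the resample distribution visibly shifted against
the point estimate — row resampling treats phylogenetically correlated
species as exchangeable, which they are not.

Fossil prediction intervals push every bootstrap coefficient vector
through the linear predictor and add, by default, a residual draw with
variance σ̂² × (expected tip depth), giving a prediction interval for a
new observation; coefficient-only bands are available via
`include_residual=False`.  Predictions from the shipped published
equation constants are point-only (no covariance information survives
publication), matching how clade-specific estimates are reported without
CIs.

## Maturity filter

A specimen is kept iff it is not flagged somatically immature, and
either carries an explicit include-override (used for rare large species
admitted a few percent below threshold) or its SCL is at least 60% of
its species' maximum SCL — the maximum of its own sex when sexed, of the
*larger* sex when unsexed.  Where the spec of the rules could be read to
let an override rescue a somatically immature specimen, immaturity wins
here: ontogenetic allometry is the contaminant the filter exists to
remove, and the override exists only to relax the size threshold.
Gravidity is carried as metadata (evidence of sexual maturity) but is
not itself a rule: the motivating gravid example (62% of maximum) passes
the 60% rule on its own.  Specimens without an SCL cannot be assessed
and are excluded (rule `missing_scl`) unless overridden.  The filter is
idempotent and every exclusion is logged with its rule name.

## Synthetic data (study conditions)

Defaults, chosen once to mirror the fitted global relationships and a
realistic turtle trait spread: 200 tips, Yule tree rescaled to height 1
(pendant edges extended by the post-speciation holding time so the
covariance is strictly positive definite), predictor root state 2.0
(100 mm), σ²_x = 0.15 (log10-SCL sd ≈ 0.35 across tips, i.e., sizes
spanning roughly 40–600 mm), intercept 0.64, slope 0.96, residual
λ = 0.94, σ²_resid = 0.005 (R² ≈ 0.95), terrestrial offset −0.05 on 25%
of species, 1% measurement error.  Specimen tables draw 1–5 specimens
per species, uniform in 0.3–1.0 × the sex maximum (female:male maximum
ratio 1.3), 30% unsexed, 5% somatically immature; limb lengths scale
isometrically from the species' own mean traits by relative size with
0.02 dex multiplicative noise, so species means recovered from mature
specimens preserve the species-level evolutionary structure.

What the generator does *not* emulate: real ontogenetic allometry
(within-species growth is isometric here), biased museum collecting,
non-Yule diversification, correlated ecology (covariate flags are
random with respect to phylogeny), or the structure of the external
amniote comparison datasets.  Passing tests therefore demonstrate the
estimators and rules, not robustness to those real-data features.

## Numerical choices

λ grid step 0.01 with 1e-6 refinement; non-positive-definite covariances
during the λ profile are treated as likelihood −inf; MVN draws add a
1e-12-scaled trace jitter before Cholesky; degenerate fits detected at
σ²_ML ≤ 1e-14 (scaled); AICc left NaN when n − k − 1 ≤ 0 for auxiliary
tiny fits.  Problem sizes in the test suite follow the study conditions
(200-tip trees, 100 replicates, B = 1000; the oracle-equivalence checks
use 200 random ≤ 8-taxon instances against a 1e-3 λ grid with explicit
matrix inversion).

## Known limitations

Only Pagel's λ is offered as a correlation structure (no OU/EB/κ/δ), no
REML, no multivariate responses.  The shipped published equations are
constants: their clade-specific predictions carry no CIs.  Grafting
fossils takes explicit attachment edges and ages — it never guesses
placements.  AICc weights depend on the k convention above and are not
bit-comparable across software with different conventions.
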