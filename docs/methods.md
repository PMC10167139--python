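# Methods

## Scope and model

`rootpsf` implements a quantitative pipeline for predicting biotic
plant–soil feedbacks (PSFs) from belowground trait strategies. The chain
is:

1. **PSF metrics** from replicate-level pot biomass,
2. a **root economics space** (RES) from four fine-root traits via
   phylogenetically informed PCA,
3. **pair geometry** (signed distances and midpoints) in that space,
4. two **linear feedback models** with sequential ANOVA tables,
5. a **generative soil-effect model** producing sign predictions and
   synthetic experiments for validation.

## PSF metrics

Cell-level performance is the mean of ln(biomass) over replicates of one
(focal, soil, treatment) cell; the `identity` transform is available for
sensitivity checks but the log is the default so that all metrics are log
response ratios, invariant to biomass units and to adding a constant to all
log-performances. The three metrics are

* `PSF_home/away = α_A − β_A`,
* `PSF_pairwise = α_A − α_B − β_A + β_B ≡ PSF_home/away(A) + PSF_home/away(B)`,
* `PSF_live/control = α_A − γ_A`,

with α, β, γ the performances on conspecific live, heterospecific live and
control (sterile/unconditioned) soil. Away soils may be pooled per focal;
pooling averages cell performances (not raw biomasses) and pooled records
are excluded from the geometry stage, which needs a single away position.
Missing cells skip the affected record with a logged warning and a summary
count rather than aborting the run.

Feedback categories (strong negative / negative / neutral / positive) use a
neutral half-width of 0.1 and a strong cut of −0.5 log units by default.
These are reporting bins, not inferential thresholds; both are exposed in
the configuration and recorded in output metadata.

## Root economics space

Traits are ln-transformed and analysed under a Brownian-motion model of
evolution on the supplied phylogeny. With `C` the phylogenetic covariance
(shared root-to-MRCA branch length; stem edges left by pruning count toward
all depths), the fitted quantities are

* GLS root mean `a = (1'C⁻¹1)⁻¹ 1'C⁻¹X`,
* evolutionary covariance `R = (X−1a)' C⁻¹ (X−1a) / (n−1)`, rescaled to a
  correlation matrix in the default `correlation` mode,
* eigendecomposition of `R`; scores are projections of the centered
  (and, in correlation mode, evolutionary-SD-standardized) traits.

Traits are standardized *after* phylogenetic correction (the evolutionary
standard deviations from `R`'s diagonal), which keeps `S'C⁻¹S/(n−1) =
diag(λ)` exact — an identity the test suite checks on random instances.
Eigenvector signs are fixed deterministically (largest-magnitude entry
positive), then axes are oriented to the framework convention: SRL loads
positively on the collaboration axis (positive = DIY pole) and N positively
on the conservation axis (positive = fast pole). The conservation-axis
convention follows the framework's distance logic (moving up the axis means
gaining pathogens); users whose data suggest the opposite vertical ordering
can inspect `reflections` in the metadata. Strategy quadrants (OS/OF/DS/DF)
are assigned by score signs, with exact zeros ties broken toward the
slow/outsourcer side and flagged.

Species missing from the tree are a hard error by default; a
`star_fallback` option substitutes `C = I` (ordinary PCA) with a logged
warning, since real trait compilations often cover only part of a species
pool. Polytomies and zero-length internal branches are allowed unless `C`
becomes singular, in which case an optional diagonal jitter is available
(off by default).

## Pair geometry

For each home/away record, signed distance = away − home and midpoint =
(home + away)/2 along each oriented axis. Distances are signed because the
direction of the comparison carries the prediction; midpoints are used
instead of home positions because home = midpoint − distance/2 makes the
home position collinear with the distance.

## Linear models and sequential ANOVA

Both feedback models are ordinary least squares with single-df terms in a
frozen order:

* live/control: `psf ~ collab + cons + collab:cons`;
* home/away: the full factorial of `{coll_mid, cons_mid, coll_dist,
  cons_dist}` up to the four-way interaction — 4 mains, 6 two-way, 4
  three-way, 1 four-way term (15 terms), in that order.

The Type I (sequential) decomposition is computed by QR orthogonalization
of the design matrix — each term's SS is the squared projection of the
response on the next orthogonalized column — and is verified against
nested-model RSS-difference refits to 1e−8 relative in the tests. Each
term's F uses the full model's residual mean square; adjusted R² is
`1 − (1−R²)(n−1)/(n−p−1)`. Covariates are not standardized by default (a
`standardize` flag exists for sensitivity analysis). Term order matters for
correlated covariates and is therefore part of the model definition;
permuting it changes individual SS rows but never the residual row, total
SS, R² or the whole-model F (also tested). Rank checks run on
column-normalized designs so that interaction columns of very different
scales are not mistaken for collinearity.

## Generative soil-effect model

Species positions are points in the oriented RES. The conditioner's soil
carries linear loads `mutualist_load = −κ·collab` (increasing toward the
outsourcer pole) and `pathogen_load = λ·cons` (increasing toward the fast
pole); the focal's log-growth response is

```
soil_effect = m·(1 + r·(−focal.collab))₊·mutualist_load
            − p·(1 + s·focal.cons)₊·pathogen_load
```

with benefit/cost coefficients `m, p ≥ 0`, focal-side receptivity and
susceptibility slopes `r, s ≥ 0` (0 = fully generalist microbes) and the
modifier factors floored at zero. Linearity is the minimal choice
consistent with a continuous accumulation of mutualists and pathogens along
the axes, and it makes the balance predictions exact: at the symmetric
generalist baseline (`m = p = κ = λ = 1`, `r = s = 0`) the home/away
feedback reduces to `m·κ·Δcollab + p·λ·Δcons` (Δ = away − home), the
live/control feedback at the four unit corners is +2 (OS), 0 (OF, DS) and
−2 (DF), the strongest negative home/away comparison is DF→OS, and every
pairwise feedback is exactly zero by antisymmetric cancellation — a
documented consequence of the symmetry assumption, not an asserted
ecological fact. Nonzero `r`/`s` break the symmetry and introduce midpoint
dependence, mirroring the empirical role of midpoints in the home/away
model. Strategy-level tables are evaluated at corner anchors (±1, ±1);
arbitrary continuous positions are supported. The analytic prediction
tables use a neutral half-width of 1e−9 (exact zeros), configurable for
noisy use.

## Synthetic data

The generator emulates the assumed data-generating process, with defaults
chosen as the package's reference study conditions:

* **Tree**: pure-birth (Yule), unit rate, final exponential waiting time so
  all pendant edges are positive; ultrametric by construction.
* **Latent gradients**: per axis, `phylo_signal`·(standardized Brownian
  realization on the tree) + `(1 − phylo_signal)`·(independent standard
  normal). Defaults: `phylo_signal = 0.5` (the collaboration gradient shows
  phylogenetic signal in real data; 0.5 mixes signal and independent
  variation), orthogonal gradients by construction.
* **Traits**: `lnSRL = +c`, `lnD = −c`, `lnN = +f`, `lnRTD = −f`, each plus
  `N(0, trait_noise_sd²)` noise (default 0.1, a modest measurement error on
  a log scale), exponentiated to positive trait units.
* **Experiment**: for each (focal, conditioner) cell in the design,
  ln biomass = `baseline_log_biomass` (default 1.0) + `soil_effect` +
  `N(0, biomass_sd²)` per pot (default 0.2, ≈20% lognormal pot-to-pot
  noise); sterile soil contributes zero effect. Defaults: 40 species,
  all-pairs design, 5 replicates per cell. `balanced_quadrants` samples one
  away per strategy quadrant per focal; `case_study_like` under-represents
  outsourcer-slow focals and over-samples DIY conditioners, emulating the
  coverage gaps of published datasets.

Everything is driven by one `numpy` Generator seeded from the config, so a
given config is bit-reproducible. With zero noise, the PSF tables computed
by the analysis stages equal the prediction engine's closed forms to
1e−10 — a closed-loop identity the tests assert.

### What the generator does not emulate

Real conditioning experiments include nutrient flushes after sterilization,
intraspecific trait variation, non-fungal agents (rhizobia, nematodes,
decomposers) and specialist microbes tracking phylogeny rather than traits.
Passing recovery tests therefore demonstrate internal consistency of the
pipeline under the framework's own assumptions, not field validity.

## Identifiability and parameter recovery

Because the two latent gradients have identical trait-block structure, the
two leading eigenvalues of the correlation-mode PCA are degenerate in
expectation: the estimated axes are recovered only up to rotation within
their 2-D subspace (the subspace itself is recovered exactly at zero
noise — canonical correlations 1). Per-axis statements such as "PC1 tracks
the collaboration latent" are therefore seed-dependent in the synthetic
setting, while they are resolved in real data by unequal axis variances.
The recovery report consequently maps fitted distance coefficients back to
the latent scale with the full 2×2 least-squares alignment between true
latents and estimated scores (`A @ b`), rather than a per-axis scalar;
recovered effects land within a few percent of the generator's `m·κ` and
`p·λ` at the default conditions.

Under a zero-effect generator the plain OLS F-test on the full all-pairs
record table is anticonservative, because records sharing a focal share
that focal's home-cell error (correlation 1/2 under the null). The
calibration study therefore subsamples one record per focal — making
record errors independent and the F null exact — and observes rejection
rates at α = 0.05 inside the exact binomial confidence band over 200
simulated experiments (24 species, 2 replicates each — sizes chosen to
keep a full calibration sweep cheap). The anticonservativeness of
full-table fits equally affects analyses of real experiments with repeated
focal species and is listed here as a known limitation of the standard
modelling approach.

## Numerical choices

* `C` is factorized by Cholesky; non-positive-definite `C` raises with a
  jitter hint rather than silently regularizing.
* Constant ln-trait columns are an error in correlation mode (zero
  evolutionary SD), naming the trait.
* Eigenvector sign convention and the frozen ANOVA term order make all
  outputs deterministic across platforms.
* Boundary scores (exactly zero) are assigned to the slow/outsourcer side
  and flagged.
* Degenerate designs (duplicate records, collinear terms) raise
  `RankDeficiencyError` naming the offending columns.

## Replicating published case-study analyses

The pipeline accepts external inputs through its file interfaces (trait
CSV, Newick tree, replicate-level or record-level PSF tables) and fits the
models in the exact printed term order, so published grassland/forest
case-study statistics (axis variances, ANOVA tables at 61 pair records
with 15 model and 45 residual df) can be recomputed when those inputs are
available; run metadata records the trait source and aggregation choices on
which exact agreement depends. No third-party dataset ships with the
package.
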