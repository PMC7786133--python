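# Methods

## The model

`guildnet` fits a hurdle joint species distribution model (JSDM) to paired
fungal and bacterial OTU tables from the same samples (deadwood logs). Each
OTU enters the response matrix twice:

- an **occurrence** column: presence–absence modelled with a probit link,
  `P(y_ij > 0) = Φ(x_i β_j + η_i λ_j)`, residual variance fixed at 1;
- an **abundance** column: the log count, z-scored per OTU over the samples
  where it is present, modelled as normal,
  `a_ij ~ N(x_i β'_j + η_i λ'_j, σ_j²)`. Absences are *missing*, not zero —
  they contribute nothing to the abundance likelihood.

`x_i` are the fixed covariates, `β_j` the species' niche coefficients, `η_i`
sample-level latent factor scores shared by every column of both guilds and
both model parts, and `λ_j` the species loadings. The residual covariance
`Ω = ΛΛᵀ` (+1 or σ² on the diagonal, per part) induces the species-to-species
association matrix `R = corr(Ω)`: co-occurrence structure left over after the
covariates are accounted for. Contrasting `R` between a **null** model
(sequencing depth the only covariate) and the **full** model (depth + wood
chemistry + physical log characteristics) separates shared habitat use from
residual association.

### Fixed effects

Full-model covariates: water %, pH, C %, log N %, lignin % (group
*chemical*); tree species (beech/spruce/fir, treatment-coded, reference
beech), decay class (<5, 5–15, 16–38, >38 years, reference <5), DBH in cm
(group *physical*); log read count (group *depth*). A C/N-ratio column, if
present in the metadata, is dropped with a notice — it is nearly collinear
with N content. Covariates are z-scored internally; coefficients can be
mapped back to the original scale (`beta_original_scale`).

Because one joint model spans both guilds but each guild has its own
sequencing depths, the joint design carries **one log-reads column per
guild** (14 columns full, 3 null). The per-guild design
(`build_design_matrix`) has the conventional 13/2 columns. Fungal species are
free to pick up a coefficient on the bacterial depth column and vice versa;
in practice those coefficients sit near zero.

### Priors and sampling

All updates are conjugate, so the sampler is a pure Gibbs scheme:

1. probit liabilities `z` by truncated-normal augmentation (computed through
   the lower normal tail on both branches, accurate for extreme predictors);
2. `β_j` — normal; prior `N(0, 1)` per standardized coefficient;
3. `Λ` — normal with a multiplicative-gamma shrinkage prior
   (`λ_jh ~ N(0, 1/(φ_jh τ_h))`, `φ_jh ~ Ga(ν/2, ν/2)`,
   `τ_h = Π δ_l`, `δ_1 ~ Ga(a₁,1)`, `δ_h ~ Ga(a₂,1)`;
   defaults ν = 3, a₁ = 2.1, a₂ = 3.1 — mild shrinkage, suited to the small
   fixed factor counts used here);
4. `η_i` — normal, standard-normal prior;
5. `σ_j²` — inverse-gamma, prior IG(1, 1) (abundance part only);
6. shrinkage hyperparameters `φ, δ`.

The number of factors is fixed (default 3), not adaptively truncated:
reproducibility and testability outweigh the modest flexibility gain, and the
association matrices of interest are low-rank by construction. One master
seed spawns independent per-chain generators. The field-scale profile is
4 chains × 150,000 iterations, 50,000 burn-in, thin 100 (4,000 retained
draws); the desk-scale default used in tests is far smaller and stated per
test.

The sampler's correctness is checked three ways: exact quadrature oracles for
the factor-free single-species posteriors, a simulate-then-update
(joint-distribution) test that the Gibbs kernel preserves the prior, and
parameter recovery on synthetic communities.

### Convergence diagnostics

`compute_psrf` uses the pooled-variance ratio `R = sqrt((W + B/n)/W)` without
the classical (n−1)/n deflation, so identical chains give exactly 1 and the
statistic is never optimistic; `split=True` (automatic when only one chain
exists) halves chains to expose trends. `compute_ess` is the
autocorrelation-based estimator with Geyer initial-monotone truncation
(via arviz), clipped at the total draw count; constant chains report 0 with a
warning.

## Association networks

Per retained draw, `R` is formed separately for the occurrence part
(diagonal + 1) and the abundance part (+ σ²); a combined view averages the two
per draw. An edge is *supported* when the posterior probability of a common
sign reaches the support level (default 0.95 — the conventional choice; the
level is configurable). `compare_networks` classifies each supported
null-model edge as retained, sign-flipped, or lost in the full model,
within and between guilds.

## Variance partitioning

Per draw and species, the fixed-effect variance of covariate group *g* is the
*g*-diagonal block of `Cov(Xβ)` over samples, with each cross-group
covariance block split equally between the two groups involved — symmetric
and exactly summing; the latent-factor (random-effect) contribution is
`Σ_h λ_jh²`. Proportions are of explained variance only and sum to 1 per
species and part. The equal split can in principle push a group share
slightly negative under strong cross-group collinearity; with the designs
used here it does not.

## Predictive power and directionality

- **Explanatory**: the model fitted to all data predicts the training
  samples using its data-conditioned factor scores.
- **Unconditional** (2-fold CV): the test fold is predicted with factor
  scores drawn from their standard-normal prior — covariate information only.
- **Conditional** (2-fold CV): for each posterior draw (an evenly spaced
  subsample, default 100), an inner Gibbs chain (default 50 burn + 100 draws)
  samples the test samples' factor scores given the *non-focal* guild's
  observed occurrences (truncated-normal augmentation) and abundances (used
  where present); the focal guild is then predicted from the conditioned
  scores. Conditioning on nothing reproduces the unconditional prediction up
  to Monte-Carlo error (tested).

Occurrence predictions are scored per species by AUC (Mann–Whitney, ties ½;
species with a single observed class are skipped with a notice and per-species
values are reported unclipped, so out-of-sample AUC may fall below 0.5);
abundances by `R² = 1 − SSE/SST` on the standardized log scale (negative
values possible out of sample). Species absent from a training fold are
excluded from the evaluation averages (they stay in the model — refitting a
reduced model per fold would make the folds' association matrices
incomparable). The **directionality statistic** is the guild-mean conditional
minus unconditional power: the information value of one guild for predicting
the other. One seeded 2-fold split is the default; simulations in the test
suite replicate over seeds.

Community diagnostics: per-guild richness is regressed on sequencing depth
and the residuals correlated between guilds; Bray–Curtis dissimilarities on
relative abundances are correlated between guilds, with a parametric t for
comparability and a Mantel permutation p (999 permutations) as the
recommended inference, since sample pairs are not independent.

## The synthetic-data generator

`simulate_community` is the generative mirror of the fitted model: covariate
niches, shared sample-level factors with per-guild loading scales, probit
occurrence, lognormal abundance given presence. Defaults mirror the study
conditions: 118 samples; 452/570 OTUs per guild (post-filter scale); tree
species drawn at the study frequencies 39/36/43 (beech/fir/spruce) and decay
classes at 21/39/36/22; per-guild read depths lognormal in the low thousands
to low tens of thousands; 3 factors. Continuous covariates use ranges typical
of decomposing temperate deadwood (water ≈ 45 ± 12 %, pH ≈ 4.6 ± 0.6,
C ≈ 48 ± 2 %, N lognormal around 0.2 %, lignin ≈ 27 ± 5 %, DBH uniform
30–100 cm).

The model itself specifies no count law (it models transformed counts), so
counts are constructed by exponentiating the latent abundances, normalizing
each sample to its target depth, rounding half-up with a floor of 1 where
present — one admissible choice that preserves the lognormal structure the
model assumes. A sample that draws no presences in a guild gets its
highest-liability species forced present with count 1, so depths stay
positive; this only matters at tiny test sizes. `make_asymmetric_scenario`
sets bacterial loadings to three times the fungal ones (0.5 vs 1.5): bacteria
track the shared factors strongly while fungal variation is covariate-
dominated, producing a known-sign directional signal — conditioning on fungi
helps predict bacteria far more than the reverse.

What the generator does **not** emulate: compositional (multinomial)
coupling between species counts beyond the shared depth normalization,
taxonomic structure, phylogenetic signal, spatial autocorrelation among logs,
and sequencing error. Passing tests therefore demonstrate that the estimation
and evaluation machinery recovers the truth *under the model's own
assumptions*, not that those assumptions hold for any particular field
dataset.

## Numerical choices and degenerate inputs

- OTU filter: prevalence strictly `>` its threshold, maximum relative
  abundance `≥` its threshold (mirroring ">10 %" / "at least 0.5 %").
- Abundance transform: natural log of the raw count, z-scored per OTU over
  presences; scaling parameters are stored so log counts can be recovered
  exactly. OTUs with fewer than two presences or zero log-count variance are
  flagged degenerate: their abundance column is centred at zero, excluded
  from R² averages, and their scale is reported as undefined.
- Factor-score summaries are sign-aligned per factor (largest-|loading|
  convention) before averaging; `R` itself is sign-invariant.
- Stacked small linear systems are solved by explicit inversion +
  symmetrization + Cholesky; dimensions never exceed the covariate count.
- A rank-deficient design or non-finite Gibbs update aborts with the
  offending column identified.

## Problem sizes used by the checked examples

Desk-scale conditions are used throughout the automated checks, chosen to
make the statistical assertions sharp at interactive cost: parameter recovery
at 30+30 species × 150 samples × 3 factors (2 chains × 5,000 iterations);
directionality over 10 replicate seeds at the same data scale (1 chain ×
1,500 iterations each); null calibration at 15+15 × 80; the
environment-versus-interaction contrast at 15+15 × 100. The acceptance script
runs the full pipeline at 40+40 species × 118 samples.

## Known limitations

- No adaptive factor-count selection; users choose `n_factors`.
- The conditional predictor subsamples posterior draws; very small
  `outer_draws`/`inner_draws` add Monte-Carlo noise to conditional gains.
- The null-model conditional regime conditions through the null model's own
  association matrix (the machinery is regime-agnostic); whether that matches
  any particular published workflow is not guaranteed.
- Spatial/temporal random effects, traits, and phylogeny are out of scope.
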