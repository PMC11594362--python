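# Methods

## The model

The pipeline estimates where each species in a community occurs, despite
imperfect detection, and then classifies every species by rarity.

**Occupancy layer.** For species *i* at 1-km grid cell *j*, true presence
is a Bernoulli draw

    z_ij ~ Bernoulli(psi_ij),    logit(psi_ij) = x_j' beta_i  [+ lambda_i' w_j]

with `x_j` the z-scored site covariates.  Replicated surveys give the
detection layer

    y_ijk ~ Bernoulli(z_ij * p_ijk),   logit(p_ijk) = alpha_i0 + alpha_i1 * v_jk

where `v_jk` is the number of visits in replicate *k* — a surrogate for
sampling effort.  Species coefficients are community random effects,
`beta_i ~ N(mu_beta, diag(tau_beta))` and `alpha_i ~ N(mu_alpha,
diag(tau_alpha))`, which is what lets sparsely detected species borrow
strength from the community.  The latent-factor variant (LFMSO) adds
`lambda_i' w_j` with `w_j ~ N(0, I_q)`, soaking up residual cross-species
correlation that the covariates miss; `q = 0` recovers the plain MSO.

**Identifiability.** The loading matrix's top q x q block is constrained
lower-triangular with unit diagonal (free entries `N(0, 1)` a priori).
This pins the scale and sign of each factor, so loadings are sign-stable
across chains and directly comparable to simulated truth.

**Priors.** Community means get `N(0, 2.72)` (roughly flat on the
probability scale through the logit link), community variances
`InverseGamma(0.1, 0.1)`.  All four hyperparameters are configurable in
`PriorSpec`.

## Sampling

All Bernoulli-logit conditionals are made conjugate by Pólya-Gamma
augmentation: with `omega ~ PG(1, eta)` the coefficient updates are
Gaussian, giving a full Gibbs sweep over `beta`, loadings, factors,
`z`, `alpha` and the community hyperparameters.

Two PG samplers are implemented in-package:

- `pg.sample_pg` — the exact Devroye rejection sampler for PG(1, z),
  as a compiled scalar kernel (numba) with a mask-vectorized numpy
  fallback; tests compare both against the infinite sum-of-gammas
  construction (KS tests) and closed-form moments.
- `pg.sample_pg_sum` — PG(b, z) for integer b via the truncated
  sum-of-gammas with the tail replaced by its exact mean
  (`sum 1/((k-1/2)^2 + a^2) = (pi/2a) tanh(pi a)`).  Detection cells
  sharing a (species, visit-count) linear predictor only enter the
  `alpha` update through the *sum* of their augmentation variables, so
  one PG(group-size, eta) draw per group replaces thousands of PG(1)
  draws.  The neglected tail variance is O(b / n_terms^3) — about 1e-6
  of the total at the default 64 terms — far below Monte-Carlo noise.

Missing (site, replicate) cells — `visits == 0` — are skipped by the
detection likelihood; `z` is still sampled at those sites.  `z` is pinned
to 1 wherever the species was detected (the model allows no false
positives).

A random-walk Metropolis variant of the coefficient updates
(`algorithm="metropolis"`, q = 0 only) exists purely as a cross-check;
a KS test on community-mean marginals verifies the two samplers target
the same posterior.

**Convergence protocol.** Monitored quantities are the community means
and variances plus every species-level coefficient.  A run converges
when all split-chain Rhat < 1.1 and all ESS > 100 (ESS via arviz; split
Rhat implemented directly, floored at 1.0, with the 0/0 constant-chain
case defined as 1.0).  A non-convergent run is retried with samples,
burn-in and thinning all doubled, up to `max_doublings`.

**Model criticism.** WAIC is computed on the deviance scale,
`-2 (lppd - p_waic)`, over (species, site) units with the latent presence
state marginalized out per draw:

    L_ij = psi_ij * prod_k Bern(y_ijk | p_ijk) + (1 - psi_ij) * [no detection at j]

Marginalizing z is essential for model comparison: conditioned on the
sampled z, the detection likelihood no longer involves psi, so the
occupancy layer — where the latent factors live — would drop out of the
criterion entirely and the MSO/LFMSO comparison would be blind to the
factors.  The Bayesian
p-value uses a site-grouped chi-square discrepancy
`sum_j (O_j - E_j)^2 / (E_j + 1/2)` on per-site detection totals,
comparing observed data against per-draw replicates; the 1/2 guards empty
expectations.  Values in (0.05, 0.95) indicate adequate fit.

**Prediction.** Occupancy at unfitted sites marginalizes the latent
factors by drawing `w_new ~ N(0, 1)` per posterior draw — there is no
spatial model linking new sites to fitted factors.  Richness is the
posterior mean of `sum_i z_ij`, which is bounded below by the observed
species count at each site because detections pin `z`.

## Rarity classification

Occupied cells are those with posterior-mean occupancy strictly above
0.5.  Three attributes per species:

- **Geographic range** — cells intersecting the convex hull of the
  occupied cells' unit-square footprints (footprints, not centroids, so
  collinear configurations still span positive area), times the cell
  area; species with <= 2 occupied cells use the summed cell area.
  Intersection is exact polygon-vs-square (shapely), counted over the
  hull's bounding box; boundary-touching cells with zero-area overlap do
  not count.
- **Area of occupancy (AOO)** — the occupied-cell count.
- **Habitat specificity** — Shannon entropy of habitat-cluster labels
  over occupied cells.

Median splits (strictly-above = wide/broad/large; ties at the median fall
to the rarer side, mirroring the strict occupancy threshold) yield the
2 x 2 x 2 Rabinowitz classes, NRS (rarest) through WBL (commonest).
Medians are taken over the classifiable species only.  Checklist species
with zero records are NO; species with records but no modelable
occupancy — below the 3-detection filter, or never above 0.5 — are DD.

Habitat clusters come from k-means (Lloyd, 10 seeded restarts) over
covariate subsets, selecting the (subset, K) pair maximizing the mean
silhouette; covariates are standardized first because mixed units make
raw Euclidean distances meaningless.  Ties prefer smaller K, then
shorter subsets.  Singleton clusters contribute silhouette 0.

## Survey-preparation rules

Species with fewer than three total detections are removed (and reported).
Zero-detection sites are removed unless total visits exceed the 95th
percentile (linear-interpolation quantile over all sites) — high-effort
empty sites are informative absences.  Candidate covariates must appear
in at least four prior studies and survive pairwise collinearity
screening: while any pair has |Pearson r| > 0.75, the lower-usage member
of the first offending pair is dropped (ties drop the later-input one).
Visit counts per (site, replicate) aggregate records by maximum, treating
each record as a survey-event summary.

## Synthetic study conditions

The generator runs the model hierarchy forward.  Defaults: N = 20
species, J = 200 sites, K = 4 replicates, P = 3 covariates, one latent
factor.  Community means (logit scale) are intercept 0 and slopes
(0.5, -0.5, 0.3) with variances 0.5 — the magnitude range observed for
community-level covariate effects in national freshwater-insect surveys —
and detection means (-1.0, 0.25) with variances (0.5, 0.05), giving
moderate per-replicate detectability that rises with effort.  Visit
counts are 1 + Poisson(2) per replicate, so every surveyed replicate has
at least one visit; the empirical distribution of real visit counts is
unknown, and the Poisson choice is a stand-in.  Covariates are iid
standard normal, re-standardized; spatial autocorrelation is available
as a Gaussian-blur option on the site grid but is off by default.

`degrade_to_survey` emulates survey pathologies without touching the
truth: a species-dropout fraction keeps at most two detections per
affected species (forcing them below the modelling filter), and an
effort-bias fraction halves visit counts at affected sites.

What the generator does *not* emulate: real covariate maps (rasters,
spatial gradients), observer heterogeneity, temporal trends within
replicates, or taxonomic misidentification.  Passing tests therefore
demonstrate the estimator's correctness under the model's own
assumptions, not robustness to the full messiness of field data.

## Evaluation studies and problem sizes

The studies module fixes the problem sizes used by the validation suite
and the reproduction script:

- **Recovery** — 20 seeded replicates of the default community, fitted
  with q = 1 at 3 chains x 2000 samples (burn 1000, no thinning).  Each
  component of `mu_beta` should fall in its central 95% credible interval
  in >= 17 of 20 runs (binomial tolerance around 19/20).
- **Model selection** — 5 seeds of the default latent-factor community;
  WAIC(LFMSO) < WAIC(MSO) expected in >= 4/5.
- **Goodness of fit** — one well-specified fit (p-value inside
  (0.05, 0.95)) against a deliberately broken perfect-detection model
  (p = 1 over-predicts per-site totals; replicated discrepancies are then
  degenerate at zero, driving the p-value to the boundary).
- **Planted classification** — a 6-species community with a planted
  corner specialist (intercept -9, slopes +5/+5) and a planted ubiquitous
  generalist (intercept +3), two never-observed checklist entries, fitted
  end to end; the specialist must land in NRS, the generalist in WBL,
  and the ten-status partition must cover the checklist.
- **Typology recovery** — seven cluster centers separated only jointly
  in three informative covariates (every 2-covariate projection collapses
  a pair), two noise covariates; the silhouette grid search must select
  the informative subset at K = 7.
- **Null calibration** — Kruskal-Wallis rejection rate at alpha = 0.05
  over 1000 four-group null replicates, expected in 0.05 +/- 0.02.

Chain lengths here are deliberately desk-scale; the full survey-scale
protocol (3 chains x 60,000 samples, burn 30,000, thin 30) is available
through `McmcSettings` and interacts identically with the
doubling-on-non-convergence rule.

## Numerical conventions and edge cases

- Constant-chain Rhat = 1.0; constant-chain ESS = total draws (flagged).
- Likelihood values are floored at 1e-300 before logs in WAIC.
- Wilcoxon rank-sum p-values use exact enumeration for untied samples of
  <= 20, otherwise the normal approximation with continuity correction;
  Bonferroni multiplies by the number of pairs and caps at 1.  Pairs with
  a group of fewer than two values are reported untested (NaN).
- Shapiro-Wilk on constant data raises (the statistic is undefined).
- An all-equal median split puts every species in the lower group and
  warns.
- k-means requires K not to exceed the number of distinct rows; the
  typology search skips infeasible (subset, K) combinations and fails
  only if the whole grid is infeasible.

## Known limitations

- Detection covariates are limited to the visit count; date and observer
  effects would need per-cell covariate support in the grouped-PG update.
- The latent-factor count q is fixed per fit; the `meaningful_factors`
  diagnostic reports which factors carry sign-consistent non-null
  loadings, but no automatic refit is performed.
- Prediction at new sites treats latent factors as exchangeable noise;
  with strong residual spatial structure this understates certainty
  at sites near fitted ones.
- The Metropolis cross-check covers q = 0 only.
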