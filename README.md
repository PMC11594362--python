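# odorare

Data-driven rarity assessment for replicated biodiversity surveys:
Bayesian multispecies occupancy models feeding the Rabinowitz rarity
framework.

## The problem

National survey programmes record where species were *detected*, not
where they *occur*: detection is imperfect, effort is uneven, and rare
species are chronically under-recorded.  Assessing rarity directly from
raw records conflates "rarely present" with "rarely found".  This package
implements the pipeline used to assess freshwater-insect (Odonata-style)
communities on 1-km survey grids:

1. **Multispecies occupancy models** separate true presence from
   detection.  Presence of species *i* at site *j* is
   `z_ij ~ Bern(psi_ij)`, `logit(psi_ij) = x_j' beta_i + lambda_i' w_j`,
   with community random effects `beta_i ~ N(mu_beta, T_beta)` and an
   optional latent site factor `w_j` with species loadings `lambda_i`
   (the LFMSO variant; `q = 0` gives the plain MSO).  Detection across
   replicates is `y_ijk ~ Bern(z_ij p_ijk)`,
   `logit(p_ijk) = alpha_i0 + alpha_i1 v_jk` with visit count `v_jk` as
   the effort covariate.  Fitting is by Gibbs sampling with Pólya-Gamma
   augmentation (implemented in-package), with split-Rhat/ESS convergence
   gates, an automatic doubling retry, WAIC model selection, and a
   site-grouped posterior-predictive check.
2. **Rabinowitz classification** reduces each species' predicted
   occupancy surface (cells with posterior-mean psi > 0.5) to geographic
   range (grid cells intersecting the minimum convex polygon of occupied
   cells), local population size (area of occupancy = occupied-cell
   count), and habitat specificity (Shannon entropy over k-means habitat
   clusters, `HS_i = -sum p_hc ln p_hc`).  Median splits yield the eight
   classes from NRS (narrow/restricted/small — rarest) to WBL
   (wide/broad/large — commonest); unmodelable species fall into NO
   (never observed) or DD (data deficient).
3. **Validation statistics** compare observation counts across status
   groups: Shapiro-Wilk normality gate, Kruskal-Wallis omnibus,
   Bonferroni-corrected pairwise Wilcoxon rank-sum tests.

Real national survey data of this kind are not publicly deposited, so the
package ships a synthetic-community generator with the exact statistical
structure the models assume; every stage is tested end to end against it.

## Worked example

```python
import numpy as np
from odorare.simulate import CommunityConfig, simulate_community
from odorare.detection import from_synthetic
from odorare.occupancy import McmcSettings, fit

cfg = CommunityConfig(seed=1)          # 20 species x 200 sites x 4 replicates
ds = simulate_community(cfg)
arr = from_synthetic(ds)

mso = fit(arr, ds.X, settings=McmcSettings(q=0, n_chains=3, n_samples=2000,
                                           n_burn=1000, n_thin=1, seed=10))
lfmso = fit(arr, ds.X, settings=McmcSettings(q=1, n_chains=3, n_samples=2000,
                                             n_burn=1000, n_thin=1, seed=11))
print(f"WAIC: MSO {mso.waic:.0f} vs LFMSO {lfmso.waic:.0f}")
print("community means:", np.round(lfmso.mu_beta.mean(axis=0), 2),
      "truth:", cfg.mu_beta)
```

prints (the data were generated with one latent factor, so the
latent-factor model wins decisively):

```
WAIC: MSO 10923 vs LFMSO 10766
community means: [-0.25  0.48 -0.34  0.32] truth: [ 0.   0.5 -0.5  0.3]
```

The WAIC gap (157 in favour of the latent-factor variant) is the model
selection signal; the community-mean estimates bracket the generating
values within posterior uncertainty.

The numbered drivers under `analysis/` run the full narrative — simulate
and degrade a survey (`01`), fit and compare both models, map richness
(`02`), select the habitat typology by silhouette (`03`), classify
rarity for a planted community (`04`), and compare observation counts
across status groups (`05`) — each writing its tables under `results/`.
Step `04`, for example, ends with the planted rare specialist in NRS,
the planted generalist in WBL, and the two never-observed checklist
species in NO.

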