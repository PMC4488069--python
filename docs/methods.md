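# Methods

## The scientific problem

Free-floating plants (duckweeds and relatives — *Lemna*, *Spirodela*,
*Wolffia*, *Azolla*, *Eichhornia*) are an ecologically consequential but
species-poor functional group in temperate lakes and ponds. In a regional
survey many water bodies hold none of them. Two mechanisms can produce that
pattern: local environmental filtering (floating plants need high-nutrient,
low-clarity water), and plain sampling — a group with few member species is
absent from many sites even under fully random community assembly. The
package implements both sides of that comparison: occurrence models that
quantify the environmental signal, and a species-pool permutation null that
quantifies the random-assembly expectation.

## Occurrence modelling

Presence of a taxon (or of any member of the group) across n sites is
modelled by logistic regression on site covariates. Covariates are first
mapped affinely onto [0, 1] (min → 0, max → 1) so coefficient magnitudes are
comparable across measurement scales; a constant covariate cannot be
rescaled and is dropped with a warning.

All 2^p predictor subsets (including intercept-only) are fitted and ranked
by the small-sample Akaike criterion

    AICc = -2·ℓ + 2k + 2k(k+1)/(n − k − 1),

with k the number of estimated parameters including the intercept. Models
with ΔAICc strictly below 2 form the candidate set; Akaike weights
w_i ∝ exp(−Δ_i/2) are renormalized within it. Averaged coefficients are
computed in both conventions:

* **full** — a model lacking a term contributes a zero estimate (shrinks
  terms that appear in few models); this is the headline variant;
* **conditional** — averaging only over models containing the term.

The unconditional standard error of an averaged term is
Σ_i w_i · sqrt(var_i + (β_i − β̄)²), with zero-variance zero-estimate
pseudo-entries included in the full variant. A term is flagged significant
when 0 lies outside estimate ± 1.96·SE. Predictions from the averaged model
default to the weight-averaged member probabilities
Σ_i w_i · logistic(X β̂_i), which is well defined under the logit link; a
coefficient-averaging mode is provided as a config switch because either
reading of "averaged model predictions" is defensible.

Fitting is IRLS (statsmodels GLM, binomial family, tolerance 1e−8, max 100
iterations). Complete or quasi-complete separation is flagged (caught
exception/warning, or |β̂| > 100 on unit-scaled data, or non-finite SEs) and
the subset is excluded from ranking rather than aborting the search. AICc
ties resolve by enumeration index (binary counting on column order), so
output is deterministic.

Diagnostics: one-step Cook's distance D_i = r_i² h_i / (k (1 − h_i)²) with
Pearson residuals and hat values from the IRLS-weighted design; sites above
a configurable threshold (default 0.9) are *reported* for analyst-confirmed
exclusion, never dropped automatically. Explained variation is the
likelihood-ratio pseudo-R² (Cox–Snell, 1 − exp(−(2/n)(ℓ₁ − ℓ₀))) with the
Nagelkerke rescaling also reported, computed for the lowest-AICc model.

## Classification evaluation

Predicted probabilities become presence calls at threshold t (present iff
p ≥ t). The operating threshold maximizes sensitivity + specificity over the
grid {0, 0.005, …, 1}; tied grid points are averaged, which is why optimal
thresholds can carry three decimals. Performance is summarized by the 2×2
confusion matrix (rows predicted, columns observed), PCC = 100·(TN+TP)/n,
and Cohen's kappa (P_o − P_e)/(1 − P_e). The kappa standard error uses the
simple large-sample formula sqrt(P_o(1−P_o)/(n(1−P_e)²)) and is informative
only — published kappa dispersions are often computed by other recipes, and
no attempt is made to match any particular one.

## Species-pool permutation null

Given the occupancy frequencies k_1…k_T of *all* taxa in the survey (the
focal group's members included), one null iteration draws S counts with
replacement, assigns each pseudo-species to that many distinct sites
uniformly at random (independently across species — no competition, no
filtering), and records the fraction of sites with zero pseudo-species.
B iterations (default 2000) give the null mean and a percentile 95%
interval; an observed prevalence of absence gets a two-sided empirical p
(2 × the smaller tail proportion, with add-one correction). Because species
are placed independently, the expectation conditional on the drawn counts is
exactly Π_i (1 − k_i/n); this closed form is the oracle the Monte-Carlo
machinery is tested against. For a single species the empty fraction is
deterministic, (n − k)/n — a useful degenerate check.

## Derived predictors

* Shoreline development index L/(2·sqrt(πA)) — shoreline length over the
  circumference of the equal-area circle; 1 for a circle, scale-invariant.
* Great-circle (haversine) distances at Earth radius 6371.0088 km; a planar
  Euclidean mode exists for synthetic grids.
* Neighbour counts within a radius use a closed ball (d ≤ r) and always
  exclude the focal site.
* Distance to the nearest *other* occupied water body excludes the focal
  site even when itself occupied, and is a missing value (never zero) when
  no other site is occupied.
* The collinearity screen reports Pearson |r| ≥ threshold (default 0.7) for
  all covariate pairs — point-biserial for binary covariates is numerically
  Pearson on the 0/1 coding — sorted by |r|; it only reports, the analyst
  decides what to drop (typical outcome: alkalinity falls to conductivity/pH,
  maximum depth to Secchi depth/size).

## Environmental PCA

Eigendecomposition of the correlation matrix of the chosen site variables
(centred, scaled, ddof = 1). Components are ordered by eigenvalue; within
each component the largest-magnitude loading is made positive (loadings are
defined only up to reflection). Scores are exactly centred with sample
variances equal to the eigenvalues. Rows with missing values are dropped
with a log message.

## Synthetic surveys

The generator emulates the structures the analysis assumes, with defaults
set to the study conditions: 176 water bodies, 124 taxa, a 6-member floating
group.

* **Occupancy frequencies**: truncated log-normal on occupied-site counts,
  support [1, 176], location 2.48122 and scale 1.0. The location was solved
  so the exact mean of the rounded, truncated law is 19.0 sites — the
  occupancy level at which a single random species leaves ≈ 89% of sites
  empty, the regime the survey sits in. Sampling is inverse-CDF on the
  truncated continuous law, then rounding.
* **Covariates**: coordinates uniform in a Connecticut-sized box; each
  covariate is a linear blend of two shared latent spatial fields
  ("chemistry" driving conductivity/alkalinity/pH/total phosphorus and
  opposing Secchi depth; "morphometry" driving size/depth/shoreline/Secchi)
  plus a covariate-specific field. Every field is an exponential-covariance
  Gaussian process (corr = exp(−d/ρ), default range ρ = 30 km, dense
  Cholesky — fine for the ≤ ~2000-site surveys used here) mixed with iid
  noise (default fraction 0.3 of variance), then pushed through a log-normal
  or normal marginal with plausible limnological ranges (e.g. total
  phosphorus median 0.025 mg/L, conductivity median 150 µS/cm). The shared
  latents give the collinearity screen and the PCA realistic structure.
* **Group presences**: logistic on unit-rescaled covariates with defaults
  intercept −2, totalP +5, cond +5, secchi −5, plus per-member intercept
  offsets (0, −1.1, −1.6, −3.6, −4.0, −4.6) producing the common-to-rare
  occupancy gradient (roughly 56/31/23/≤4 of 176). True probabilities are
  returned for recovery tests.
* **Remaining taxa**: placed at random with sampled occupancy counts —
  exactly the null model's assumption, so null-model calibration tests have
  ground truth.
* Derived spatial predictors (lakes within 1/10 km, distance to nearest
  occupied site for the three common members) are computed from the
  generated geometry, as a GIS workflow would.

One root seed streams all randomness (numpy `SeedSequence.spawn`), so a
config and seed reproduce every output byte-for-byte.

What the generator does **not** emulate: river connectivity between water
bodies, repeat-survey structure, detection error, and taxon-level
co-occurrence structure beyond shared environmental drivers. Tests passing
on synthetic data therefore validate the machinery and its statistical
calibration, not the ecological conclusions for any real region.

## Problem sizes and numerical choices

Unit tests run on 40–300-site surveys; recovery experiments use 2000 sites
× 200 replicates with iid covariates (the GP adds nothing to a coverage
check and a 2000² Cholesky per replicate would be wasteful); Monte-Carlo
oracle comparisons use B = 10 000 with 3-standard-error bands; pipeline
tests use 60 sites and B = 100. The full default pipeline (four responses ×
2^12–2^13 subsets, B = 2000) runs in about 90 s.

Degenerate inputs: constant predictors are rejected by the rescaler and
excluded from screens; separation flags instead of failing; kappa with
degenerate marginals (P_e = 1) returns NaN with a warning; a group with no
observed member taxa is vacuously absent everywhere (empty proportion 1);
thresholds outside [0, 1] and AICc with n ≤ k + 1 raise.

## Open design choices taken

* Full-average coefficients are the headline (the convention of the widely
  used multimodel-inference tooling); conditional is always computed too.
* Both Cox–Snell and Nagelkerke pseudo-R² are reported; Cox–Snell is the
  default headline.
* The null model's frequency pool includes all taxa, focal group included;
  CI is the empirical percentile interval.
* The collinearity screen is advisory; predictor exclusions are config
  entries, not hard-coded.
* The printed shoreline-index formula in survey literature sometimes omits
  the square root; the dimensionless form L/(2√(πA)) is used so a circle
  scores exactly 1.

## Known limitations

* No interaction terms, no spatial autoregressive occurrence models, no
  ROC/AUC, no richness (Poisson) models — out of scope for this version.
* The one-step Cook's distance approximates case-deletion refits; exact
  refits can be run manually for verification.
* The kappa SE variant is intentionally simple (see above).
* The null model's pluggable pieces (weighted frequency sampling,
  co-occurrence-constrained assignment) are hooks for future extensions,
  not implemented.
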