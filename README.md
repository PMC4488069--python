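# lemna

Why is an uncommon functional group — free-floating plants such as duckweeds
(*Lemna*, *Spirodela*, *Wolffia*) — present in some lakes and ponds and
absent from most others? `lemna` implements the two complementary analyses a
regional presence/absence survey supports:

* **Occurrence models.** Logistic regression of presence on site conditions,
  with an all-subsets search ranked by the small-sample Akaike criterion
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), Akaike-weight averaging of all models
  within 2 AICc units of the best (w_i ∝ exp(−Δ_i/2)), and threshold-based
  classification evaluation: optimal threshold by maximum sensitivity +
  specificity, confusion matrix, percent correctly classified, and Cohen's
  kappa = (P_o − P_e)/(1 − P_e).
* **Species-pool permutation null.** Is the fraction of sites lacking the
  group surprising, or what random assembly predicts for a pool of S
  species? Each iteration samples S occupancy counts (with replacement) from
  the occupancy frequencies of *all* surveyed taxa, scatters each
  pseudo-species over that many random sites, and records the proportion of
  sites left empty — with the closed-form conditional expectation
  Π_i (1 − k_i/n) as a built-in oracle.

Supporting pieces: derived spatial predictors (shoreline development index
L/(2√(πA)), great-circle distances, neighbour counts, distance to nearest
occupied water body), a collinearity screen, correlation-matrix PCA of site
conditions, a synthetic survey generator with known ground truth (spatially
autocorrelated covariates, right-skewed occupancy frequencies, logistic
group presences), and a config-driven CLI. It is aimed at community
ecologists and biostatisticians working with site-by-taxon presence/absence
matrices; everything runs on plain CSV inputs.

## Worked example

```python
import pandas as pd
from lemna import synthetic, glm, evaluation, null_model
from lemna.predictors import rescale_unit_interval

# a survey with the default study conditions: 176 water bodies, 124 taxa,
# a 6-member floating-plant group driven by totalP (+), cond (+), secchi (-)
sites, occ, meta = synthetic.generate_survey(synthetic.SynthConfig(seed=7))

obs = null_model.observed_empty_proportion(occ, "floating")
X = pd.DataFrame({n: rescale_unit_interval(sites.covariate(n))
                  for n in ["totalP", "cond", "secchi", "pH", "boatlaunch"]})
y = occ.group_presence("floating").to_numpy()

cand = glm.candidate_set(glm.all_subsets(X, y))   # dAICc < 2
avg = glm.model_average(cand)
probs = glm.predict_average(avg, X)
t = evaluation.optimal_threshold(y, probs)
ev = evaluation.confusion_matrix(y, probs, t)

null6 = null_model.permutation_null(occ.occupancy().to_numpy(), 6, 176,
                                    iterations=2000, seed=7, observed=obs)

print(f"sites without floating plants: {100*obs:.1f}%")
print(f"candidate models (dAICc < 2): {len(cand)}")
for term in avg.terms:
    star = "  *" if avg.significant()[term] and term != "intercept" else ""
    print(f"  {term:10s} {avg.full[term]:+.2f} (SE {avg.se_full[term]:.2f}){star}")
kappa, _ = evaluation.cohen_kappa(ev)
print(f"optimal threshold {t:.3f}: PCC {evaluation.percent_correct(ev):.1f}%, "
      f"kappa {kappa:.3f}")
print(f"null (S=6): mean {100*null6.mean:.1f}%, 95% CI "
      f"{100*null6.ci_lo:.1f}-{100*null6.ci_hi:.1f}%, p = {null6.p_value:.2f}")
```

Output:

```
sites without floating plants: 56.2%
candidate models (dAICc < 2): 4
  intercept  -0.68 (SE 0.77)
  cond       +4.91 (SE 1.31)  *
  secchi     -8.75 (SE 1.93)  *
  pH         +1.29 (SE 1.42)
  boatlaunch +1.37 (SE 0.59)  *
  totalP     +0.74 (SE 1.39)
optimal threshold 0.390: PCC 77.8%, kappa 0.556
null (S=6): mean 53.3%, 95% CI 19.9-79.5%, p = 0.96
```

Reading: 56.2% of the 176 simulated water bodies hold no floating plant.
The averaged model recovers the generating physics — conductivity up,
Secchi depth (water clarity) down — with coefficients on unit-rescaled
covariates, and classifies 77.8% of sites correctly at its optimal
threshold (kappa 0.556, i.e. well above chance agreement). The permutation
null says a random 6-species pool would leave 53.3% (CI 20–80%) of sites
empty, so the observed 56.2% is entirely unsurprising (p = 0.96): for a
group this small, prevalence of absence alone carries little evidence of
environmental filtering — the model coefficients, not the absence rate, are
where the signal lives.

## Command line

```sh
lemna all --seed 1 --out run1          # full pipeline on synthetic defaults
lemna simulate --seed 1 --out data     # write survey CSVs
lemna screen --config cfg.yaml --out run1
lemna fit --config cfg.yaml --out run1
lemna evaluate --predictions run1/predictions_floating_group.csv --out run1
lemna nullmodel --pool-sizes 1,6,12,24 --seed 1 --out run1
lemna pca --config cfg.yaml --out run1
```

`lemna all` emits, per response, the candidate-model table, averaged
coefficients, per-site predicted probabilities and the threshold evaluation,
plus the collinearity report, null-model samples and summary, PCA loadings
and scores, and a `summary.json` recording the seed and config hash. The
same config and seed reproduce every output file byte-for-byte. Real
surveys enter through `input_paths` in the YAML config (sites, occurrence
and taxon-group CSVs — see `lemna.io`).

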