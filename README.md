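# sensetraits

Which sensory modalities predict quantitative autistic traits? Sensory
processing differences (visual, auditory, tactile, olfactory, gustatory,
proprioceptive, vestibular) correlate with continuously distributed
autistic traits in the general population, but the modalities are
themselves strongly intercorrelated, so naive per-modality regressions
cannot say which ones matter. `sensetraits` implements the two-stage
analysis used to answer this question on Likert questionnaire cohorts:

1. **Spike-and-slab stochastic search variable selection (SSVS).**
   A Bayesian linear regression of a trait subscale score on the seven
   modality subscale scores plus demographic covariates, where each
   standardized coefficient β_j has the mixture prior

   β_j | γ_j ~ (1 − γ_j)·N(0, spike²) + γ_j·N(0, slab²),  γ_j ~ Bernoulli(α),

   with α = 0.5, sampled by a Gibbs sweep (5000 burn-in of 20,000 total
   iterations). The marginal inclusion probability MIP_j = E[γ_j | data]
   selects predictors (threshold 0.5), and convergence is checked by the
   Pearson correlation of MIP vectors across two independently seeded
   runs (required ≥ 0.99). Selections can be intersected across
   independent cohorts.

2. **Monte-Carlo dominance analysis (DA) with a spurious-predictor
   null.** For the selected predictors, each predictor's *general
   dominance weight* is its incremental R² averaged over all subsets of
   the other predictors (weights sum exactly to the full-model R²).
   Weights are recomputed over 1000 bootstrap resamples of the
   respondents, each resample augmented with a freshly drawn
   standard-normal spurious predictor. The 95th percentile of the pooled
   spurious weights is the noise floor: **Sig** is the percentage of
   runs a predictor's weight exceeds it, and the pairwise matrix reports
   how often |w_A − w_B| exceeds it.

The package also scores the two instruments (three 12-item trait
subscales rated 1–6; seven 6-item sensory subscales rated 1–5 with two
rigid-overlap items removed, leaving 40 items; Cronbach's α; hyper/hypo
pooling), applies attention-check and diagnosis-flag screening, computes
the replication-stage Mann–Whitney / Spearman table, and ships a seeded
synthetic-cohort generator (correlated modality latents, graded Likert
items, planted modality→trait effects) so every stage is testable
without raw data.

## Worked example

```python
import pandas as pd
import sensetraits as st
from sensetraits.instruments import SENSORY_SUBSCALES

table, covariates, truth = st.generate_dataset(st.SimConfig(seed=42))
key = st.drop_overlap_items(table.key)
scores = st.score_subscales(table.responses, key)

X = pd.DataFrame({s: scores[s].to_numpy(float) for s in SENSORY_SUBSCALES})
for c in ["age", "adhd", "dcd", "anxiety", "mood", "gender_man", "gender_nonbinary"]:
    X[c] = covariates[c].to_numpy(float)
Xs, ys, _ = st.standardize_design(X, scores["aloof"].to_numpy(float))
Xs = pd.DataFrame(Xs, columns=X.columns)

r1, r2, r = st.two_run_ssvs(Xs, ys, st.SSVSConfig(), seed_pair=(1, 2))
print("stability r =", round(r, 4))          # stability r = 0.9995
sel = st.select_predictors(r1)               # ['auditory', 'gustatory']
res = st.run_mc_dominance(X[sel], scores["aloof"].to_numpy(float), st.DAConfig(seed=3))
print(res.to_frame().round(3))
```

prints the per-predictor dominance table

```
predictor  weight_mean  weight_ci_low  weight_ci_high  sig_percent  rank_mean
 auditory        0.133          0.068           0.209        100.0      1.214
gustatory        0.096          0.043           0.165        100.0      1.786
```

with full-model R² = 0.232 [0.145, 0.326]. Here the auditory subscale
(planted as the strongest generating effect) carries the largest mean
weight, is significantly above the spurious noise floor in 100% of
runs, and holds the best average rank; the bracketed values are 2.5/97.5
percentile bootstrap intervals.

The full two-cohort study replica (screen → score → SSVS ×3 outcomes ×2
runs → cross-cohort selection intersection → per-cohort DA → CSV/JSON
report) runs from a config file:

```bash
sensetraits run-study --config study.yaml --seed 7 --out report/
```

(`sensetraits simulate | score | ssvs | dominance` expose the individual
stages.)

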