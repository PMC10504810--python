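# Methods

## Instruments and scoring

Two Likert instruments are modelled. The trait questionnaire has three
12-item subscales — aloof (social interaction), pragmatic
(communication), rigid — rated 1–6; subscale scores are plain item sums
(range 12–72), and the total is the sum of the three. The sensory
questionnaire has seven 6-item modality subscales rated 1–5, each item
tagged as probing hyper- or hypo-sensitivity. Two sensory items (an
auditory repeated-music item and a gustatory same-foods item) overlap
conceptually with the rigid trait construct; `drop_overlap_items` marks
exactly those two as removed before any modality→trait modelling,
leaving 40 scorable items with five-item auditory and gustatory
subscales. Hyper and hypo sums pool the tagged items (20/20 after
removal in the synthetic key); only pooled modality scores feed the
inference.

Cronbach's α uses population (divide-by-n) variances throughout:
α = k/(k−1)·(1 − Σ var(itemᵢ)/var(sum)). α is invariant to the shared
variance convention; fixing one makes tests bit-exact. Missing or
out-of-range responses are hard errors naming the respondent and item —
no imputation. Reverse-keyed items are supported through a per-item
flag but the synthetic instruments are all positively keyed.

Screening applies declared rules in order, first match wins: an
attention rule (any check item answered off its stored correct
alternative) and flag rules (binary diagnosis columns). The log records
one reason per removed respondent.

## Synthetic cohorts

The generator draws, per respondent:

- seven modality latents from N(0, R) with R a 7×7 correlation matrix
  (default: 0.4 off-diagonal — the moderate-to-strong intercorrelation
  sensory subscales typically show);
- covariates: age ~ N(34.1, 11.6²); a 4-level gender categorical
  (woman .575 / man .361 / non-binary .052 / other .012) dummy-coded
  against the woman reference, with "other" never dummy-coded; binary
  diagnosis flags (ADHD .064, DCD .079, anxiety .384, mood .306),
  independent of the latents by default;
- three trait latents T = P·Bᵀ + σε, where P stacks the standardized
  predictors (latents are standard by construction; age and binaries
  are standardized by their theoretical moments so B is a matrix of
  true standardized coefficients), σ = 0.85 by default;
- items from a one-factor graded model: item = λ·latent +
  √(1−λ²)·unique noise, thresholded at equally spaced standard-normal
  quantiles (symmetric categories, absent any constraint on item
  distributions). Default loadings are per-instrument: λ = 0.55 for
  sensory items and λ = 0.7 for trait items. A single shared loading
  cannot reproduce both reliability bands at once — λ = 0.7 pushes a
  6-item five-point subscale to α ≈ 0.83 while λ = 0.55 gives α ≈ 0.69
  and, with 12 six-point items, α ≈ 0.82; the split defaults land
  sensory subscales near α ≈ 0.63–0.71 and trait subscales near
  α ≈ 0.90, the moderate/high bands such instruments report;
- attention checks answered correctly, then a seeded fraction
  (default 3.5%) of respondents flips one randomly chosen check.

Default planted effects make the auditory modality dominant for every
trait (0.35, plus one 0.15 secondary modality and a 0.10 covariate per
trait), echoing the qualitative pattern the analysis is designed to
detect. Everything regenerates bit-for-bit from the config seed.

What the generator does *not* emulate: differential item functioning,
missing data, non-normal latents, floor/ceiling asymmetries,
latent–covariate confounding (an optional hook aside), or
acquiescence/reversal artifacts. Passing recovery tests therefore show
the pipeline recovers the assumed linear-factor structure — not that
real questionnaire data satisfy it.

## SSVS sampler

Standardization: every predictor column and the outcome are centered
and scaled to SD 1 (ddof = 1). Binary dummies are standardized like
everything else so one slab scale is comparable across predictors; the
intercept is handled by centering (none is sampled). `run_ssvs` rejects
designs whose column means exceed 1e-8.

The Gibbs sampler sweeps j = 1..p in fixed order each iteration:
γ_j | β_j from the Bernoulli posterior odds of slab vs spike density at
the current β_j; β_j | γ, σ² from its conjugate normal given the
partial residual; then σ² | β from InvGamma(a₀ + n/2, b₀ + RSS/2).
Defaults: prior inclusion 0.5, burn-in 5000 of 20,000 iterations,
spike SD 0.01, slab SD 1.0, a₀ = b₀ = 0.01. The continuous spike keeps
all conditionals conjugate; on the standardized scale spike SD 0.01
makes "included" mean |β| ≳ 0.02. MIPs are indicator means over the
15,000 retained draws; `mip_mc_se` provides batch-means Monte-Carlo
SEs that respect chain autocorrelation. A single seeded stream and the
fixed sweep order make runs bit-reproducible. The inner loop is
numba-compiled; a 20,000-iteration run on n = 252, p = 13 takes well
under a second, so the two-run stability correlation (pass bound 0.99)
is cheap to require everywhere.

Each trait outcome is analyzed in its own SSVS run; selections
(MIP > 0.5, computed on the mean of the two runs' MIPs) can be
intersected across any number of cohorts.

## Dominance analysis

`general_dominance_weights` decomposes R² from a correlation matrix:
for each predictor, the incremental R² of adding it to a subset of the
others is averaged within each subset size, then across sizes. All 2^p
subset R² values are computed by (batched) linear solves, with a
pseudoinverse fallback and warning for singular submatrices; p is
capped at 20 by an explicit guard. The decomposition telescopes, so the
weights sum to the full-model R² to ~1e-15 per run.

The Monte-Carlo layer interprets "simulated runs" as a nonparametric
paired bootstrap of respondents (a parametric-Gaussian alternative is a
config switch): each of 1000 runs resamples n rows, appends a freshly
drawn standard-normal spurious predictor, and computes weights from the
run's own correlation matrix (correlations are scale-free, so no
re-standardization is needed). Runs with a constant resampled column
are redrawn (≤10 times, logged). Reported per predictor: mean weight
with 2.5/97.5 percentile CI, mean per-run rank (average-rank ties,
spurious excluded from ranking) with percentile CI, Sig, and the
pairwise percentage matrix; plus full-model R² mean and CI.

**Calibration caveat.** The noise floor q is the 95th percentile of the
pooled spurious weights. The spurious predictor embodies *per-run*
sampling noise only, while a fixed null column's bootstrap weights also
carry the dataset-level luck of its observed sample correlation. A
truly null fixed predictor therefore shows Sig with expectation
≈ P(|N(0,√2)| > z₀.₉₅) ≈ 16% — not the nominal 5% — with wide spread
across datasets (our simulations: mean 16%, per-dataset values 6–40%).
Only a predictor *regenerated* each run like the spurious one sits at
the nominal 5%. Sig values for weak predictors should be read with
this inflation in mind; no within-dataset rule can remove dataset-level
luck.

For the same reason, which of two predictors with moderately different
planted effects attains the top *mean* weight in a given cohort is
itself a random variable: at n ≈ 250 with inter-modality correlation
0.4 and Likert attenuation, a 0.5-vs-0.2 standardized gap leaves a
~8% chance per cohort×outcome analysis that the secondary predictor
tops the ranking. Joint "top rank everywhere" claims across six
analyses succeed in only ~60% of replications under those conditions.

## Pipeline

`run_study` screens, scores, and analyzes any number of cohorts. Every
stage seed derives from the master seed as
SHA-256(master:stage:cohort:outcome) mod 2³¹, giving independent,
forever-reproducible streams. Per cohort×outcome the SSVS runs twice;
a stability correlation below 0.99 marks the outcome FAILED (diagnostic
logged, DA skipped). DA runs on each cohort's own selection; an empty
selection is recorded as "no predictors selected". The non-binary
gender dummy is retained even when sparse, with a warning below five
positives. The report bundle writes scores, exclusion logs,
reliabilities, MIP tables, DA tables, pairwise matrices, optional
plots, and a JSON manifest of all seeds, stability values, and
versions.

The group-comparison table reports, per sensory scale (total + seven
subscales), per-group median ± SD (SD with ddof = 1 — the
median-with-SD pairing follows the reporting convention of the tables
this mirrors), min-U Mann–Whitney with midrank ties (exact enumeration
when n₁·n₂ ≤ 400 and tie-free, else the tie-corrected normal
approximation) and Spearman ρ against the trait total; raw p-values,
no multiplicity correction. The Shapiro–Wilk preliminary delegates to
scipy.

## Problem sizes used in the test suite

Statistical checks run at the cohort sizes the analysis targets
(n = 252/268, 13–14 predictors, 20,000-iteration chains, 1000 bootstrap
runs); replicate counts per property (20–100 seeds) were chosen to keep
binomial bounds meaningful. The whole suite runs in about a minute on
one core thanks to the compiled sampler and batched DA solves.

## Known limitations

- The spike/slab hyperparameters of the original online SSVS tool are
  not public; MIP magnitudes on real data shift with them.
- The per-run significance rule and resampling scheme of the cited DA
  procedure are declared choices behind config switches, with the
  calibration caveat above.
- No measurement-error disattenuation (low subscale reliabilities make
  disattenuated correlation matrices non-positive-definite), no
  conditional/complete dominance tabulations, no four-quadrant sensory
  profile scoring, no norm-referenced cutoffs.
- The hyper/hypo split of the synthetic key is a stand-in; the real
  instrument's item-level tagging is not inferred here.
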