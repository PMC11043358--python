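# Methods

## The problem

Large pharmacogenomic screens (GDSC, CCLE, CTRP, organoid libraries) report
drug sensitivity as absolute dose-response summaries — the half-maximal
inhibitory concentration (IC50), the area under the dose-response curve
(AUC), the normalized AUC, or the drug relevance score (IC50 divided by the
maximum therapeutic concentration). These measures are dominated by the
intrinsic potency or toxicity of each drug: two samples of entirely
different origin still show near-unit Pearson correlation between their
response profiles, simply because both profiles track the per-drug potency
spread. A model that predicts absolute response can therefore look accurate
while learning nothing about the sample. Per-drug z-scoring,
`Z[i, j] = (x[i, j] − mean_i) / sd_i` computed for each drug across all
samples it was tested on, removes the drug's systematic component and turns
the task into predicting *relative* sensitivity — the signal precision
oncology actually needs. This package implements the full chain needed to
study that contrast quantitatively, with a synthetic screen generator in
place of the (large, external) public datasets.

## The synthetic screen generator

`generate_screen` plants a known ground truth

```
ln IC50[j, i] = mu_i + f_j + u_{s(j), i} + Σ_g w_{i,g} · x_{j,g}
```

with `mu_i ~ N(0, drug_potency_sd²)` the per-drug mean log-potency,
`f_j ~ N(0, sample_factor_sd²)` a per-sample general-sensitivity
(multi-drug-resistance) factor, `u_{s,i} ~ N(0, subtype_effect_sd²)` a
per-(subtype, drug) effect, `x` standard-normal expression and `w` sparse
causal gene weights. Viability at concentration `c` follows the
two-parameter log-logistic (Hill) curve `v = 1 / (1 + (c/IC50)^h)` with
upper asymptote 1 and lower asymptote 0, plus Gaussian assay noise, clipped
to [0, 1.2] (screens do report >100% viability). The Hill form was chosen
because it is analytically invertible: every downstream fit can be checked
against the planted truth exactly.

Defaults (all standard deviations in natural-log concentration units):

| parameter | default | role |
|---|---|---|
| `n_samples` x `n_drugs` x `n_genes` | 50 x 30 x 200 | desk-scale screen |
| `drug_potency_sd` | 2.0 | between-drug spread; the dominant term |
| `sample_factor_sd` | 0.5 | general sensitivity / multi-drug resistance |
| `genetic_effect_sd` | 0.2 | per-gene causal effect scale |
| `subtype_effect_sd` | 0.3 | per-(subtype, drug) effect |
| `noise_sd` | 0.05 | viability assay noise |
| `hill_slope` | 1.0 | Hill coefficient h |
| `dose_grid` | 9 points, 1e-3 to 1e3 uM | log-spaced test concentrations |
| `coverage_fraction`, `coverage_sd` | 0.9, 0.05 | per-sample drug coverage |

With per-sample coverage around 0.9, an unordered sample pair shares on
average ~81% of the drug panel, matching the overlap regime of large public
screens. Coverage rates are drawn from a Beta distribution matched to
(mean, sd); each drug is then dropped independently per sample.

Design choices worth knowing:

* **Causal weights** are drawn as `genetic_effect_sd · sign · U(0.5, 1.5)`
  rather than Gaussian, so every planted gene carries an effect of
  comparable, bounded-away-from-zero magnitude. A Gaussian would plant
  near-zero "causal" genes that no method could or should recover,
  making recall an ill-posed quantity.
* **Subtype structure** enters as a per-(subtype, drug) random effect, not
  as a shift of the per-sample factor. A per-sample constant cancels when a
  profile is centered, so it cannot change any profile correlation; a
  subtype-by-drug interaction is the minimal term that makes within-subtype
  pairs genuinely more correlated than between-subtype pairs.
* **Fingerprints** are 256-bit synthetic vectors in which drugs sharing a
  target-pathway label share a fixed bit-block, giving the Tanimoto
  similarity real structure without a cheminformatics dependency. Morgan
  fingerprints (radius 2, 2048 bits) can be computed from SMILES through
  the optional RDKit path.

What the generator does **not** emulate: gene-gene co-expression (genes are
independent), batch effects, dose-dependent assay artifacts, realistic
pharmacokinetics. Consequences of the first omission are discussed under
limitations.

## Measure derivation

`fit_ic50` fits the two-parameter log-logistic model (log-IC50, slope) by
bounded least squares, starting from the interpolated 50%-viability
crossing and falling back to a 5-point multi-start over the dose range when
the first fit leaves a mean squared residual above 0.02 per dose point.
IC50 is carried as natural-log IC50 throughout; slopes are bounded to
[0.05, 20] and log-IC50 to the tested range ±6 log units. A fit outside the
tested concentration range (e.g. a flat curve) is returned with an
`extrapolated` flag, never as NaN. AUC is the trapezoidal integral of
clipped viability over log10(concentration); the normalized AUC divides by
the log10 span, so full survival gives exactly 1 and full kill 0. For all
shipped measures lower means more sensitive.

## Profile correlation

For samples j, k the Pearson (or Spearman) correlation is computed over the
drugs observed in both, with profile means taken over those shared drugs
only. Pairs sharing fewer than `min_shared = 10` drugs, or with a
zero-variance profile, are reported undefined with a reason and excluded
from summaries. Pairs are unordered (j < k canonical); self-pairs excluded.
Subtype stratification splits pairs into within- and between-subtype
groups; pathway restriction reruns the computation on one pathway's drugs.

## Per-drug z-scoring

Population standard deviation (divide by N) by default — the screened
sample set is treated as the reference population, matching how public
screens publish z-scores; `ddof` is switchable. Drugs with fewer than 3
observed values or zero variance are dropped with a warning naming them.
The transform is applied to the full matrix before CV splitting: the
z-score is treated as a property of the dataset, as it is in the published
resources. This has a measurable leakage consequence for the mean baseline:
because each drug's z-scores sum to zero over all samples, the train-set
mean of a drug is exactly the negated mean of its test-fold values, and the
per-sample correlation of the mean baseline is then centered near
−1/√n_test (≈ −0.32 for 5-fold CV of 50 samples) rather than 0. The
pan-drug models do not inherit this artifact. In the zero-shot transfer
setting the train-set z-means are exactly zero, the baseline's predictions
are constant, and its correlation is reported undefined — the honest
statement of the collapse.

## Gene selection

`CorrelationPruner` removes multicollinearity by agglomerative clustering
with complete linkage on `1 − |Pearson r|` distances, cut at distance 0.4
(i.e. |r| ≥ 0.6), keeping the highest-variance member of each cluster
(ties by lexicographic id) and repeating on the representatives until every
cluster is a singleton. Pairs whose correlation is not significant at
p < 0.05 are never linked. The contract — no retained pair with |r| ≥ 0.6
and p < 0.05 — is verified by an exhaustive post-hoc scan in the tests.

Five per-gene relevance scores are computed against one drug's responses,
all oriented so larger = more relevant: |Pearson r|, |Spearman rho|, mutual
information (k-nearest-neighbor estimator for continuous variables, k = 3),
the negated sum of squared residuals of a degree-2 polynomial fit, and the
absolute coefficients of a linear SVM regression fitted on all genes
jointly. `threshold_sweep` then evaluates 100 thresholds per score — equally
spaced quantiles of the score's empirical distribution, so the grid adapts
to any score scale — by cross-validated Pearson correlation of a single-drug
model (ridge, alpha = 10), breaking ties toward fewer genes.

**Two sweep protocols.** By default the relevance scores are recomputed
inside each training fold (`refit_scores_per_fold=True`), so no test
information touches selection; the reported gene set is then the full-data
set at the winning (score, quantile). The alternative,
`refit_scores_per_fold=False`, computes scores once on all samples — the
protocol implied by reported organoid analyses (average held-out Pearson
near 0.93 with hundreds of genes selected from thousands on a few dozen
samples is only reachable when selection has seen the full dataset). The
difference is large and worth measuring: on a pure-noise response the
full-data protocol manufactures a cross-validated Pearson around 0.3 where
the fold-internal protocol stays near 0.1, and on a planted-signal drug it
reports ~0.94 versus ~0.8. Both numbers are produced by the package's
tests; which protocol answers your question depends on whether you are
replicating a published pipeline or estimating honest generalization.

## Prediction models

* **DrugMeanRegressor** — per-drug train mean as the prediction for every
  test sample; blind to omics by construction (its real- and
  zero-filled-omics outputs are identical bit for bit).
* **BimodalKNNRegressor** — distance between (sample, drug) pairs is
  `w · (1 − Tanimoto(fp, fp')) + (1 − w) · ||e − e'|| / scale` with
  w = 0.5 and the expression distance normalized by the largest train-set
  distance, so both modalities live in [0, 1]; prediction is the mean
  response of the k = 5 nearest train pairs. Tanimoto of two all-zero
  fingerprints is defined as 1.
* **FeedForwardRegressor** — three fully connected hidden layers
  (256, 128, 64) with a linear output, MSE loss, early stopping, fixed
  seed; inputs are the concatenated fingerprint and expression vector
  (the fingerprint standing in for an encoded SMILES string).
* **Single-drug registry** — ridge (alpha = 10, the default), kNN, SVR
  (linear / RBF / polynomial), decision tree, random forest, MLP, all
  behind one name-addressed contract.

The zero-filled-omics ablation replaces every expression vector with zeros
at both fit and predict time, so a cell of the experiment matrix is one
coherent setting. The four-setting matrix crosses {raw, z-scored} with
{real, zero-filled} under sample-disjoint k-fold CV (folds share no
samples; sizes differ by at most one; seeded). Zero-shot transfer trains on
one screen and evaluates on another restricted to the shared drugs, with
expression harmonized by z-scoring each dataset per gene, concatenating,
and z-scoring the merged matrix once more.

## Ranking metrics

"Top" always means most sensitive, i.e. smallest measure value.
Precision@k is the fraction of the true top-k recovered in the predicted
top-k; ties at the k-boundary are broken by drug id after the value sort,
which trades a slightly pessimistic score for exact reproducibility.
NDCG@k maps each drug's response to a relevance
`(worst − value) / (worst − best) ∈ [0, 1]` over the sample's observed
drugs and uses the log2 positional discount, normalized by the ideal
ordering. Samples with fewer than k observed drugs, or an all-constant
profile, are reported undefined and excluded from aggregates with a
warning. Per-sample and per-drug Pearson/MSE are computed on observed test
cells; a constant predictor yields an undefined (NaN) correlation, never 0
or 1. k defaults to 5.

## Numerical choices

Curve fits use `scipy.optimize.least_squares` with box bounds; viability is
clipped to [0, 1.2] before fitting. Correlation of a vector with spread
below 1e-12 (relative) is treated as undefined. Z-score contracts hold to
1e-12; planted-truth identities to 1e-10. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; repeated runs
are bit-identical.

## Problem sizes used in the shipped checks

The acceptance-style checks run the default 50 x 30 screen (10 seeds for
the correlation phenomenon), a 200-sample x 1000-gene screen with 20
causal genes per drug for gene selection, 1000 genes for the
multicollinearity scan, and a 50-to-40-sample transfer pair. These sizes
keep a full run in a couple of minutes on one CPU while leaving every
phenomenon comfortably away from its decision threshold.

## Known limitations

* **The middle-of-the-grid plateau is not reproducible at desk scale.**
  On real organoid RNAseq, held-out performance is famously flat across a
  broad range of selected-gene counts. That flatness depends on gene-gene
  co-expression (an effective dimension far below the gene count). With
  independent synthetic genes, ridge at alpha = 10 enters its p ≈ n
  variance regime as soon as several hundred genes are selected at
  n = 200: even for a noiseless, exactly realizable signal, held-out
  Pearson falls from 1.0 (20 genes) to ~0.74 (334) and ~0.51 (667). The
  middle third of the threshold grid (334–667 genes of 1000) therefore
  sits 10–30% below the sweep's maximum, not within 5%, for every
  relevance score. The corresponding check is kept, and fails, as an
  honest record; the measured mid-grid ratio is reported by the
  acceptance script.
* The mean baseline's −1/√n_test artifact under full-dataset z-scoring
  (see above) is a property of the evaluation design, not of the data;
  fold-internal z-scoring would remove it at the cost of leaving the
  baseline's predictions exactly constant (undefined correlations).
* Synthetic fingerprints encode pathway structure only; they do not model
  real chemical similarity gradients within a pathway.
* The generator's noise model is additive Gaussian on viability;
  heteroscedastic assay noise and plate effects are out of scope.
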