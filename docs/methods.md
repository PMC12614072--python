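# Methods

## Model and pipeline

`rpsubtype` treats B-ALL subtyping as multiclass classification of bulk
RNA-seq profiles. The pipeline has four stages.

**1. Preprocessing.** Input is a gene x sample matrix in raw counts, FPKM,
TPM or log2(TPM+1), tagged with its unit so each stage can refuse the wrong
one. Genes expressed (value > 0 by default; the cutoff is configurable) in
fewer than `ceil(0.75 * N)` samples are removed — the ceiling makes "at least
75%" literal at every N. Counts are converted to TPM per sample
(`rate_g = count_g / length_kb_g`, scaled so the column sums to 10^6) using a
caller-supplied gene-length table; which length definition (union exon vs
transcript) to use is left to the caller, since TPMs are only comparable
within one definition. FPKM needs no lengths — only the within-sample
rescaling. The training representation is log2(TPM+1). At prediction time the
incoming matrix is aligned to the training gene list by identifier; if fewer
than 90% of the training genes are present the call errors, and zero-filling
the remainder is opt-in (`fill_missing=True`) because silently imputed zeros
perturb the projections unpredictably.

**2. Sparse random projection.** The d x D projection matrix has i.i.d.
entries in {-sqrt(p), 0, +sqrt(p)} with probabilities {1/(2p), 1-1/p, 1/(2p)}.
Any p >= 1 gives zero mean and unit variance, hence the Johnson–Lindenstrauss
distance-preservation guarantee for `A = R T / sqrt(d)`; the default
`p = sqrt(D)` follows the very-sparse-projection recommendation and makes the
matrix ~99.3% empty at transcriptome scale. The construction draws the nonzero
count from Binomial(dD, 1/p), places the nonzeros uniformly without
replacement and assigns fair signs — exactly equivalent to entrywise i.i.d.
sampling, but O(nnz) in memory. The sqrt(p) magnitude is folded into the
stored matrix, and the 1/sqrt(d) scale into the projection, so projected
squared distances are unbiased estimates of the originals.

**3. Ensemble classification.** Member m draws its projection with seed
`master_seed + m`, so every member is independently reproducible and the whole
fit is deterministic. On each projected training matrix a linear-kernel SVM
(C = 1.0 by default; the true regularization optimum is data-dependent and
exposed) is fitted with libsvm's built-in probability calibration (Platt
scaling per binary subproblem with pairwise coupling). libsvm is used rather
than an external calibration wrapper because its internal folds degrade
gracefully on the very small classes real subtype cohorts contain, instead of
erroring. The ensemble score is the plain average of member probability
vectors — a distribution whenever the members' are — and the call is the
argmax, ties broken by class order (alphabetical). Averaging raw decision
values instead is available behind `raw_margins=True` (softmax-normalized so
the output remains row-stochastic). No post-projection standardization and no
class weighting by default; both are exposed as options. Because projections
are data-independent, cross-validation draws the M matrices once per run and
refits only the SVMs per fold — nothing about held-out labels can leak
through R.

**4. Visualization.** Samples are embedded in 2-D from the matrix
`[ w * Z(A^T) | Z(onehot(y_hat)) ]`, where Z is a column-wise Z-score and w
balances expression structure (w > 1) against predicted-subtype cohesion
(0 < w < 1; default 1.0). Z uses the population (divide-by-N) standard
deviation, recorded in the output metadata; zero-variance columns map to
zeros rather than erroring. The feature block uses the first member's
projection by default. The embedding backend is pluggable; the default is
t-SNE with perplexity `min(30, (N-1)/3)`, PCA initialization and a fixed
seed, which is deterministic per platform. The matrix construction — the
part that matters — is backend-independent.

## Metrics

Per-class metrics come from one-vs-rest counts: Acc = (TP+TN)/N,
F1 = 2TP/(2TP+FP+FN), MCC = (TP·TN−FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
with the standard 0-return when a denominator factor vanishes (the paper-style
binary definitions say nothing about degenerate counts). Aggregate F1 defaults
to the support-weighted mean — more stable under the heavy class imbalance of
subtype cohorts — with the macro mean always reported alongside; aggregate MCC
is Gorodkin's multiclass form, with the one-vs-rest mean alongside. Per-class
"accuracy" in the confusion-matrix sense is reported as recall (diagonal over
row sum). Subtype-group rollups restrict the confusion matrix to the rows of
the group's member classes while keeping all prediction columns, so a sample
predicted outside its group still counts against it.

Cross-validation is stratified by dealing each class's shuffled samples
round-robin across folds (per-fold class proportions within one sample);
classes smaller than k land in only some test folds and trigger a warning.
The 30% hold-out takes `round(0.3 N)` test samples apportioned by per-class
largest remainder, never emptying a class out of training.

## Synthetic cohorts

The generator emulates exactly the data features the pipeline exercises:
imbalanced classes, disjoint blocks of marker genes shifted by `effect_size`
on the log2 scale in their class, a shared log-normal baseline
(mean 5, sd 1.5 on log2), per-entry Gaussian noise (`noise_sd`), log-normal
per-sample library-size factors (sd 0.2), Poisson counting noise, and a 10%
zero-inflated gene fraction (50% dropout) that the prevalence filter removes.
Counts — not TPM — are emitted, together with gene lengths, so the entire
filter → TPM → log path is exercised. The `cohort-like` preset has 20 classes
named after the harmonized B-ALL subtypes with 500 samples in proportions
echoing the real cohort's imbalance (18.6% / 15.4% / 10.8% at the head, a
tail floored at 5 samples) over 5,000 genes, with effect size 4 and noise
sd 0.5 — a strongly separable regime. The generator does not model real
co-expression covariance, fusion-transcript signal or batch structure, so
passing tests demonstrate pipeline correctness and the ensemble's statistical
behavior, not clinical-grade accuracy on real cohorts.

For distance-preservation diagnostics a clustered Gaussian
(`gaussian_clusters`: a 4-component mixture shifting 10% of features by 2) is
used instead of an isotropic Gaussian. This is deliberate: isotropic
high-dimensional Gaussians have pairwise distances concentrating with relative
spread ~sqrt(2/D) (~3% at D = 2000), below the projection's own ~sqrt(2/d)
noise floor, so the distance correlation is capped near 0.6 at d = 1200 for
*any* unbiased projection; with cluster structure — which real expression
data has — the correlation exceeds 0.95 at d = 1200 and grows with d.

## Desk-scale study sizes

The acceptance checks run minutes on one CPU by scaling the problems, not the
thresholds: projection statistics at d x D = 400 x 2000 plus 1,000 independent
10 x 50 draws for the norm-preservation ratio; distance preservation at
D = 2000, N = 100 over 10 seeds; metric exactness on the exhaustive
{0..20}^4 one-vs-rest grid and 100 random 4x4 confusion matrices against a
brute-force oracle; ensemble-vs-individual over 20 replicates of a 3-class,
50-sample cohort at effect size 2 with d = 40, M = 30 (the regime where
single projections are mid-accuracy and ensemble averaging visibly helps);
cohort-like fivefold CV and 30% hold-out at d = 400, M = 5; and the
silhouette comparison over 20 seeds of a 4-class cohort.

## Known limitations

- No batch-effect correction or minority-class oversampling; inputs are
  assumed comparable.
- Probability calibration quality on classes with a handful of samples is
  poor (libsvm's internal folds see one or two positives); the confidence
  column should be read cautiously for rare subtypes.
- The ensemble never abstains: the argmax subtype is always reported, with
  low confidence as the only signal of an unreliable call.
- t-SNE determinism is per-platform (BLAS/compiler dependent), though always
  reproducible within a machine for a fixed seed.
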