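# Methods

`gliomix` implements a supervised multi-block analysis for tumour subtype
classification and biomarker discovery from 2–3 omics layers (mRNA
expression, DNA-methylation beta values, miRNA expression), together with
the synthetic data generator used to validate every stage.

## Supervised sparse generalized CCA

For Q standardized data blocks X^(1), …, X^(Q) (samples × features) plus a
column-centered class-indicator block Y (one dummy column per class), each
component h solves

    max  Σ_{q≠j} c_qj · cov(X^(q) a^(q), X^(j) a^(j))
    s.t. ‖a^(q)‖₂ = 1,  ‖a^(q)‖₀ ≤ keepX_q,

where C = {c_qj} is the design matrix. Sparsity is parameterized by the
number of features to keep per block and component (`keepX`) rather than an
ℓ1 penalty: inside the block-coordinate ascent, the update direction
z = X^(q)ᵀ Σ_j c_qj t^(j) is soft-thresholded at τ = the (k+1)-th largest
|z| and renormalized, which leaves exactly k nonzero loadings in the
absence of ties. The outcome block is unpenalized (only normalized).

Solver details that the objective alone does not determine:

- **Initialization.** Every block starts from its first right singular
  vector. Within each sweep the outcome block is updated *first*, so its
  loading is immediately driven by the signal-rich initial data-block
  scores; updating the data blocks first can lock the iteration into a
  noise fixed point whenever the top singular direction of Y happens to be
  orthogonal to the discriminative direction.
- **Ascent guard.** A data-block update is accepted only if it does not
  decrease that block's linear partial objective zᵀa. The previous loading
  is always feasible once it satisfies the cardinality bound (the dense
  initialization is exempt), so the recorded objective path is
  non-decreasing by construction, not merely empirically.
- **Convergence** is declared when every block's loading moves by less than
  `tol = 1e-6` in the ∞-norm, measured up to a global sign flip per block;
  `max_iter = 100`. Non-convergence returns the last iterate with a warning.
- **Sign convention.** After convergence each loading is flipped so its
  largest-magnitude entry is positive. Scores, centroids and deflation
  coefficients are flipped consistently, so predictions are unaffected.
- **Deflation.** Each block (including the outcome) is deflated by its own
  component scores, X ← X − t (tᵀt)⁻¹ tᵀX, and the regression row is stored
  so test samples can be projected through the identical sequence. This
  makes successive scores within a block exactly orthogonal.
- **Components.** H = K − 1 by default (K classes); overridable.

The number of components and all covariances use the unbiased (n − 1)
denominator.

## Design matrix

Block connectivity is data-driven: for each pair of blocks a one-component
PLS (rank-1 SVD of X₁ᵀX₂) is fit and the Pearson correlation r of the two
score vectors is rounded down to one decimal, c = floor(10·|r|)/10 (a 1e-9
epsilon guards against floating-point representations of exact tenths).
Every data block is fully connected (weight 1) to the outcome block. The
rounding-down rule reproduces the conventional mappings 0.8796 → 0.8 and
0.6027 → 0.6.

## Sparsity tuning

`keepX` is tuned one component at a time (earlier components frozen) by
stratified 5-fold cross-validation repeated 5 times, scoring the overall
misclassification rate of the *complete* prediction path (standardize with
training statistics → project → per-block centroid distance → weighted
vote). The coarse grid is the Cartesian product over blocks; the winner
(ties broken toward the smallest total feature count, then lexicographic
order) is refined with step halving, with candidates clamped to the coarse
grid's span, until the step reaches 1 or the winner stops moving. Fold
assignment depends only on sample IDs (classes visited in sorted order,
IDs sorted before shuffling), so the CV error is invariant to input row
order given the seed.

## Classification

Per block, class centroids are means of training component scores; a test
sample votes for its nearest centroid (Euclidean distance in the H-dim
score space; ties to the first class in first-appearance order). Block
votes are fused by weighted vote with

    weight_q = (1/H) Σ_h max_k | corr(t_h^(q), Y_centered[:, k]) |,

the mean over components of the strongest score–class correlation on
training data. Tied fused votes follow the vote of the highest-weight
block among the tied classes. Reported metrics: accuracy, one-vs-rest
precision/recall/F1 (zero-division reported as 0 and flagged), confusion
matrix, and per-class AUC computed from the negative distance to each
class centroid as the continuous score (Mann–Whitney concordance with ties
counted ½).

## Consensus (stability) selection

The tuned model is refit on 30 stratified 70/30 partitions (partition p
seeded `base_seed + p`; tuning is *not* repeated per partition). For every
(block, component, feature) the number of partitions with a nonzero
loading and the absolute loadings on those partitions are accumulated; the
median is taken over the partitions where the feature was selected, not
zero-padded. A feature is kept iff

    frequency > 15 and median |loading| > 0.05,  or
    frequency > 10 and median |loading| > 0.2,

with strict inequalities, and the final list is the union over components.
Each kept feature is assigned an outcome class:

- **Expression** (count-based features): from pairwise differential
  expression — a class qualifies if both of its contrasts are significant
  (FDR < 0.05) with consistently signed log-fold-changes; its score is the
  smaller |logFC|, and the best-scoring class wins. If no class qualifies,
  the contrast with the smallest FDR decides (class with the higher
  expression), flagged low-confidence. The max–min formalization is one
  concrete reading of "lower FDR and higher logFC"; the flag marks where
  the fallback was used.
- **Methylation**: the class whose mean beta differs most, on average, from
  the other classes.
- **miRNA** (two-class setting): the class with the higher mean expression.

## Differential expression

Counts (genes × samples, raw) are filtered to genes with CPM > 1 in at
least `min(group sizes)` samples, normalized with TMM (reference = sample
whose upper-quartile CPM is closest to the mean upper quartile; 30%
two-sided trim on M, 5% on A; precision weights from the asymptotic
binomial variance; factors rescaled to geometric mean 1), and tested
per-gene with a negative-binomial likelihood-ratio test: group-specific
vs shared log-means (Newton iterations vectorized over genes, offsets =
log effective library size), statistic referred to χ²₁. The dispersion per
gene is a shrinkage estimate, 0.25 × method-of-moments + 0.75 × the 25%
trimmed-mean common value, clipped to [1e-8, 10]. This NB-LRT stands in
for a quasi-likelihood F-test; it is validated by calibration simulations
(null type-I error ≈ 5% at n = 10/group, dispersion 0.1) rather than by
numeric parity with any specific implementation. logFC is log2 of group
mean CPM with prior count 0.5; p-values are BH-adjusted.

Significant genes (FDR < 0.05) are split by the sloped volcano cut-line:
with M = max(−log10 FDR) over the contrast and c = −log10(0.05), a gene is
*positively relevant* when −log10(FDR) > M + logFC·(c − M) and *negatively
relevant* when −log10(FDR) > M + logFC·(M − c). Both lines pass through c
at logFC = ±1 and through M at logFC = 0, so only genes combining strong
significance with non-trivial fold change are labelled relevant; the rest
remain "significant, not relevant". FDR values that underflow to 0 are
clamped to the smallest positive float so M stays finite. If M ≤ c (no
gene significant at the printed precision) the line is degenerate and the
rule falls back to FDR < 0.05 & |logFC| > 1 with a warning. The preranked
gene-set metric is −log10(p) × sign(logFC).

## Correlation and survival

Pearson correlations between selected features use pairwise-complete
observations with two-sided p from t = r√(n−2)/√(1−r²). For survival,
each feature's expression is dichotomized at the median, unless the
Gaussian KDE (Silverman bandwidth, 512-point grid padded by 3 bandwidths
so edge peaks keep their prominence) shows ≥ 2 peaks with prominence
≥ 5% of the maximum density — then the cutoff is the density minimum
between the two most prominent peaks. "Low" is ≤ cutoff. Groups are
compared with Kaplan–Meier curves and the two-group log-rank test
(χ²₁). KM and log-rank are computed via lifelines; the tests verify them
against hand-computed product-limit and hypergeometric values.

## Synthetic data generator

The generator emulates the statistical structure of a multi-class tumour
multi-omics study; it is the ground truth for every recovery and
calibration claim.

- **Latent factors.** K class means sit at the vertices of a regular
  simplex in R^(K−1) with circumradius `class_separation`; within-class
  noise is N(0, I). `class_separation = 5` (default) gives essentially
  separable classes, matching the high accuracies of well-separated tumour
  subtypes; 0 gives pure null data.
- **Blocks.** Each informative feature loads on exactly one latent axis
  with magnitude `loading_scale` and a random sign; informative features
  are spread round-robin over the axes so each class contrast is carried by
  a comparable number of features (as when distinct gene sets mark each
  subtype). Gaussian blocks add N(0, noise_sd²); methylation blocks pass
  signal+noise through the inverse logit (values strictly in (0,1)) with
  half the informative signs forced negative, emulating
  expression–methylation anticorrelation; count blocks draw NB with
  log-mean = 5 + signal and dispersion 0.1 (typical bulk RNA-seq).
- **Survival.** Exponential times with hazard exp(lp)/baseline_scale, lp
  proportional to the standardized first latent axis; independent U(0, c)
  censoring with c solved numerically so the expected censored fraction
  matches `censor_fraction` (default 0.3).
- **Defaults** follow the analysis settings throughout: 70/30 stratified
  splits, 5×5 CV, 30 consensus partitions, thresholds 15/0.05/10/0.2,
  H = K − 1.

What the generator does *not* emulate: batch effects, missingness, probe
cross-hybridization, library-size extremes, non-proportional hazards, or
correlated noise between features beyond the shared latent factors.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated model, not robustness to every artefact of real
consortium-scale tumour data.

## Numerical and scale choices

- Standardization uses the unbiased (ddof=1) standard deviation; test
  samples always use training statistics.
- Stratified splits round per-class train counts half away from zero and
  correct any total mismatch on the largest class.
- Near-zero-variance filtering removes features with zero variance or with
  (distinct/n < 0.10 and top-frequency ratio > 19), the 95/5 convention.
- Problem sizes in the test-suite simulations (e.g. 150 samples × 300
  features per block, 5000 genes for DE calibration, 1000 log-rank
  replicates) were chosen as the smallest sizes at which the Monte-Carlo
  bands in the corresponding checks are meaningful.
- The master seed expands into per-stage seeds through
  `SeedSequence([master, stage_index])`; partition p of the consensus
  stage uses `base_seed + p`.

## Known limitations

- The NB-LRT's χ²₁ reference is asymptotic; at very small group sizes
  (< 5 per group) it can be liberal.
- The weighted-vote weight formula is one reading of "correlation between
  the latent components and the outcome"; alternatives (per-component
  votes, Fisher-combined correlations) are not implemented.
- The solver's block-coordinate ascent is a local method; the outcome-first
  sweep order removes the known initialization trap, but global optimality
  is only verified on small instances by enumeration.
- Only two-group log-rank comparisons are provided; no Cox regression.
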