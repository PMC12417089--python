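# Methods

## Problem and model

`nfembed` predicts the nitrogenase activity of diazotrophic bacterial
strains from genomic information. Two prediction targets are supported:

- **Classification** — is activity above 50 nmol C2H4/mg protein/hour?
  A strain is positive iff its measured activity *strictly* exceeds the
  threshold; the comparison at exactly 50 is a convention (the boundary
  direction is configurable).
- **Regression** — the log-compressed activity `y = log10(x + 2)`, which
  tames the heavy right tail of acetylene-reduction measurements while
  staying finite at x = 0. The inverse `x = 10^y − 2` recovers the
  original scale.

The predictor is a two-layer stacking ensemble. The training set is split
60/40 (stratified for classification). Base learners fit on the 60%
partition; their hold-out outputs on the 40% partition — positive-class
probabilities for classification, real predictions for regression — form
the base-learner-probability (BLP) vector, which is appended to the 40%
partition's feature rows before the meta learner is fitted. At prediction
time the base layer recomputes the BLP for new samples. Default learners
follow the tuned configuration: k-NN (5 neighbors, uniform weights) base
with a random-forest meta (200 trees, unbounded depth, min-split 5, log2
feature subsampling, bootstrap) and decision threshold 0.55 (inclusive:
probability = threshold predicts positive) for classification; a
decision-tree regressor (depth 5, random splitter, min-split 10, sqrt
features) and a gradient-boosted regressor (depth 5, learning rate 0.01,
200 rounds, gamma 0) as bases with an RBF support-vector regressor
(C = 1, epsilon = 0.01, scale kernel width) meta for regression. The SVR
kernel is taken to be RBF; the tuned-value table we follow prints an
uninterpretable token for that cell, and RBF is the searched value
consistent with the remaining entries. Base learners stay fitted on the
60% partition; they are not refit on the full training set.

## Feature groups

Nine named groups, each a fixed-width block (one row per strain). Protein
descriptors are computed per structural gene (nifH, nifD, nifK) and
averaged element-wise over the three proteins.

| Group | Width | Definition |
|---|---|---|
| CT | 343 | conjoint-triad: relative frequency of residue-class triplets (7 classes by side-chain dipole/volume), count/(L−2) |
| DPC | 400 | dipeptide composition, count/(L−1), alphabetical order, row-major |
| PAAC | 50 | pseudo-amino-acid composition: 20 damped frequencies + 30 lagged correlation factors (hydrophobicity, hydrophilicity, side-chain mass; weight w = 0.05, lambda = 30) |
| RSCU | 61 | relative synonymous codon usage over the sense codons, averaged over the three structural-gene CDS |
| Euclidean_distance | 1 | distance of the RSCU vector from neutral usage (all ones), averaged over the three CDS |
| Expression | 24 | (CAI, E, Fop) for each of the eight expression genes nifA/B/D/E/H/K/N/X |
| Gene_distance | 1 | genomic span max(end) − min(start) of nifHDK |
| Copy_number | 34 | copy counts of the 34-gene nitrogen-fixation panel |
| embedding | D | mean-pooled per-residue protein-language-model embedding, averaged over the three proteins (ESMC_600M: D = 1152) |

Decisions worth noting:

- **Conjoint-triad classes.** The seven-class dipole/volume grouping is
  {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}; it is a
  swappable config asset. CT entries are relative frequencies by default;
  the original min–max rescaling is available as an option.
- **PAAC.** The squared-difference three-property correlation is
  symmetric, so PAAC is provably invariant under sequence reversal; order
  sensitivity is asserted on non-reversal permutations. Property tables
  are the classical ones, standardized to mean 0 / sd 1 over the 20
  amino acids. On a homopolymer every correlation term vanishes and PAAC
  reduces exactly to amino-acid composition.
- **RSCU and unobserved families.** Codons of families absent from a gene
  take fill value 0 by default (a neutral fill of 1 is available), and
  all 61 entries enter the neutral-usage distance.
- **CAI/Fop reference.** Relative adaptiveness weights come from a
  user-supplied reference table; the bundled default is derived from a
  deterministic *synthetic* highly-expressed gene set (40 genes, 300
  codons, family-first codon preferred with probability 0.6, fixed seed)
  so that tests need no external data. It carries no organism-specific
  biology; real analyses should supply their own reference. Weights are
  floored at 1e−4; singleton families (Met, Trp) are excluded from CAI
  and Fop.
- **Codon-bias E.** Defined here explicitly as the family-share-weighted
  mean absolute deviation of within-family codon frequencies from uniform
  usage. It is 0 iff every used multi-codon family is uniform and is
  invariant to gene length at fixed within-family proportions. This
  definition is artifact-specific; numerical agreement with other
  packages' E statistics is not claimed.
- **Gene distance.** "How far apart" is operationalized as the genomic
  span of the three genes (a single scalar); a pairwise-midpoint-sum mode
  exists. Genes on different replicons are an error by default
  (configurable sentinel). Circular replicons are treated as linear — a
  known limitation.
- **Embeddings.** Language-model inference is out of scope: per-residue
  matrices are ingested from TSV tables and validated against declared
  source widths (ProtT5 1024, ProteinBERT 512, Ankh 1536, ESMC 960/1152/
  2560). Pooling averages residue rows only. The deterministic
  pseudo-embedding backend hashes (residue identity, coarse position
  window, seed) into rows in [−1, 1]; it is bit-reproducible and purely
  synthetic.

## Selection procedures

**IFS (incremental feature selection).** Round 1 scores every single
group by mean 5-fold cross-validated F1 (classification, stratified
folds) or R² (regression, shuffled folds) under an evaluation model
(gradient-boosted trees by default; injectable). Each later round scores
the retained set plus each unused group and keeps the best extension,
running to exhaustion (G + (G−1) + … + 1 evaluated sets for G groups).
The final selection is the global maximum over every evaluated set;
scores within 1e−9 tie, and ties break toward fewer groups, then
evaluation order. An optional repeat count re-runs CV under reseeded
folds and averages.

**IMI (incremental base-learner selection).** The same greedy scheme over
candidate learners with mutual information (nats) as the objective:
candidates fit once on the Training-60 partition; their Training-40
outputs are scored against the truth. Classification uses the plug-in MI
of the *joint* discrete distribution of predicted labels (predicted
labels, not probabilities); regression stacks predictions as a
multivariate variable into a Kraskov-type k-nearest-neighbor estimator
(k = 3, Chebyshev metric). A deterministic seeded jitter of 1e−10 breaks
exact duplicates before the kNN estimate, and negative estimates clamp
to 0. Candidates that fail to fit are skipped with a warning.

## Metrics

Confusion-count metrics (F1, SN, SP, ACC, BACC, PREC, MCC) are computed
directly from their formulas with explicit zero-denominator conventions
(ratio metrics → 0; MCC → 0 when a marginal is empty). AUC is the
rank-based Mann–Whitney statistic with ties counted 1/2 — exact for
finite samples, no trapezoidal approximation. Regression reports R²,
MSE, RMSE (= √MSE identically) and MAE.

## Synthetic data generator

The generator emulates the *structure* of the real strain data: three
structural proteins of 250–550 residues, CDS for the eight expression
genes, coordinates on one replicon, the 34-gene copy panel, and a
continuous activity with the class threshold at 50. Signal is planted
through a latent score

    s = β_cn·z(nifH copies) + β_emb·z(embedding projection)
        + β_cb·z(codon bias) + N(0, σ),

shifted by the empirical (1 − balance) quantile so the configured class
balance holds, then exponentiated: activity = 50·10^s. The log target is
therefore near-linear in s. CDS are back-translations of the generated
proteins with a per-sample bias parameter (optimal codon with probability
0.2 + 0.6·bias), so CAI carries tunable signal. Defaults: n = 100,
balance 0.5, β = 1 each, σ = 0.25, chosen so that each planted channel is
individually detectable at n ≈ 60–100 without making the task trivial.

What the generator does *not* emulate: phylogenetic correlation between
strains, homology to real nif sequences, realistic amino-acid
composition, measurement error of the acetylene-reduction assay, or
missing genes. Passing recovery tests therefore demonstrates that the
pipeline's selection and stacking machinery works, not that the real
biological signal is of this form or strength.

## Numerical and design choices

- Stratified splits allocate per class floor(fraction × n) to the first
  partition, remainders to the second — this reproduces the canonical
  arithmetic 209/193 → 167/154 + 42/39 at fraction 0.8. Membership is a
  seeded permutation within each class.
- Scale-sensitive learner families (k-NN, SVM/SVR, logistic, MLP, lasso,
  ridge, Bayesian ridge) are fitted behind a standardizing transform,
  since the raw blocks mix unit-scale frequencies with base-pair
  distances around 1e3–1e4. Tree ensembles are fitted on raw features.
- Grid search enumerates the Cartesian product of the declared value
  lists in declared order; a cell that fails to fit scores −inf and is
  logged; ties keep the first cell. The decision threshold is tuned by F1
  on hold-out probabilities over {0.40, 0.45, …, 0.70}.
- Ambiguous protein letters (B, Z, X, U, O) are rejected by default; a
  drop-residue mode logs a warning. CDS must be stop-free internally;
  a terminal stop codon is allowed and stripped before codon counting.
  Standard genetic code only.
- Model archives are versioned; loading rejects unknown format versions
  and corrupt files.

## Problem sizes used in the shipped checks

Recovery and ablation properties use 20 seeded replicate datasets of
60–300 samples; the end-to-end demonstration uses a 200-strain synthetic
cohort with an 80/20 stratified split and the full featurize → IFS →
stacking → evaluate pipeline. These sizes give stable pass/fail behavior
for the planted effect sizes above while keeping a full run in minutes on
one CPU.

## Known limitations

- The real headline performance of the published ensembles depends on a
  curated 402-strain dataset and externally computed 600M-parameter
  language-model embeddings; neither ships here, so absolute performance
  on real strains is out of scope.
- The E statistic and the CAI reference set are artifact-specific
  definitions (documented above), not re-implementations of any specific
  external package's internals.
- The kNN MI estimator is biased at small n; IMI scores should be
  compared within a run, not across datasets.
- Circular replicons and multi-replicon nif operons are not modeled.
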