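# Methods

`puppred` predicts which proteins are pupylated and which of their lysines
carry the modification, from sequence (plus GO annotation for the
protein-level task). This note documents the models, the defaults and why,
the numerical choices, and what the synthetic test corpus does and does not
demonstrate.

## Problem setting

Pupylation attaches the prokaryotic ubiquitin-like protein (Pup) to
substrate lysines in actinobacteria, marking proteins for proteasomal
degradation. Two supervised tasks follow:

* **protein task** — binary classification of whole proteins
  (pupylated / not);
* **site task** — binary classification of every lysine in a protein,
  using a fixed-length peptide window around it.

## Site windows

A candidate site is represented by the peptide
`theta_delta(K) = R_{i-delta} ... K ... R_{i+delta}` of length
`2*delta + 1` centered on the lysine at position `i` (1-based
coordinates). Positions beyond either end of the protein are padded with
the pseudo-residue `X`. The default is `delta = 28` (window length 57),
the half-width at which windowed predictors of this modification perform
best in the literature this design follows; it is configurable.

Sanitization maps ambiguity codes (`B, J, O, U, Z`, `*`, gaps, pre-existing
`X`) to `X` with a logged warning rather than rejecting the record — the
downstream 21-letter alphabet (`ACDEFGHIKLMNPQRSTVWY` + `X`) absorbs them.

## Site-task encoders

Six blocks are fused per window (13,927 stateless columns + 896 learned):

| encoder | dim (delta=28) | definition |
|---|---|---|
| TPC | 9,261 | tripeptide frequencies over the 21-letter alphabet, 21³ bins, sum 1 |
| AAI | 855 | 15 amino-acid property scales per position (57 × 15) |
| One-Hot | 1,140 | 20 bits per position (A first … Y last), `X` = all zeros |
| PseAAC | 25 | composition + lambda=5 sequence-order factors, omega=0.05 |
| CKSAAP | 2,646 | k-spaced pair frequencies, k = 0..5, 441 pairs per k, each block / (L−k−1) |
| embedding | 896 | fused k-mer CBOW vectors (below) |

**PseAAC correlation factors.** Only the branch form of the composition is
fixed by the method; for the correlation factor we adopt the canonical
type-1 convention: `theta_j = (1/(L-j)) * sum_i Theta(R_i, R_{i+j})` with
`Theta(a,b)` the mean squared difference of six physicochemical scales
(hydrophobicity, hydrophilicity, side-chain mass, pK1, pK2, pI), each
standardized to zero mean and unit population variance over the 20
residues. `X` carries no property values and is stripped before encoding;
all 25 components sum to 1.

**AAI table.** The 15 bundled scales (`src/puppred/data/aaindex15.tsv`) are
well-known published property scales keyed by their AAindex accession IDs
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Grantham polarity
and volume, Zimmerman bulkiness/polarity/pI, molecular weight, net charge,
normalized van der Waals volume, Chou–Fasman helix/sheet/turn propensities,
flexibility, relative mutability). The particular set of 15 used by prior
pupylation predictors is only available in a third-party supplement, so the
table is a configurable TSV input and the bundled default may differ from
theirs. The `X` policy defaults to an all-zero property vector.

**CKSAAP denominator.** `F_N = L - k - 1` is exactly the number of
k-spaced pairs in a length-`L` string for `k <= L-2`; shorter inputs are
rejected by precondition, so every 441-block sums to 1.

## k-mer embeddings

Sequences are cut into overlapping k-mers (stride 1) and treated as
sentences. Three CBOW models with negative sampling are trained — fragment
lengths 2, 3, 4 paired monotonically with dimensions 128, 256, 512 (the
pairing is configurable; only the two sets are fixed by the method) — and a
sequence is represented by the concatenation of the per-model mean token
vectors: 896 dimensions. Mean pooling is our choice; the method's source
only says the word vectors are "combined". Out-of-vocabulary tokens are
skipped, and an all-OOV sequence maps to the zero vector with a warning.

The trainer is an in-package numpy implementation (no external embedding
library is required): hierarchical details follow word2vec practice —
unigram^0.75 negative-sampling distribution, linearly decaying learning
rate (initial 0.025), float32 weights. One SGD step processes a small group
of sentences (~256 center positions; context windows never cross sentence
boundaries); larger step sizes were observed to diverge and are avoided.
Defaults: context window 5, 10 epochs, 5 negatives, min_count 1 — all
surfaced in the config. Training is single-threaded and seeded, so results
are bit-reproducible.

## GO-KNN features (protein task)

The distance between two proteins is the Jaccard distance of their GO term
sets, `1 - |A ∩ B| / |A ∪ B|`. A query's feature vector is the fraction of
positive training proteins among its `Y` nearest training neighbors, for
`Y in (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)` — ten components. The
published ladder lists only nine values (2..256, 1024) for a stated
10-dimensional feature; 512 is inserted to complete the doubling sequence,
and the ladder is configurable so the literal nine-value variant is
available.

Numerical details:

* distance ties are broken by ascending protein id (determinism);
* a training query is excluded from its own neighbor list (leave-self-out),
  otherwise every training vector is biased by its own self-distance 0;
* a `Y` of at least the training-set size is truncated to the set size: the
  neighborhood is then *everyone*, so the component is defined as the
  training-set positive fraction computed over the full list, self
  included. Under plain leave-self-out this component would equal
  `(P - own_label)/(n-1)` for training queries — a perfect, artifactual
  separator of the training classes that is constant for validation
  queries; gradient boosting exploits it and collapses. At realistic
  training sizes (n > 1024) no ladder value truncates and the two readings
  coincide;
* unannotated proteins are a hard error; the expectation (documented in the
  error message) is that users substitute the GO terms of a close homolog
  upstream. The table reader accepts only fully resolved annotations.

## Selection and balancing

**Chi-square selection.** The standard non-negative-feature selector:
per feature, the observed class-conditional feature mass is compared with
the mass expected from the class priors. Columns that can be negative
(AAI, embeddings) are first min-max-shifted to [0, 1] by a transform fitted
on training data only and stored in the model bundle. The top `K = 600`
columns are kept by default (configurable); ranking ties break by original
column order.

**Balancing.** Random under-sampling (RUS) deletes majority rows uniformly
at random; SMOTE synthesizes minority rows as `x + u (x_nn - x)` with
`u ~ U[0,1]` and `x_nn` one of the 5 nearest minority neighbors (Chawla's
default). The protein pipeline composes them — RUS negatives to 2:1, then
SMOTE positives to 1:1 — because the source method states both were used
but not the order; the composition and ratios are configurable. Synthetic
rows get `synth:`-prefixed sample ids. All balancing is seeded.

## Classifiers and evaluation

Five engines: random forest (500 trees), RBF-kernel SVM with probability
outputs, KNN (k = 5), XGBoost (library defaults), and a stacking ensemble
whose base learners (RF, SVM, KNN) feed a logistic-regression meta-learner
through out-of-fold probability columns (5 inner folds). Hyperparameters
are exposed in the config since the source prints none. Default engines
mirror the best performers per task: XGBoost for proteins, stacking for
sites.

Metrics: `Sn = TP/(TP+FN)`, `Sp = TN/(TN+FP)`, `ACC = (TP+TN)/N`, and

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC reported as 0 (logged) when a marginal is empty. ROC is the
standard TPR-vs-FPR curve over all thresholds with trapezoid-rule AUC; tied
scores cross their threshold simultaneously (all-equal scores give exactly
0.5). The decision threshold for confusion counts is 0.5, configurable.

**Cross-validation** is stratified 10-fold with a fixed seed. Everything
fitted on data — embeddings, GO-KNN neighbor labels, the min-max shift,
the chi-square ranking, balancing — is fitted inside each training fold
and applied to its validation fold. Out-of-fold scores are pooled into a
single report (pooling rather than per-fold averaging is our choice; the
source does not say which it used). Validation folds are never balanced.

## Synthetic corpus

Real pupylation datasets require curated databases, redundancy removal
(CD-HIT, run externally), and GO annotation services. The bundled
generator emulates the *shapes* of that data so the full stack is testable
offline:

* uniform-random proteins over the 20 residues, lengths 60–120;
* half the proteins positive, each with 1–3 positive lysine sites;
* positive sites carry an implanted upstream motif (`GGQ` at offset −3
  from the K) with probability `motif_prob`; negative sites are scrubbed
  so they never carry it. The motif is a *stand-in* for real sequence
  preference around modified lysines, which is diffuse in real data;
* GO term sets are class-correlated symmetrically: positives draw each
  term from an enriched vocabulary half with probability
  `class_term_bias`, negatives with probability `1 − class_term_bias`.
  Bias 0.5 is therefore an exact null and bias 1.0 disjoint usage.

Defaults (200 proteins, ~400 windows at a 1:1 site ratio, bias 0.9,
motif probability 1) define the standard study conditions used by the
acceptance checks. `generate_ratio_dataset` also reproduces arbitrary
class ratios exactly (e.g. 201 positives at 1:5.6 → 1,126 negatives).

**What passing these tests shows — and does not.** Recovery of a planted,
deterministic motif and a strong annotation bias demonstrates that the
plumbing is correct end to end (no leakage, no label misalignment, fused
features reach the classifier). It does not estimate real-data accuracy:
real pupylation signal is weaker, homology structure induces train/test
dependence the generator does not model, and proteome composition is not
uniform.

## Problem sizes and runtime choices

The acceptance computations run both pipelines at the study size
(200 proteins / ~400 windows) with the full 10-fold protocol for the
strong-signal condition and 5 folds for the null condition (the null band
0.5 ± 0.1 is insensitive to fold count, and the narrower protocol keeps
the whole acceptance run to minutes on one CPU). The byte-determinism
check uses a 40-protein corpus with 3 folds — determinism is
scale-independent.

## Known limitations

* The embedding trainer is a compact reference implementation; it is
  adequate for corpora of hundreds to thousands of sequences, not for
  proteome-scale pretraining.
* The bundled 15-scale AAI table is a documented default, not the exact
  set used by prior pupylation predictors.
* GO-KNN quality depends entirely on annotation coverage; the package
  does not perform homolog-based annotation transfer itself.
* SVM probability outputs rely on internal Platt scaling; scikit-learn is
  migrating this API (`CalibratedClassifierCV`), which may change scores
  slightly across future library versions.
* Model bundles store the fitted classifier with pickle and are therefore
  not portable across major library versions.
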