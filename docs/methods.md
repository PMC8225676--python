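# Methods

## Problem setting

Public bioactivity knowledge about small molecules can be organized into 25
"spaces" spanning a chemistry-to-clinics axis (A: chemistry, B: targets,
C: networks, D: cells, E: clinics; five sublevels each).  In each space a
molecule is represented by a fixed-width real-valued *signature* whose
Euclidean/cosine neighborhoods reflect similar behavior of that kind.
Experimental signatures are acutely incomplete: chemistry spaces cover
essentially every molecule, clinical spaces a few thousand drugs.  This
package implements a family of models — *signaturizers* — that infer a
molecule's signature in a target space from whatever signatures it has in
the other spaces, plus the machinery to score, distill, and exploit those
inferences.

## Per-space signaturizer

For a target space S_i, the covariates matrix X stacks the 128-wide
signature blocks of all spaces covering at least 10 % of S_i's molecules
(m blocks, width 128·m).  Missing blocks are stored as NaN and fed to the
network as zeros — the neutral value of the Tanh-centered signature scale
— after the presence mask is recorded.

The network is shared across the three members of a molecule triplet
(anchor, positive, negative): multiplicative Gaussian input noise
(sigma = 0.1), two dense hidden layers with SeLU activations and
alpha-dropout 0.2, and a dense output head with Tanh activation followed
by L2 normalization, so every inferred signature is a unit vector with
components in [-1, 1].  Hidden sizes follow
`h1 = min(512, m·128/2), h2 = min(256, m·128/4)` — an interpolation
between input and output widths that saturates at (512, 256) for large m
(m = 7 gives (448, 224); m = 25 gives (512, 256)).  At reduced synthetic
scale the same rule is applied with the block width of the store, and the
output width equals the block width so inferred spaces re-enter the store
as regular blocks.

Triplets are sampled from the target space itself: the positive uniformly
from the anchor's k nearest neighbors (k tuned by cross-space neighbor
agreement and clipped to [10, 50]), the negative uniformly from molecules
strictly farther than the chosen positive, so d(a, p) < d(a, n) holds by
construction.  Molecules are split 80:20 after near-duplicate removal
(single-linkage at epsilon = 1e-6, i.e. exact duplicates), giving
train–train, test–train and test–test triplet populations of increasing
difficulty.

Training minimizes the sum of three terms with equal weights:

* **triplet hinge** `max(0, ‖e_a − e_p‖ − ‖e_a − e_n‖ + 1)` on plain
  Euclidean embedding distances;
* **self-MSE** between the anchor embedding under signature dropout and
  the embedding computed from the S_i block alone; the S_i-only embedding
  is treated as a stop-gradient target, which keeps the term a pure
  regression of the dropped-out view onto the self view and avoids the
  degenerate solution where both views collapse jointly;
* **global orthogonal regularization** `M1² + max(0, M2 − 1/d)` on
  anchor–negative inner products (M1/M2 the first/second moments),
  weighted by alpha = 1, pushing non-matching embeddings toward the
  moments of random unit vectors.

Signature dropout masks each non-target block j with keep probability
equal to the fraction of *not-in-S_i* molecules that possess space j (the
realistic availability at prediction time); the S_i block itself is
dropped with a raised-cosine probability `(1 − cos(2π·c·t/T))/2`
oscillating between 0 and 1, c = 5000 cycles per epoch.  The waveform and
its zero phase are this package's choice; only the range and cycle count
are inherited requirements.  At the small training runs used here the
schedule aliases against the number of optimizer steps, which makes the
self-dropout probability effectively quasi-uniform over [0, 1] — the
intended regime (all masking levels visited) is preserved.

Optimization is Adam at learning rate 1e-4, batch size 128 (batch size,
shuffling, and LeCun/Glorot initialization are package choices), 5 epochs
for spaces under 30,000 molecules and 2 above.  Only train–train triplets
contribute gradient steps.  The network engine is an in-package numpy
implementation (dense/SeLU/alpha-dropout/Gaussian-noise/Tanh/L2 layers
with analytic backprop, verified against finite differences in the test
suite); determinism is guaranteed given a seed on a fixed BLAS, and
statistical behavior — not cross-platform bit-identity — is the contract.

### Evaluation

Two accuracy surfaces: (a) per-split triplet accuracy — the fraction of
triplets with ‖e_a − e_p‖ < ‖e_a − e_n‖ when the target block is removed
from all three inputs; (b) per-molecule agreement between the
target-dropped embedding and the S_i-only "truth" embedding.  Because the
Tanh head makes components bimodal, agreement is a Matthews correlation
coefficient over the 2×2 sign-contingency of the embedding dimensions
(exact zeros binarize to +1; an empty margin returns MCC 0, flagged).
Neighbor recovery reports, for ranks t, the fraction of query molecules
with at least one true (experimental-space) neighbor among their top-t
predicted neighbors.

## Applicability score (alpha)

Five factors, three characteristics: distance to the applicability domain
(mean of the average distances to the 5 and 25 nearest training
signatures — read as a single factor so the total is five; a random-forest
regression of achievable MCC from the signature; the mean absolute
deviation from the null/average training signature), robustness (mean
componentwise standard deviation over 10 prediction-time dropout draws),
and a-priori expectancy (random-forest probability of above-median MCC
from the presence/absence pattern alone; the median threshold is this
package's binarization choice).  Factors are standardized; weights come
from least squares of held-out MCC on the factors; alpha is the empirical
CDF of the linear score on the calibration set, hence always in [0, 1].
Constant factors receive weight zero and are flagged.

## Chemistry-to-signature distillation

A fingerprint-only model (2048-bit Morgan, radius 2 → three ReLU hidden
layers of 1024/512/256 with dropout 0.2 → Tanh head of 128,
L2-normalized by default) is trained with Adam at 1e-3 for 30 epochs
against inferred signatures, with an 80:20 split and per-test-molecule
Pearson correlation as the report.  L2 normalization of the output is a
package choice for consistency with the inferred-signature invariants.

## Analytics

Inferred signatures are total, so per-space blocks concatenate (A1→E5
order) into a global signature (GSig; 3200-d for 25 spaces).  Similarity
is negative Euclidean distance throughout (monotone in cosine on
unit-norm blocks).  Cross-space agreement is the per-query ROC-AUC of
recovering a space's top-5 neighbors from another space's distances,
averaged over queries (per-query averaging makes identical spaces score
exactly 1; pooling over pairs would not).  Label sharing is the AUC of
GSig similarity for detecting pairs with a common annotation.  Empirical
similarity p-values come from sampled random-pair distance distributions
(order-statistic quantiles, +1 smoothing, seeded); a query–target pair is
a hit when its smallest per-space p-value falls below the threshold
("best across spaces").  Library analytics: k-means occupancy vectors
over K = round(sqrt(N/2)) reference clusters, Gini homogeneity in the
discrete mean-absolute-difference form Σij|xi − xj| / (2K Σxi),
average-linkage dendrograms over normalized occupancy vectors (Newick
output), and high-alpha vicinity — the mean 10-NN GSig distance to a
high-confidence reference subset with the fraction under the p = 0.01
distance threshold.

## SigAR models

Signature–activity relationship classifiers stack per-space signature
blocks as features (optionally excluding spaces that would leak the
label's provenance).  The base learner is a random forest tuned by
randomized search with exactly 10 candidate draws over
{100, 500, 1000} trees × {None, 5, 10} depth × {2, 3, 10} min-split ×
{gini, entropy} × {sqrt, log2} features, scored by 3-fold stratified
ROC-AUC (the fold count and metric are package choices).  Calibration is
Mondrian (class-conditional) cross-conformal prediction over 10
stratified folds: nonconformity 1 − p(true class), per-class p-values
pool fold counts with +1 smoothing, giving class-conditional error at
most epsilon at significance epsilon.  Scaffold-aware splits pack whole
scaffolds (largest first, seeded ties) into the training side so no test
scaffold is seen in training; very large tasks are handled by up to 30
stratified under-samples of 10,000 molecules (ensemble by probability
averaging).  Evaluation uses five stratified 80:20 splits and ROC/PR
AUC.  Signature-type importance ranks features by mean |SHAP| (an
in-package path-dependent TreeSHAP for sklearn forests, verified against
brute-force Shapley enumeration), sums within the top 250 features per
space, and normalizes by the largest per-space sum.  Y-scrambling
(training on permuted labels, testing on intact ones) is the negative
control; its expected ROC-AUC is 0.5.

## Synthetic universes

The generator emulates the two structural facts the method relies on:
cross-space correlation and block missingness.  Latent factors
z ~ N(0, I_h) are shared; space s sees a sparse factor subset through a
random loading matrix L_s and observes `tanh(z L_sᵀ/√k + ε)`,
ε ~ N(0, 0.1²) by default.  The first two (chemistry-like) spaces are
fully covered; others drop a configured fraction of molecules.  Defaults
— 2000 molecules, 8 spaces, width 128, 16 latent factors, 50 % loading
density, 30 % missingness — are the package's standing study conditions
for metric-learning experiments; SigAR and distillation experiments use
smaller widths (16–32) because their checks depend on sample counts, not
signature width, and this keeps full runs on one CPU within minutes.
Binary tasks threshold a random linear latent score at its median
(balanced labels) with optional label flipping; `flip_rate = 0.5` is the
exact no-signal limit.  Scaffold labels are k-means cluster ids
(k = n/50) on the first chemistry space — a stand-in for Murcko
scaffolds that preserves the property scaffold splits test (groups of
structurally similar molecules leave the training set together).
Synthetic fingerprints fire bit b when a random latent projection
exceeds a random threshold, so structure determines bits as chemistry
determines real fingerprints; per-molecule bit-position scrambling is
the matched control.

What the generator does *not* emulate: heavy-tailed and discrete
signature value distributions, correlated (non-independent) missingness
driven by database provenance, chemical series redundancy, class
imbalance of real screening data, and real Murcko scaffold topology.
Passing tests therefore demonstrate the machinery's correctness and the
method's behavior under its own assumptions, not performance levels on
real corpora.

## Numerical choices and degenerate inputs

Distances are plain Euclidean; ties in neighbor orderings break by
molecule key (stable).  The L2 output head guards the zero vector by
emitting the unit vector e_1 (reachable only for pathological inputs).
MCC on an empty contingency margin returns 0 with a flag; AUC operations
return NaN when fewer than 20 molecules are shared or no positive pair
exists.  Near-duplicate removal keeps the lexicographically smallest key
of each single-linkage group.  Empirical p-values are +1-smoothed so the
smallest attainable p is 1/(n_pairs + 1) and a zero threshold yields no
hits.  Undersampling distributes rounding remainders to the largest
classes, keeping subset class ratios within one sample of the full data.

## Known limitations

The numpy training engine is single-threaded and sized for desk-scale
runs (10^3–10^4 molecules, 10^4–10^5 triplets); the published-scale
regime (10^6 molecules, 10^7 triplets) would need a GPU framework behind
the same interfaces.  Approximate nearest-neighbor backends are out of
scope — all searches are exact.  Applicability calibration is an
empirical CDF, so alpha values are ranks, comparable within one space
and calibration set but not across differently calibrated models.
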