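# biosig

Bioactivity signatures — fixed-width vector representations of what a
small molecule *does* (targets it binds, cells it perturbs, clinical
effects it causes) rather than what it *is* — are only experimentally
available for a small, well-studied corner of chemical space.  `biosig`
implements a family of models that infer these signatures for any
molecule and put the inferences to work, for computational drug-discovery
practitioners who want biology-aware descriptors as drop-in replacements
for structural fingerprints.

The package covers, end to end:

* **Signature store** — a multi-space (A1–E5, chemistry→clinics)
  collection of per-molecule signature matrices with block missingness,
  HDF5-backed, with cross-coverage accounting and covariate stacking.
* **Signaturizers** — per-space Siamese neural networks trained on
  molecule triplets (anchor, positive, negative) with a signature-dropout
  scheme that simulates realistic prediction-time availability of the
  other spaces.  Output signatures are 128-d, Tanh-activated and
  L2-normalized, so Euclidean similarity search works uniformly.
* **Applicability scores** — a calibrated confidence alpha in [0, 1] per
  inferred signature, combining five factors: distance to training
  signatures, a supervised accuracy estimate, signature intensity,
  robustness under input dropout, and the accuracy expected a priori from
  which covariate spaces the molecule has.
* **Distillation** — chemistry-to-signature models mapping 2048-bit
  Morgan fingerprints directly to inferred signatures, for on-the-fly use.
* **Analytics** — global-signature (GSig) stacking, cross-space
  recall AUCs, shared-label AUCs, empirical-p-value similarity queries,
  k-means occupancy vectors with Gini homogeneity, and library
  dendrograms.
* **SigAR models** — signature–activity relationship classifiers (random
  forests with Mondrian cross-conformal calibration, scaffold-aware
  splits, SHAP-by-signature-type interpretation, Y-scrambling controls).
* **Synthetic universes** — a first-class generator of miniature
  multi-space collections with shared latent factors, configurable
  missingness, label tasks and synthetic fingerprints, so everything is
  testable without external data.

## The model in brief

For a target space S_i with n molecules, the covariates matrix
X ∈ R^(n × 128m) stacks the signature blocks of the m spaces covering at
least 10 % of S_i.  A shared-weight network
f: X → e ∈ S^127 (Gaussian input noise σ=0.1 → dense h₁, SeLU,
alpha-dropout 0.2 → dense h₂, SeLU, alpha-dropout 0.2 → dense 128, Tanh,
L2-norm; h₁ = min(512, 64m), h₂ = min(256, 32m)) is trained on triplets
(a, p, n) sampled from S_i neighborhoods to minimize

    L = max(0, ‖e_a − e_p‖ − ‖e_a − e_n‖ + 1)
      + ‖e_a^dropout − e_a^{S_i-only}‖²/128
      + α_GOR · (M₁² + max(0, M₂ − 1/128)),

with Adam (lr 1e-4).  Covariate blocks are masked during training with
the probabilities that they would be missing for molecules outside S_i;
the S_i block itself oscillates between fully present and fully absent
(5000 cycles/epoch).  See `docs/methods.md` for assumptions, parameter
meanings, and design choices.

## Worked example

```python
from biosig import UniverseConfig, generate_universe
from biosig.store import stack_covariates
from biosig.triplets import sample_triplets, split_molecules, tune_k
from biosig.siamese import SiameseSpec, train
from biosig.evaluation import evaluate

universe = generate_universe(
    UniverseConfig(n_molecules=400, n_spaces=5, d=32, h=8, seed=11)
)
target = "A3"
train_keys, test_keys = split_molecules(universe[target].keys, seed=11)
k = tune_k(universe, target, seed=11)
triplets = sample_triplets(
    universe[target], 4000, k=k, seed=11,
    train_keys=train_keys, test_keys=test_keys,
)
model = train(universe, target, triplets, SiameseSpec(seed=11))
report = evaluate(model, stack_covariates(universe, target), triplets)

print(f"tuned k: {k}")
for split, acc in report.triplet_accuracy.items():
    print(f"triplet accuracy [{split}]: {acc:.3f}")
print(f"median per-molecule MCC: {report.mcc_quantiles[0.5]:.3f}")
```

Output:

```
tuned k: 10
triplet accuracy [train_train]: 0.777
triplet accuracy [test_train]: 0.730
triplet accuracy [test_test]: 0.676
median per-molecule MCC: 0.328
```

The triplet accuracies are the fraction of sampled triplets whose
anchor–positive embedding distance is smaller than the anchor–negative
one *with the target space withheld from the input* — i.e. how well the
other spaces alone recover S_i neighborhoods — reported on triplets of
increasing difficulty (all-train, test anchor with train mates, all
held-out).  The per-molecule MCC compares the signs of the inferred
signature against the signature computed from the target block alone.
This 400-molecule universe is deliberately tiny; at the package's
standing study scale (2000 molecules, 8 spaces, 50,000 triplets) held-out
triplet accuracies exceed 0.8, as asserted by the test suite.

A thin CLI exposes the common entry points
(`biosig store inspect|coverage`, `biosig synth universe|tasks`,
`biosig train`, `biosig layer-sizes`, `biosig gini`).

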