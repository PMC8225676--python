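"""Accuracy surfaces for trained signaturizers.

Two complementary views: a triplet accuracy (the fraction of sampled
triplets whose anchor-positive embedding distance is smaller than the
anchor-negative one, with the target-space block withheld from the input),
reported per split of increasing difficulty, and a per-molecule agreement
between the signature inferred *without* the target block and the
"truth" embedding computed from the target block alone.  Because the Tanh
head makes signature components bimodal, agreement is measured as a
Matthews correlation coefficient over the 2x2 sign-contingency table of
the 128 dimensions, not as a Pearson correlation.  A neighbor-recovery
curve checks that inferred signatures retrieve experimentally supported
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .store import SignatureSpace

__all__ = [
    "EvaluationReport",
    "triplet_accuracy",
    "binarize",
    "mcc_correlation",
    "mcc_profile",
    "neighbor_recall",
    "evaluate",
]

SPLITS = ("train_train", "test_train", "test_test")


@dataclass
class EvaluationReport:
    space_id: str
    triplet_accuracy: dict
    mcc: np.ndarray
    mcc_quantiles: dict


def triplet_accuracy(signaturizer, covariates, triplet_set, drop_target: bool = True):
    """Fraction of correctly ordered triplets per split.

    A triplet counts as correct iff ||e_a - e_p|| < ||e_a - e_n|| with the
    target block removed from all three inputs (the realistic scenario
    where S_i is what we are trying to infer).  Empty splits are reported
    as None, not 0.
    """
    drop = [signaturizer.space_id_] if drop_target else None
    emb = signaturizer.transform(covariates, drop_blocks=drop)
    idx = {k: i for i, k in enumerate(covariates.keys)}
    out = {}
    for split in SPLITS:
        sub = triplet_set.subset(split)
        if len(sub) == 0:
            out[split] = None
            continue
        a = emb[[idx[k] for k in sub.anchors]]
        p = emb[[idx[k] for k in sub.positives]]
        n = emb[[idx[k] for k in sub.negatives]]
        d_ap = np.linalg.norm(a - p, axis=1)
        d_an = np.linalg.norm(a - n, axis=1)
        out[split] = float(np.mean(d_ap < d_an))
    return out


def binarize(signature) -> np.ndarray:
    """Sign of each component; exact zeros map to +1 (documented tie rule)."""
    sig = np.asarray(signature, dtype=float)
    if not np.all(np.isfinite(sig)):
        raise ValueError("signature must be finite")
    return np.where(sig >= 0, 1, -1)


def mcc_correlation(predicted, truth, return_flag: bool = False):
    """Matthews correlation over the sign-contingency of two signatures.

    The 128 dimensions of both vectors are binarized (positive/negative)
    and cross-tabulated; MCC = (TP*TN - FP*FN) / sqrt of the product of
    the four marginals.  A zero marginal makes the formula undefined; 0 is
    returned with ``degenerate=True`` when ``return_flag`` is set.
    """
    p = binarize(predicted)
    t = binarize(truth)
    if p.shape != t.shape:
        raise ValueError("signature width mismatch")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == -1) & (t == -1)))
    fp = int(np.sum((p == 1) & (t == -1)))
    fn = int(np.sum((p == -1) & (t == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return (0.0, True) if return_flag else 0.0
    mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return (float(mcc), False) if return_flag else float(mcc)


def mcc_profile(signaturizer, covariates, keys=None) -> np.ndarray:
    """Per-molecule MCC between dropped-out and target-only embeddings."""
    pred = signaturizer.transform(covariates, drop_blocks=[signaturizer.space_id_])
    truth = signaturizer.transform(covariates, only_target=True)
    if keys is not None:
        idx = {k: i for i, k in enumerate(covariates.keys)}
        rows = [idx[k] for k in keys]
        pred, truth = pred[rows], truth[rows]
    return np.asarray([mcc_correlation(p, t) for p, t in zip(pred, truth)])


def neighbor_recall(
    inferred_space: SignatureSpace,
    truth_space: SignatureSpace,
    top_t=(1, 10, 100),
    exclude=(),
    n_true: int = 5,
):
    """Fraction of queries with >=1 true neighbor among their top-t predictions.

    True neighbor sets are each query's ``n_true`` nearest molecules in the
    experimental (truth) space; predicted rankings come from the inferred
    space.  ``exclude`` keys are removed from the candidate pool.  Returns
    (recall dict, number of queries evaluated).
    """
    exclude = set(exclude)
    shared = [k for k in inferred_space.keys if k in set(truth_space.keys.tolist())]
    candidates = [k for k in shared if k not in exclude]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate molecules")
    vi = inferred_space.rows(candidates)
    vt = truth_space.rows(candidates)
    d_pred = cdist(vi, vi)
    d_true = cdist(vt, vt)
    np.fill_diagonal(d_pred, np.inf)
    np.fill_diagonal(d_true, np.inf)
    n = len(candidates)
    hits = {t: 0 for t in top_t}
    evaluated = 0
    for i in range(n):
        true_set = set(np.argsort(d_true[i], kind="stable")[:n_true])
        if not true_set:
            continue
        evaluated += 1
        ranked = np.argsort(d_pred[i], kind="stable")
        for t in top_t:
            if true_set & set(ranked[:t]):
                hits[t] += 1
    recall = {t: hits[t] / evaluated for t in top_t}
    return recall, evaluated


def evaluate(signaturizer, covariates, triplet_set) -> EvaluationReport:
    """Full report: per-split triplet accuracy + per-molecule MCC summary."""
    acc = triplet_accuracy(signaturizer, covariates, triplet_set)
    mcc = mcc_profile(signaturizer, covariates)
    qs = {q: float(np.quantile(mcc, q)) for q in (0.1, 0.25, 0.5, 0.75, 0.9)}
    return EvaluationReport(
        space_id=signaturizer.space_id_,
        triplet_accuracy=acc,
        mcc=mcc,
        mcc_quantiles=qs,
    )
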