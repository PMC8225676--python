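"""Molecule splitting and triplet sampling for metric learning.

For one target space, the training signal is a set of (anchor, positive,
negative) molecule triples: the positive is drawn from the anchor's
k-nearest neighbors in the target space, the negative uniformly from
molecules strictly farther than the chosen positive, so every triplet
satisfies d(a, p) < d(a, n) by construction.  Molecules are first split
80:20 (after near-duplicate removal) and triplets are labeled
train_train / test_train / test_test by the membership of their members,
so the three evaluation regimes of increasing difficulty are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .store import SignatureSpace, Store

__all__ = [
    "Triplet",
    "TripletSet",
    "remove_near_duplicates",
    "split_molecules",
    "clip_k",
    "tune_k",
    "sample_triplets",
]

K_MIN, K_MAX = 10, 50


@dataclass(frozen=True)
class Triplet:
    anchor: str
    positive: str
    negative: str
    space_id: str = ""


@dataclass
class TripletSet:
    """Columnar triplet container: parallel key arrays plus split labels."""

    space_id: str
    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    splits: np.ndarray  # train_train | test_train | test_test
    k_used: int = 0
    truncated_anchors: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        for a, p, n in zip(self.anchors, self.positives, self.negatives):
            yield Triplet(a, p, n, self.space_id)

    def subset(self, split: str) -> "TripletSet":
        mask = self.splits == split
        return TripletSet(
            self.space_id,
            self.anchors[mask],
            self.positives[mask],
            self.negatives[mask],
            self.splits[mask],
            self.k_used,
        )


def remove_near_duplicates(space: SignatureSpace, epsilon: float = 1e-6) -> list:
    """Keys retained after collapsing near-duplicate signatures.

    Molecules closer than ``epsilon`` (Euclidean) are single-linkage
    grouped; the lexicographically lowest key of each group is kept, so no
    retained pair is within ``epsilon`` of each other.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if space.n == 0:
        raise ValueError("space is empty")
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from sklearn.neighbors import NearestNeighbors

    n = space.n
    rows, cols = [], []
    if epsilon > 0:
        nn = NearestNeighbors(radius=epsilon).fit(space.values)
        dists, idxs = nn.radius_neighbors(space.values, return_distance=True)
        for i, (di, ji) in enumerate(zip(dists, idxs)):
            for d, j in zip(di, ji):
                if j != i and d < epsilon:  # strict: pairs at exactly epsilon stay
                    rows.append(i)
                    cols.append(int(j))
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    keep: dict[int, str] = {}
    for key, comp in zip(space.keys, labels):
        if comp not in keep or str(key) < str(keep[comp]):
            keep[comp] = key
    return sorted(keep.values())


def split_molecules(keys, fraction: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive train/test split with |train| = round(fraction*n)."""
    keys = np.asarray(list(keys), dtype=object)
    if len(keys) < 5:
        raise ValueError("need at least 5 keys to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_train = int(round(fraction * len(keys)))
    return keys[order[:n_train]].tolist(), keys[order[n_train:]].tolist()


def clip_k(k: int, lo: int = K_MIN, hi: int = K_MAX) -> int:
    """Clip the neighbor count to the admissible [10, 50] range."""
    return int(min(max(int(k), lo), hi))


def _neighbor_order(values: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Per-row candidate ordering by (distance, key), self excluded."""
    d = cdist(values, values)
    n = len(keys)
    order = np.empty((n, n - 1), dtype=int)
    key_rank = np.argsort(np.argsort(keys.astype(str)))
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        order[i] = idx[np.lexsort((key_rank[idx], d[i, idx]))]
    return order


def tune_k(
    store: Store,
    target_space: str,
    candidates=(5, 10, 15, 20, 25, 30, 40, 50, 60, 80),
    max_anchors: int = 200,
    seed: int = 0,
) -> int:
    """Choose k by cross-space neighbor agreement, clipped to [10, 50].

    For each candidate k and each other space S_j overlapping the target:
    a shared-molecule pair (a, b) is labeled positive when b lies within
    a's k-nearest set in S_j, and scored by (negative) target-space
    distance; the per-space ROC-AUCs are averaged and the best candidate
    (before clipping) is returned clipped.
    """
    if target_space not in store:
        raise KeyError(target_space)
    target = store[target_space]
    rng = np.random.default_rng(seed)
    others = []
    for sid in store.space_ids:
        if sid == target_space:
            continue
        shared = sorted(set(store[sid].keys.tolist()) & set(target.keys.tolist()))
        if len(shared) >= 10:
            others.append((sid, shared))
    if not others:
        raise ValueError(f"no space overlaps target {target_space!r}")

    mean_auc = {k: [] for k in candidates}
    for sid, shared in others:
        shared = np.asarray(shared, dtype=object)
        if len(shared) > max_anchors:
            shared = shared[rng.permutation(len(shared))[:max_anchors]]
            shared = np.asarray(sorted(shared), dtype=object)
        vt = target.rows(shared)
        vj = store[sid].rows(shared)
        d_target = cdist(vt, vt)
        order_j = _neighbor_order(vj, shared)
        n = len(shared)
        scores = []
        for i in range(n):
            idx = np.delete(np.arange(n), i)
            scores.append(-d_target[i, idx])
        scores = np.concatenate(scores)
        for k in candidates:
            kk = min(k, n - 1)
            labels = np.zeros((n, n - 1), dtype=bool)
            for i in range(n):
                pos = set(order_j[i, :kk])
                idx = np.delete(np.arange(n), i)
                labels[i] = np.isin(idx, list(pos))
            lab = labels.ravel()
            if lab.all() or not lab.any():
                continue
            mean_auc[k].append(roc_auc_score(lab, scores))
    avg = {k: np.mean(v) for k, v in mean_auc.items() if v}
    if not avg:
        raise ValueError("k tuning degenerate: no informative space")
    best = max(avg, key=lambda k: (avg[k], -k))
    return clip_k(best)


def sample_triplets(
    space: SignatureSpace,
    n_triplets: int,
    k: int,
    seed: int = 0,
    train_keys=None,
    test_keys=None,
) -> TripletSet:
    """Sample ceil(n_triplets / n) triplets per anchor molecule.

    The positive is uniform over the anchor's k-nearest neighbors within
    the triplet's molecule pool (train pool for train_train and
    test_train triplets, test pool for test_test), the negative uniform
    over pool molecules strictly farther than the chosen positive.  Test
    anchors alternate between test_train and test_test pools.  Anchors
    whose pool has fewer than k+1 molecules use a truncated k and are
    recorded in ``truncated_anchors``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = space.n
    if n_triplets < n:
        raise ValueError("need at least one triplet per anchor")
    keys = space.keys
    if train_keys is None or test_keys is None:
        train_keys, test_keys = split_molecules(keys, seed=seed)
    train_set = set(train_keys) & set(keys.tolist())
    test_set = set(test_keys) & set(keys.tolist())
    idx_of = space.key_index()
    pools = {
        "train": np.asarray(sorted(train_set), dtype=object),
        "test": np.asarray(sorted(test_set), dtype=object),
    }
    pool_idx = {name: np.asarray([idx_of[key] for key in p]) for name, p in pools.items()}

    per_anchor = int(np.ceil(n_triplets / n))
    rng = np.random.default_rng(seed)
    anchors, positives, negatives, splits = [], [], [], []
    truncated = []

    key_rank = np.argsort(np.argsort(keys.astype(str)))
    for key in keys:
        i = idx_of[key]
        in_train = key in train_set
        if in_train:
            plan = [("train", "train_train", per_anchor)]
        else:
            n_tt = (per_anchor + 1) // 2
            plan = [
                ("train", "test_train", n_tt),
                ("test", "test_test", per_anchor - n_tt),
            ]
        for pool_name, split, count in plan:
            if count == 0:
                continue
            cand = pool_idx[pool_name]
            cand = cand[cand != i]
            if len(cand) < 2:
                continue
            d = np.linalg.norm(space.values[cand] - space.values[i], axis=1)
            sort = np.lexsort((key_rank[cand], d))
            order = cand[sort]
            d_sorted = d[sort]
            kk = min(k, len(order) - 1)
            if kk < k and key not in truncated:
                truncated.append(key)
            if kk < 1:
                continue
            for _ in range(count):
                # retry positives in case the pool ties at one distance
                for _retry in range(5):
                    j = rng.integers(kk)
                    p_idx = order[j]
                    farther = order[d_sorted > d_sorted[j]]
                    if len(farther):
                        n_idx = farther[rng.integers(len(farther))]
                        anchors.append(key)
                        positives.append(keys[p_idx])
                        negatives.append(keys[n_idx])
                        splits.append(split)
                        break

    return TripletSet(
        space_id=space.space_id,
        anchors=np.asarray(anchors, dtype=object),
        positives=np.asarray(positives, dtype=object),
        negatives=np.asarray(negatives, dtype=object),
        splits=np.asarray(splits, dtype=object),
        k_used=k,
        truncated_anchors=truncated,
    )
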