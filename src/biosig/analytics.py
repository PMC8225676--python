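"""Global-signature stacking and signature-space analytics.

Inferred per-space signatures are total (every molecule gets one), so they
can be concatenated in fixed chemistry-to-clinics order into a global
signature (GSig; 25 x 128 = 3200 dimensions when all spaces are present).
This module provides the map- and library-level machinery built on these
vectors: cross-space neighbor-recall AUC, shared-label AUC, empirical
similarity p-values and distance thresholds, "best-across-spaces"
similarity queries, k-means cluster occupancy vectors with their Gini
homogeneity, high-applicability vicinity summaries, and hierarchical
clustering of compound libraries by occupancy.

Similarity is scored as negative Euclidean distance throughout; on
unit-norm signatures this is monotone in cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

from .store import SignatureSpace, Store
from .synthetic import SPACE_NAMES

__all__ = [
    "GlobalSignatureSet",
    "OccupancyVector",
    "stack_gsig",
    "cross_space_auc",
    "pairwise_label_auc",
    "empirical_distance_threshold",
    "similarity_query",
    "kmeans_occupancy",
    "gini",
    "high_alpha_vicinity",
    "library_dendrogram",
]


@dataclass
class GlobalSignatureSet:
    """Stacked global signatures: block i of ``values`` is space ``space_ids[i]``."""

    keys: np.ndarray
    values: np.ndarray
    space_ids: list
    d: int = 128

    def block(self, space_id: str) -> np.ndarray:
        i = self.space_ids.index(space_id)
        return self.values[:, i * self.d : (i + 1) * self.d]

    def rows(self, keys) -> np.ndarray:
        idx = {k: i for i, k in enumerate(self.keys)}
        return self.values[[idx[k] for k in keys]]


@dataclass
class OccupancyVector:
    """Distribution of one library over the reference k-means clusters."""

    library_id: str
    frequencies: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if (self.frequencies < 0).any():
            raise ValueError("occupancy frequencies must be nonnegative")


def stack_gsig(store: Store, keys=None) -> GlobalSignatureSet:
    """Concatenate inferred spaces (A1 -> E5 order) into global signatures.

    Every requested space must hold an inferred signature for every key;
    a space still lacking inference raises with an instruction to run
    predict first.
    """
    space_ids = [s for s in SPACE_NAMES if s in store]
    if not space_ids:
        raise ValueError("store holds no spaces")
    for sid in space_ids:
        if store[sid].kind != "inferred":
            raise ValueError(
                f"space {sid} has no inferred signatures; run the signaturizer's "
                "predict over the full universe first"
            )
    if keys is None:
        keys = store[space_ids[0]].keys.tolist()
    keys = np.asarray(list(keys), dtype=object)
    d = store[space_ids[0]].d
    blocks = []
    for sid in space_ids:
        sp = store[sid]
        missing = set(keys.tolist()) - set(sp.keys.tolist())
        if missing:
            raise ValueError(
                f"space {sid} lacks inferred signatures for {len(missing)} keys; "
                "run predict over the full universe first"
            )
        blocks.append(sp.rows(keys))
    return GlobalSignatureSet(
        keys=keys, values=np.hstack(blocks), space_ids=space_ids, d=d
    )


def cross_space_auc(
    space_i: SignatureSpace, space_j: SignatureSpace, top: int = 5, subset=None
) -> float:
    """Capacity of S_i similarities to recall top-`top` S_j neighbors (ROC-AUC).

    For each shared molecule, its `top` nearest neighbors in S_j (self
    excluded) are the positives; all other shared molecules are negatives;
    candidates are scored by negative S_i distance.  Per-query AUCs are
    averaged (so identical spaces score exactly 1).  Returns NaN when
    fewer than 20 molecules are shared.
    """
    shared = sorted(set(space_i.keys.tolist()) & set(space_j.keys.tolist()))
    if subset is not None:
        shared = sorted(set(shared) & set(subset))
    if len(shared) < 20:
        return float("nan")
    vi = space_i.rows(shared)
    vj = space_j.rows(shared)
    di = cdist(vi, vi)
    dj = cdist(vj, vj)
    np.fill_diagonal(di, np.inf)
    np.fill_diagonal(dj, np.inf)
    n = len(shared)
    aucs = []
    for q in range(n):
        pos = np.argsort(dj[q], kind="stable")[:top]
        lab = np.zeros(n, dtype=bool)
        lab[pos] = True
        mask = np.arange(n) != q
        if lab[mask].all() or not lab[mask].any():
            continue
        aucs.append(roc_auc_score(lab[mask], -di[q, mask]))
    return float(np.mean(aucs))


def pairwise_label_auc(gsigs: GlobalSignatureSet, label_map: dict) -> float:
    """AUC of GSig similarity for detecting pairs sharing >= 1 label.

    ``label_map`` maps key -> set of labels; molecules without labels are
    ignored.  Returns NaN when no positive pair exists.
    """
    keys = [k for k in gsigs.keys if label_map.get(k)]
    if len(keys) < 2:
        return float("nan")
    V = gsigs.rows(keys)
    d = cdist(V, V)
    n = len(keys)
    iu = np.triu_indices(n, k=1)
    labels = np.asarray(
        [bool(label_map[keys[i]] & label_map[keys[j]]) for i, j in zip(*iu)]
    )
    if labels.all() or not labels.any():
        return float("nan")
    return float(roc_auc_score(labels, -d[iu]))


def empirical_distance_threshold(
    values: np.ndarray, p: float, n_pairs: int = 100_000, seed: int = 0
) -> float:
    """Distance below which a random pair lands with probability ~p.

    Samples ``n_pairs`` random (distinct) row pairs and returns the
    p-quantile as an order statistic: the ceil(p * n_pairs)-th smallest
    sampled distance (the maximum for p = 1).
    """
    values = np.asarray(values, dtype=float)
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n_pairs * p < 1:
        raise ValueError("too few pairs sampled for the requested p")
    rng = np.random.default_rng(seed)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 rows")
    i = rng.integers(n, size=n_pairs)
    j = rng.integers(n, size=n_pairs)
    clash = i == j
    while clash.any():
        j[clash] = rng.integers(n, size=int(clash.sum()))
        clash = i == j
    dists = np.sort(np.linalg.norm(values[i] - values[j], axis=1))
    return float(dists[int(np.ceil(p * n_pairs)) - 1])


def similarity_query(
    query_space_rows: dict,
    target_space_rows: dict,
    background_rows: dict,
    p_threshold: float,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Best-across-spaces empirical-p-value similarity search.

    Parameters are per-space mappings: ``query_space_rows[sid]`` and
    ``target_space_rows[sid]`` are (keys, matrix) pairs for the query and
    target sets, ``background_rows[sid]`` the matrix the empirical null is
    sampled from.  A query-target pair is a hit when its smallest
    per-space empirical p-value (+1-smoothed, so never exactly 0) is below
    ``p_threshold``.
    """
    if not query_space_rows:
        raise ValueError("empty space list")
    rng = np.random.default_rng(seed)
    spaces = sorted(query_space_rows)
    null: dict = {}
    for sid in spaces:
        bg = np.asarray(background_rows[sid], dtype=float)
        i = rng.integers(len(bg), size=n_pairs)
        j = rng.integers(len(bg), size=n_pairs)
        keep = i != j
        null[sid] = np.sort(np.linalg.norm(bg[i[keep]] - bg[j[keep]], axis=1))
    rows = []
    qkeys, _ = query_space_rows[spaces[0]]
    tkeys, _ = target_space_rows[spaces[0]]
    for qi, qk in enumerate(qkeys):
        for ti, tk in enumerate(tkeys):
            pvals = {}
            for sid in spaces:
                _, qv = query_space_rows[sid]
                _, tv = target_space_rows[sid]
                d = float(np.linalg.norm(qv[qi] - tv[ti]))
                m = len(null[sid])
                pvals[sid] = (np.searchsorted(null[sid], d, side="right") + 1) / (m + 1)
            best = min(pvals, key=pvals.get)
            rows.append(
                {
                    "query": qk,
                    "target": tk,
                    **{f"p_{sid}": pvals[sid] for sid in spaces},
                    "best_space": best,
                    "best_p": pvals[best],
                    "hit": pvals[best] < p_threshold,
                }
            )
    return pd.DataFrame(rows)


def kmeans_occupancy(
    reference_gsigs: np.ndarray,
    library_gsigs: np.ndarray,
    seed: int = 0,
    library_id: str = "library",
    kmeans: KMeans | None = None,
):
    """Library occupancy over K = round(sqrt(N/2)) reference clusters.

    Returns (OccupancyVector, fitted KMeans); pass ``kmeans`` to reuse a
    reference clustering across libraries.  An empty library yields the
    zero vector, flagged.
    """
    ref = np.asarray(reference_gsigs, dtype=float)
    if kmeans is None:
        if len(ref) < 8:
            raise ValueError("reference must hold at least 8 molecules")
        K = int(round(np.sqrt(len(ref) / 2)))
        kmeans = KMeans(n_clusters=K, n_init=4, random_state=seed).fit(ref)
    K = kmeans.n_clusters
    lib = np.asarray(library_gsigs, dtype=float)
    if len(lib) == 0:
        return OccupancyVector(library_id, np.zeros(K), empty=True), kmeans
    assign = kmeans.predict(lib)
    freq = np.bincount(assign, minlength=K) / len(lib)
    return OccupancyVector(library_id, freq, empty=False), kmeans


def gini(occupancy) -> float:
    """Gini coefficient, mean-absolute-difference form.

    G = sum_ij |x_i - x_j| / (2 K sum_i x_i); 0 for a uniform vector,
    (K-1)/K for a one-hot vector over K clusters.
    """
    x = np.asarray(
        occupancy.frequencies if isinstance(occupancy, OccupancyVector) else occupancy,
        dtype=float,
    )
    if (x < 0).any():
        raise ValueError("occupancy must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("zero-sum occupancy: Gini undefined")
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2 * len(x) * total))


def high_alpha_vicinity(
    library_gsigs: np.ndarray,
    high_alpha_reference: np.ndarray,
    k: int = 10,
    threshold: float | None = None,
    p: float = 0.01,
    n_pairs: int = 10_000,
    seed: int = 0,
    exclude_self: bool = False,
):
    """Mean k-NN distance of library molecules to the high-alpha reference.

    Returns (per-molecule mean distances, fraction below the significance
    threshold).  The threshold defaults to the empirical p = 0.01 distance
    of random reference pairs.  With ``exclude_self`` a zero-distance
    nearest match (the molecule itself appearing in the reference) is
    discarded before averaging.
    """
    lib = np.atleast_2d(np.asarray(library_gsigs, dtype=float))
    ref = np.atleast_2d(np.asarray(high_alpha_reference, dtype=float))
    kk = min(k, len(ref))
    d = cdist(lib, ref)
    d.sort(axis=1)
    if exclude_self:
        means = np.empty(len(lib))
        for i in range(len(lib)):
            row = d[i]
            row = row[row > 0] if (row == 0).any() else row
            means[i] = row[: min(kk, len(row))].mean()
    else:
        means = d[:, :kk].mean(axis=1)
    if threshold is None:
        threshold = empirical_distance_threshold(ref, p=p, n_pairs=n_pairs, seed=seed)
    frac = float(np.mean(means < threshold))
    return means, frac


def _newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def library_dendrogram(occupancy_vectors: dict):
    """Average-linkage hierarchy of libraries by occupancy distance.

    ``occupancy_vectors`` maps library_id -> occupancy vector (normalized
    to sum 1 before comparison).  Returns (newick string, distance
    DataFrame, scipy linkage matrix).
    """
    if len(occupancy_vectors) < 2:
        raise ValueError("need at least 2 libraries")
    ids = sorted(occupancy_vectors)
    mats = []
    for lid in ids:
        v = occupancy_vectors[lid]
        v = np.asarray(
            v.frequencies if isinstance(v, OccupancyVector) else v, dtype=float
        )
        s = v.sum()
        mats.append(v / s if s > 0 else v)
    V = np.vstack(mats)
    dm = cdist(V, V)
    Z = linkage(squareform(dm, checks=False), method="average")
    tree = to_tree(Z)
    newick = _newick(tree, ids) + ";"
    return newick, pd.DataFrame(dm, index=ids, columns=ids), Z
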