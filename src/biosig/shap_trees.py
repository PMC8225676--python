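"""Path-dependent SHAP values for scikit-learn tree ensembles.

Computes exact Shapley values of the conditional-expectation game defined
by a decision tree's own cover statistics: when a feature is "absent" the
tree is descended through both children weighted by their training cover.
This is the polynomial-time path-dependent TreeSHAP recursion; for a
forest, per-tree attributions are averaged (forests average their trees'
outputs, and Shapley values are linear in the value function).

Only what the signature-type importance analysis needs is implemented:
binary classifiers (attributions of the positive-class probability) and
regressors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values", "expected_value_conditioned"]


class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self):
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(path, pz, po, pi):
    path = [el.copy() for el in path]
    path.append(_PathElement(pi, pz, po, 1.0 if not path else 0.0))
    l = len(path) - 1
    for i in range(l - 1, -1, -1):
        path[i + 1].w += po * path[i].w * (i + 1) / (l + 1)
        path[i].w = pz * path[i].w * (l - i) / (l + 1)
    return path


def _unwind(path, i):
    path = [el.copy() for el in path]
    l = len(path) - 1
    po, pz = path[i].o, path[i].z
    n = path[l].w
    for j in range(l - 1, -1, -1):
        if po != 0:
            t = path[j].w
            path[j].w = n * (l + 1) / ((j + 1) * po)
            n = t - path[j].w * pz * (l - j) / (l + 1)
        else:
            path[j].w = path[j].w * (l + 1) / (pz * (l - j))
    for j in range(i, l):
        path[j].d, path[j].z, path[j].o = path[j + 1].d, path[j + 1].z, path[j + 1].o
    path.pop()
    return path


def _unwound_sum(path, i):
    l = len(path) - 1
    po, pz = path[i].o, path[i].z
    total = 0.0
    if po != 0:
        n = path[l].w
        for j in range(l - 1, -1, -1):
            tmp = n / ((j + 1) * po)
            total += tmp
            n = path[j].w - tmp * pz * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += path[j].w / (pz * (l - j))
    return total * (l + 1)


def _leaf_values(tree, positive_class: bool) -> np.ndarray:
    v = tree.value  # (n_nodes, 1, n_outputs) or class counts
    if positive_class:
        counts = v[:, 0, :]
        with np.errstate(invalid="ignore"):
            probs = counts / counts.sum(axis=1, keepdims=True)
        return probs[:, 1]
    return v[:, 0, 0]


def tree_shap_values(tree, x: np.ndarray, positive_class: bool = True) -> np.ndarray:
    """SHAP values of one fitted sklearn tree for a single sample ``x``."""
    t = tree.tree_
    values = _leaf_values(t, positive_class)
    cover = t.weighted_n_node_samples
    phi = np.zeros(len(x))

    def recurse(node, path, pz, po, pi):
        path = _extend(path, pz, po, pi)
        left, right = t.children_left[node], t.children_right[node]
        if left < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[el.d] += w * (el.o - el.z) * values[node]
            return
        f = t.feature[node]
        hot, cold = (
            (left, right) if x[f] <= t.threshold[node] else (right, left)
        )
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(path)) if path[i].d == f), 0)
        if k:
            iz, io = path[k].z, path[k].o
            path = _unwind(path, k)
        recurse(hot, path, iz * cover[hot] / cover[node], io, f)
        recurse(cold, path, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def forest_shap_values(model, X: np.ndarray, positive_class: bool = True) -> np.ndarray:
    """(n_samples, n_features) SHAP matrix for a fitted sklearn forest."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float32))
    estimators = getattr(model, "estimators_", [model])
    out = np.zeros((len(X), X.shape[1]))
    for est in estimators:
        for i, x in enumerate(X):
            out[i] += tree_shap_values(est, x, positive_class=positive_class)
    return out / len(estimators)


def expected_value_conditioned(tree, x, feature_set, positive_class: bool = True):
    """Path-dependent E[f(x)] with features in ``feature_set`` fixed to x.

    The independent brute-force game definition TreeSHAP attributes: at a
    split on a conditioned feature follow x; otherwise average children by
    cover.  Used as the enumeration oracle in tests.
    """
    t = tree.tree_
    values = _leaf_values(t, positive_class)
    cover = t.weighted_n_node_samples
    fs = set(feature_set)

    def walk(node):
        left, right = t.children_left[node], t.children_right[node]
        if left < 0:
            return values[node]
        f = t.feature[node]
        if f in fs:
            child = left if x[f] <= t.threshold[node] else right
            return walk(child)
        return (cover[left] * walk(left) + cover[right] * walk(right)) / cover[node]

    return walk(0)
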