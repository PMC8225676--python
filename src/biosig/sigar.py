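"""Signature-activity relationship (SigAR) models.

The biological analogue of SAR on chemical fingerprints: a classifier
learns active/inactive labels from horizontally stacked per-space
signatures.  The pipeline is deliberately generic — a random forest with a
small randomized hyperparameter search — so the signal comes from the
features, not the learner.  Prediction confidence is calibrated with a
Mondrian (class-conditional) cross-conformal scheme over 10 stratified
folds, which guarantees per-class error rates at any chosen significance.
Evaluation follows activity-benchmark practice: stratified or
scaffold-aware splits (no training scaffold appears in the test set),
under-sampling ensembles for very large tasks, ROC/PR AUC metrics,
signature-type importance via SHAP aggregation, and Y-scrambling controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import (
    ParameterSampler,
    StratifiedKFold,
    StratifiedShuffleSplit,
    cross_val_score,
)

from .shap_trees import forest_shap_values
from .store import Store
from .synthetic import SPACE_NAMES

__all__ = [
    "HYPERPARAMETER_GRID",
    "SigARModel",
    "ImportanceProfile",
    "stack_features",
    "tune_base_learner",
    "MondrianConformalForest",
    "mondrian_cross_conformal",
    "scaffold_split",
    "undersample_large",
    "evaluate_task",
    "shap_type_importance",
    "y_scramble",
]

#: randomized-search space of the base learner
HYPERPARAMETER_GRID = {
    "n_estimators": [100, 500, 1000],
    "max_depth": [None, 5, 10],
    "min_samples_split": [2, 3, 10],
    "criterion": ["gini", "entropy"],
    "max_features": ["sqrt", "log2"],
}

N_SEARCH_ITER = 10


@dataclass
class ImportanceProfile:
    """Per-space cumulative |SHAP| within the top-ranked features, max 1."""

    space_ids: list
    values: np.ndarray
    cap: int = 250

    def as_dict(self) -> dict:
        return dict(zip(self.space_ids, self.values))


def stack_features(store: Store, keys, excluded_spaces=()):
    """Stacked signature features for the given keys.

    Returns (feature matrix of width d * n_retained_spaces, block map:
    per-column space id).  Excluding every space is an error.
    """
    excluded = set(excluded_spaces)
    space_ids = [s for s in SPACE_NAMES if s in store and s not in excluded]
    if not space_ids:
        raise ValueError("all spaces excluded: no features left")
    keys = list(keys)
    blocks, block_map = [], []
    for sid in space_ids:
        sp = store[sid]
        missing = set(keys) - set(sp.keys.tolist())
        if missing:
            raise ValueError(f"space {sid} lacks signatures for {len(missing)} keys")
        blocks.append(sp.rows(keys))
        block_map.extend([sid] * sp.d)
    return np.hstack(blocks), np.asarray(block_map, dtype=object)


def tune_base_learner(train_features, labels, seed: int = 0, cv_folds: int = 3):
    """Randomized search (exactly 10 candidates) over the forest grid.

    Selection by mean 3-fold stratified ROC-AUC.  Returns (best params,
    evaluation log of (params, score) pairs).
    """
    X = np.asarray(train_features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    sampler = ParameterSampler(
        HYPERPARAMETER_GRID, n_iter=N_SEARCH_ITER, random_state=seed
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    log = []
    for params in sampler:
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        score = float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="roc_auc")))
        log.append((params, score))
    best = max(log, key=lambda t: t[1])[0]
    return best, log


class MondrianConformalForest(BaseEstimator, ClassifierMixin):
    """Random forest calibrated by Mondrian cross-conformal prediction.

    Ten stratified folds; each fold's model is fit on the other nine and
    supplies class-conditional calibration nonconformity scores
    (1 - predicted probability of the true class) for its own fold.  At
    prediction time the per-class p-value pools the fold counts with the
    +1 smoothing convention, so p-values are always in (0, 1], and the
    class-conditional error at significance eps is bounded by eps.

    Parameters
    ----------
    base_params : dict or None
        Forest hyperparameters (e.g. from :func:`tune_base_learner`).
    n_folds : int, default 10
    seed : int
    """

    def __init__(self, base_params: dict | None = None, n_folds: int = 10, seed: int = 0):
        self.base_params = base_params
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if (counts < self.n_folds).any():
            raise ValueError(
                f"every class needs >= {self.n_folds} samples for "
                f"{self.n_folds}-fold conformal calibration"
            )
        params = self.base_params or {}
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        self.models_ = []
        # calibration_[k][c] = sorted nonconformity scores of class c in fold k
        self.calibration_ = []
        for fit_idx, cal_idx in skf.split(X, y):
            clf = RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
            clf.fit(X[fit_idx], y[fit_idx])
            proba = clf.predict_proba(X[cal_idx])
            cal = {}
            for ci, c in enumerate(self.classes_):
                mask = y[cal_idx] == c
                cal[c] = np.sort(1.0 - proba[mask, ci])
            self.models_.append(clf)
            self.calibration_.append(cal)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X)
        return np.mean([m.predict_proba(X) for m in self.models_], axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_p(self, X) -> np.ndarray:
        """Per-class conformal p-values, shape (n_samples, n_classes)."""
        X = np.asarray(X)
        n = len(X)
        p = np.zeros((n, len(self.classes_)))
        ge_counts = np.zeros((n, len(self.classes_)))
        n_cal = np.zeros(len(self.classes_))
        for model, cal in zip(self.models_, self.calibration_):
            proba = model.predict_proba(X)
            for ci, c in enumerate(self.classes_):
                scores = 1.0 - proba[:, ci]
                # count calibration scores >= test score
                ge_counts[:, ci] += len(cal[c]) - np.searchsorted(
                    cal[c], scores, side="left"
                )
        for ci, c in enumerate(self.classes_):
            n_cal[ci] = sum(len(cal[c]) for cal in self.calibration_)
            p[:, ci] = (ge_counts[:, ci] + 1) / (n_cal[ci] + 1)
        return p

    def predict_set(self, X, epsilon: float) -> list:
        """Conformal prediction sets at significance ``epsilon``."""
        p = self.predict_p(X)
        return [self.classes_[row > epsilon].tolist() for row in p]


@dataclass
class SigARModel:
    """A tuned, conformally calibrated SigAR classifier plus provenance."""

    task_id: str
    classifier: MondrianConformalForest
    base_params: dict
    tuning_log: list
    feature_block_map: np.ndarray
    excluded_spaces: list = field(default_factory=list)


def mondrian_cross_conformal(
    features, labels, folds: int = 10, seed: int = 0, base_params: dict | None = None
) -> MondrianConformalForest:
    """Functional wrapper fitting a :class:`MondrianConformalForest`."""
    return MondrianConformalForest(
        base_params=base_params, n_folds=folds, seed=seed
    ).fit(features, labels)


def scaffold_split(keys, scaffold_labels, fraction: float = 0.8, seed: int = 0):
    """Leak-free split: train and test share no scaffold.

    Whole scaffolds are packed (largest first, ties shuffled by seed) into
    the training side until it reaches round(fraction * n); the remainder
    is the test side, so the test fraction is as close to 1 - fraction as
    whole scaffolds allow.
    """
    keys = np.asarray(list(keys), dtype=object)
    scaffold_labels = np.asarray(list(scaffold_labels), dtype=object)
    uniq = np.unique(scaffold_labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 scaffolds to split")
    rng = np.random.default_rng(seed)
    groups = {s: np.where(scaffold_labels == s)[0] for s in uniq}
    order = sorted(
        rng.permutation(uniq).tolist(), key=lambda s: -len(groups[s])
    )
    target = int(round(fraction * len(keys)))
    train_idx: list = []
    test_idx: list = []
    for s in order:
        if len(train_idx) < target:
            train_idx.extend(groups[s])
        else:
            test_idx.extend(groups[s])
    if not test_idx:  # every scaffold was consumed by train; free the smallest
        smallest = order[-1]
        test_idx = groups[smallest].tolist()
        train_idx = [i for i in train_idx if i not in set(test_idx)]
    return keys[sorted(train_idx)].tolist(), keys[sorted(test_idx)].tolist()


def undersample_large(
    features, labels, max_sets: int = 30, set_size: int = 10_000, seed: int = 0
) -> list:
    """Stratified under-sampled index subsets for very large tasks.

    Tasks with n <= set_size come back as a single identity subset;
    larger tasks yield min(max_sets, ceil(n / set_size)) subsets of
    ``set_size`` samples whose class ratio matches the full data within
    one sample.
    """
    y = np.asarray(labels)
    n = len(y)
    if n <= set_size:
        return [np.arange(n)]
    n_sets = min(max_sets, int(np.ceil(n / set_size)))
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    ratio = counts / n
    take = np.floor(set_size * ratio).astype(int)
    # distribute the rounding remainder to the largest classes
    for i in np.argsort(-ratio)[: set_size - take.sum()]:
        take[i] += 1
    subsets = []
    for _ in range(n_sets):
        idx = []
        for c, t in zip(classes, take):
            pool = np.where(y == c)[0]
            idx.append(rng.choice(pool, size=t, replace=False))
        subsets.append(np.sort(np.concatenate(idx)))
    return subsets


def evaluate_task(
    model_builder,
    features,
    labels,
    n_splits: int = 5,
    metric: str = "roc_auc",
    seed: int = 0,
    test_fraction: float = 0.2,
):
    """Mean +- sd of a metric over stratified 80:20 train-test splits.

    ``model_builder()`` must return an unfitted classifier exposing
    ``predict_proba``; ``metric`` is "roc_auc" or "pr_auc".
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    scorer = {
        "roc_auc": roc_auc_score,
        "pr_auc": average_precision_score,
    }[metric]
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    scores = []
    for tr, te in sss.split(X, y):
        if len(np.unique(y[te])) < 2:  # pragma: no cover - stratified guard
            continue
        model = model_builder()
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])[:, 1]
        scores.append(scorer(y[te], proba))
    return float(np.mean(scores)), float(np.std(scores))


def shap_type_importance(model, features, block_map, cap: int = 250) -> ImportanceProfile:
    """Cumulative |SHAP| per signature type within the top-ranked features.

    Features are ranked by mean absolute SHAP across molecules; within the
    top ``cap`` the per-space sums are normalized by the largest, so the
    most explanatory signature type scores 1.
    """
    forest = getattr(model, "models_", None)
    if forest:  # conformal wrapper: average fold forests
        shap = np.mean(
            [forest_shap_values(m, features) for m in forest], axis=0
        )
    else:
        if not hasattr(model, "estimators_") and not hasattr(model, "tree_"):
            raise TypeError("SHAP aggregation needs a fitted tree or tree ensemble")
        shap = forest_shap_values(model, features)
    block_map = np.asarray(block_map, dtype=object)
    mean_abs = np.abs(shap).mean(axis=0)
    top = np.argsort(-mean_abs, kind="stable")[:cap]
    space_ids = sorted(set(block_map.tolist()), key=SPACE_NAMES.index)
    sums = np.zeros(len(space_ids))
    for rank_idx in top:
        sums[space_ids.index(block_map[rank_idx])] += mean_abs[rank_idx]
    m = sums.max()
    return ImportanceProfile(
        space_ids=space_ids, values=sums / m if m > 0 else sums, cap=cap
    )


def y_scramble(
    features,
    labels,
    model_builder,
    n_repeats: int = 10,
    seed: int = 0,
    test_fraction: float = 0.2,
    with_intact: bool = True,
):
    """Label-permutation control: train on shuffled Y, test on intact Y.

    Returns a dict with per-repeat "scrambled" ROC-AUCs and, when
    ``with_intact``, the matching intact-label AUCs for the same splits.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(features)
    y = np.asarray(labels)
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    rng = np.random.default_rng(seed)
    scrambled, intact = [], []
    for tr, te in sss.split(X, y):
        y_perm = y[tr][rng.permutation(len(tr))]
        model = model_builder()
        if len(np.unique(y_perm)) < 2:  # pragma: no cover - balanced tasks
            continue
        model.fit(X[tr], y_perm)
        scrambled.append(roc_auc_score(y[te], model.predict_proba(X[te])[:, 1]))
        if with_intact:
            m2 = model_builder()
            m2.fit(X[tr], y[tr])
            intact.append(roc_auc_score(y[te], m2.predict_proba(X[te])[:, 1]))
    return {"scrambled": np.asarray(scrambled), "intact": np.asarray(intact)}
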