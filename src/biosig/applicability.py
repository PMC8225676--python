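"""Applicability score (alpha) for inferred signatures.

Every inferred signature gets a confidence estimate combining five factors
grouped in three characteristics:

*distance to the applicability domain* — (1) the average distance of the
predicted signature to its 5/25 nearest training signatures, (2) a random
forest regression of the achievable accuracy (per-molecule MCC) from the
signature itself, and (3) an intensity term, the mean absolute deviation
from the null (average training) signature, which separates informative
signatures from the "innocuous molecule" region;

*robustness* — (4) the ensemble standard deviation of predictions under
repeated prediction-time signature dropout;

*a-priori expectancy* — (5) a random forest classification of accuracy
from the 25 presence/absence covariate-block flags alone.

The five factors are standardized, combined by least squares against
held-out per-molecule MCC, and the linear score is calibrated to [0, 1]
by its empirical CDF on the calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ApplicabilityRecord",
    "nn_distance_factor",
    "supervised_accuracy_factor",
    "intensity_factor",
    "robustness_factor",
    "prior_expectancy_factor",
    "ApplicabilityScorer",
    "ApplicabilityModel",
    "FACTOR_NAMES",
]

FACTOR_NAMES = (
    "nn_distance",
    "supervised_accuracy",
    "intensity",
    "robustness_sd",
    "prior_expectancy",
)


@dataclass
class ApplicabilityRecord:
    key: str
    nn_distance: float
    supervised_accuracy: float
    intensity: float
    robustness_sd: float
    prior_expectancy: float
    alpha: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.robustness_sd < 0:
            raise ValueError("intensity and robustness must be nonnegative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


def nn_distance_factor(pred_signatures, training_signatures) -> np.ndarray:
    """Mean of the average distances to the 5 and 25 nearest training rows.

    With fewer than 25 training signatures all of them are used for the
    second average (the factor degrades gracefully on tiny spaces).
    """
    pred = np.atleast_2d(np.asarray(pred_signatures, dtype=float))
    train = np.atleast_2d(np.asarray(training_signatures, dtype=float))
    k5 = min(5, len(train))
    k25 = min(25, len(train))
    nn = NearestNeighbors(n_neighbors=k25).fit(train)
    dists, _ = nn.kneighbors(pred)
    return (dists[:, :k5].mean(axis=1) + dists[:, :k25].mean(axis=1)) / 2.0


def supervised_accuracy_factor(
    pred_signatures, accuracy_targets, seed: int = 0, n_folds: int = 5
):
    """Random forest regression of per-molecule accuracy from signatures.

    Returns (fitted regressor, out-of-fold predictions).  Refuses to fit
    below 50 molecules (the factor would be mostly noise).
    """
    X = np.atleast_2d(np.asarray(pred_signatures, dtype=float))
    y = np.asarray(accuracy_targets, dtype=float)
    if len(X) < 50:
        raise ValueError("need >= 50 molecules to fit the supervised factor")
    model = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = cross_val_predict(model, X, y, cv=cv)
    model.fit(X, y)
    return model, oof


def intensity_factor(pred_signatures, null_signature) -> np.ndarray:
    """Mean absolute deviation from the null (average training) signature."""
    pred = np.atleast_2d(np.asarray(pred_signatures, dtype=float))
    null = np.asarray(null_signature, dtype=float)
    return np.abs(pred - null).mean(axis=1)


def robustness_factor(
    signaturizer, covariates, n_draws: int = 10, seed: int = 0
) -> np.ndarray:
    """Mean componentwise standard deviation over a dropout ensemble.

    Exactly ``n_draws`` forward passes with independently dropped-out
    inputs; small values indicate predictions that do not depend on which
    covariate blocks happen to be available.
    """
    ens = signaturizer.ensemble_transform(covariates, n_draws=n_draws, seed=seed)
    return ens.std(axis=0).mean(axis=1)


def prior_expectancy_factor(
    presence_patterns, accuracy_labels, seed: int = 0, n_folds: int = 5
):
    """P(high accuracy) from the presence/absence pattern alone.

    ``accuracy_labels`` are binary (per-molecule MCC above/below the
    training-set median).  Single-class inputs return a constant
    probability with a degenerate flag.
    """
    X = np.atleast_2d(np.asarray(presence_patterns, dtype=float))
    y = np.asarray(accuracy_labels, dtype=int)
    if len(np.unique(y)) < 2:
        return None, np.full(len(X), float(y[0]) if len(y) else 0.5), True
    model = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(model, X, y, cv=cv, method="predict_proba")[:, 1]
    model.fit(X, y)
    return model, proba, False


class ApplicabilityScorer(BaseEstimator):
    """Combine standardized factors into a calibrated alpha in [0, 1].

    Fit least-squares weights of held-out MCC on the standardized factors;
    score new factor vectors by the linear combination mapped through the
    empirical CDF of the calibration scores.  Constant factors get weight
    zero (flagged in ``degenerate_factors_``).
    """

    def __init__(self) -> None:
        pass

    def fit(self, factors, mcc):
        X = np.atleast_2d(np.asarray(factors, dtype=float))
        y = np.asarray(mcc, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.degenerate_factors_ = np.where(sd == 0)[0].tolist()
        self.sd_ = np.where(sd == 0, 1.0, sd)
        Z = (X - self.mean_) / self.sd_
        Z[:, self.degenerate_factors_] = 0.0
        A = np.column_stack([Z, np.ones(len(Z))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.weights_ = coef[:-1]
        self.weights_[self.degenerate_factors_] = 0.0
        self.intercept_ = coef[-1]
        self.calibration_scores_ = np.sort(Z @ self.weights_ + self.intercept_)
        return self

    def score_samples(self, factors) -> np.ndarray:
        """Alpha per row: empirical-CDF position of the linear score."""
        X = np.atleast_2d(np.asarray(factors, dtype=float))
        Z = (X - self.mean_) / self.sd_
        Z[:, self.degenerate_factors_] = 0.0
        raw = Z @ self.weights_ + self.intercept_
        ranks = np.searchsorted(self.calibration_scores_, raw, side="right")
        return ranks / len(self.calibration_scores_)

    transform = score_samples


class ApplicabilityModel:
    """End-to-end applicability estimation for one fitted signaturizer.

    ``fit`` learns the factor models (nearest-neighbor reference, the two
    random forests, the null signature) from per-molecule MCC targets and
    tunes/calibrates the linear alpha combination on the held-out rows;
    ``score`` produces :class:`ApplicabilityRecord` rows for any
    covariates, using the fitted factor models only.
    """

    def __init__(self, signaturizer, n_draws: int = 10, seed: int = 0) -> None:
        self.signaturizer = signaturizer
        self.n_draws = n_draws
        self.seed = seed

    def _base_factors(self, covariates, presence=None, seed=None):
        sig = self.signaturizer
        pred = sig.transform(covariates, drop_blocks=[sig.space_id_])
        f_nn = nn_distance_factor(pred, self.reference_)
        f_int = intensity_factor(pred, self.null_signature_)
        f_rob = robustness_factor(
            sig, covariates, n_draws=self.n_draws,
            seed=self.seed if seed is None else seed,
        )
        if presence is None:
            presence = covariates.presence
        return pred, f_nn, f_int, f_rob, np.asarray(presence, dtype=float)

    def fit(self, covariates, mcc, train_mask, calibration_mask=None):
        """Fit factor models and the alpha combination.

        ``train_mask`` marks rows whose target-only embeddings form the
        training-signature reference; ``calibration_mask`` (default: the
        complement) marks the held-out rows the linear weights and the
        empirical-CDF calibration are tuned on.
        """
        sig = self.signaturizer
        mcc = np.asarray(mcc, dtype=float)
        train_mask = np.asarray(train_mask, dtype=bool)
        if calibration_mask is None:
            calibration_mask = ~train_mask
        calibration_mask = np.asarray(calibration_mask, dtype=bool)
        truth = sig.transform(covariates, only_target=True)
        self.reference_ = truth[train_mask]
        self.null_signature_ = self.reference_.mean(axis=0)
        pred, f_nn, f_int, f_rob, presence = self._base_factors(covariates)
        self.supervised_model_, f_sup = supervised_accuracy_factor(
            pred, mcc, seed=self.seed
        )
        labels = (mcc >= np.median(mcc[train_mask])).astype(int)
        self.expectancy_model_, f_exp, self.expectancy_degenerate_ = (
            prior_expectancy_factor(presence, labels, seed=self.seed)
        )
        self.factors_ = np.column_stack([f_nn, f_sup, f_int, f_rob, f_exp])
        self.scorer_ = ApplicabilityScorer().fit(
            self.factors_[calibration_mask], mcc[calibration_mask]
        )
        self.alpha_ = self.scorer_.score_samples(self.factors_)
        return self

    def factor_matrix(self, covariates, presence=None, seed=None) -> np.ndarray:
        """(n, 5) factor matrix via the fitted factor models."""
        pred, f_nn, f_int, f_rob, presence = self._base_factors(
            covariates, presence, seed=seed
        )
        f_sup = self.supervised_model_.predict(pred)
        if self.expectancy_model_ is None:
            f_exp = np.full(len(pred), 0.5)
        else:
            f_exp = self.expectancy_model_.predict_proba(presence)[:, 1]
        return np.column_stack([f_nn, f_sup, f_int, f_rob, f_exp])

    def score(self, covariates, keys=None, presence=None, seed=None) -> list:
        """Alpha records (five factors + calibrated alpha) per molecule."""
        factors = self.factor_matrix(covariates, presence, seed=seed)
        alpha = self.scorer_.score_samples(factors)
        if keys is None:
            keys = getattr(covariates, "keys", None)
            if keys is None:
                keys = [f"row{i}" for i in range(len(factors))]
        return [
            ApplicabilityRecord(str(k), *map(float, f), float(a))
            for k, f, a in zip(keys, factors, alpha)
        ]
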