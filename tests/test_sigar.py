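import copy
import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from biosig.shap_trees import (
    expected_value_conditioned,
    forest_shap_values,
    tree_shap_values,
)
from biosig.sigar import (
    HYPERPARAMETER_GRID,
    MondrianConformalForest,
    scaffold_split,
    shap_type_importance,
    stack_features,
    tune_base_learner,
    undersample_large,
    y_scramble,
)
from biosig.store import SignatureSpace, Store


def signal_task(n=300, d=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(n) > 0).astype(int)
    return X, y


class TestStackFeatures:
    @staticmethod
    def _store(rng, n_spaces=3, d=4):
        from biosig.synthetic import SPACE_NAMES

        keys = [f"m{i}" for i in range(8)]
        return Store(
            {
                sid: SignatureSpace(sid, keys, rng.standard_normal((8, d)))
                for sid in SPACE_NAMES[:n_spaces]
            },
            width=d,
        ), keys

    def test_width_and_block_map(self, rng):
        st, keys = self._store(rng)
        X, bm = stack_features(st, keys)
        assert X.shape == (8, 12)
        assert bm.tolist() == ["A1"] * 4 + ["A2"] * 4 + ["A3"] * 4

    def test_exclusion_removes_block(self, rng):
        st, keys = self._store(rng)
        X, bm = stack_features(st, keys, excluded_spaces={"A2"})
        assert X.shape == (8, 8)
        assert "A2" not in set(bm.tolist())

    def test_excluding_all_rejected(self, rng):
        st, keys = self._store(rng)
        with pytest.raises(ValueError):
            stack_features(st, keys, excluded_spaces={"A1", "A2", "A3"})


class TestTuneBaseLearner:
    def test_ten_evaluations_on_grid(self):
        X, y = signal_task(n=120, seed=1)
        best, log = tune_base_learner(X, y, seed=0)
        assert len(log) == 10
        for params, score in log:
            for key, value in params.items():
                assert value in HYPERPARAMETER_GRID[key]
            assert 0 <= score <= 1
        best_score = max(s for _, s in log)
        assert any(p == best and s == best_score for p, s in log)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_base_learner(rng.standard_normal((30, 4)), np.ones(30), seed=0)


@pytest.fixture(scope="module")
def conformal_fitted():
    X, y = signal_task(n=400, seed=2)
    model = MondrianConformalForest(
        base_params={"n_estimators": 100}, seed=0
    ).fit(X[:300], y[:300])
    return model, X[300:], y[300:]


class TestMondrianConformal:
    @pytest.fixture()
    def fitted(self, conformal_fitted):
        return conformal_fitted

    def test_p_values_in_unit_interval(self, fitted):
        model, Xte, _ = fitted
        p = model.predict_p(Xte)
        assert np.all((p > 0) & (p <= 1))

    def test_class_conditional_validity(self, fitted):
        model, Xte, yte = fitted
        eps = 0.2
        sets = model.predict_set(Xte, eps)
        for c in model.classes_:
            mask = yte == c
            errors = sum(c not in s for s, is_c in zip(sets, mask) if is_c)
            n_c = int(mask.sum())
            # one-sided binomial check: error rate not significantly > eps
            assert errors <= binom.ppf(0.975, n_c, eps)

    def test_duplicated_calibration_point_shifts_p_by_at_most_one_count(self, fitted):
        model, Xte, _ = fitted
        clone = copy.deepcopy(model)
        c = clone.classes_[0]
        extra = clone.calibration_[0][c][0]
        clone.calibration_[0][c] = np.sort(np.append(clone.calibration_[0][c], extra))
        n_cal = sum(len(cal[c]) for cal in model.calibration_)
        diff = np.abs(
            clone.predict_p(Xte[:20])[:, 0] - model.predict_p(Xte[:20])[:, 0]
        )
        assert diff.max() <= 1 / (n_cal + 1) + 1e-12

    def test_small_class_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.r_[np.ones(25, int), np.zeros(5, int)]
        with pytest.raises(ValueError, match="class"):
            MondrianConformalForest().fit(X, y)


class TestScaffoldSplit:
    def test_disjoint_scaffolds_always(self, rng):
        keys = [f"m{i}" for i in range(60)]
        scaff = rng.choice([f"s{j}" for j in range(9)], size=60)
        lookup = dict(zip(keys, scaff))
        for seed in range(10):
            tr, te = scaffold_split(keys, scaff, seed=seed)
            assert not {lookup[k] for k in tr} & {lookup[k] for k in te}
            assert sorted(tr + te) == sorted(keys)

    def test_greedy_packing_small_example(self):
        keys = [f"m{i}" for i in range(10)]
        scaff = ["a"] * 5 + ["b"] * 3 + ["c"] + ["d"]
        tr, te = scaffold_split(keys, scaff, fraction=0.8, seed=0)
        assert len(te) == 2  # two singleton scaffolds

    def test_deterministic(self, rng):
        keys = [f"m{i}" for i in range(40)]
        scaff = rng.choice(list("abcdef"), size=40)
        assert scaffold_split(keys, scaff, seed=3) == scaffold_split(keys, scaff, seed=3)

    def test_single_scaffold_rejected(self):
        with pytest.raises(ValueError):
            scaffold_split(["a", "b"], ["s", "s"])


class TestUndersample:
    def test_small_task_identity(self, rng):
        y = rng.integers(0, 2, 5000)
        subsets = undersample_large(None, y)
        assert len(subsets) == 1
        np.testing.assert_array_equal(subsets[0], np.arange(5000))

    def test_large_task_thirty_subsets(self, rng):
        n = 437_929
        y = (rng.random(n) < 0.02).astype(int)
        subsets = undersample_large(None, y, seed=0)
        assert len(subsets) == 30
        full_ratio = y.mean()
        for s in subsets:
            assert len(s) == 10_000
            assert abs(y[s].sum() - full_ratio * 10_000) <= 1

    def test_class_ratio_preserved(self, rng):
        y = (rng.random(25_000) < 0.3).astype(int)
        for s in undersample_large(None, y, set_size=4000, seed=1):
            assert abs(y[s].mean() - y.mean()) * 4000 <= 1


class TestEvaluateTask:
    def test_separable_task_near_one(self, rng):
        from biosig.sigar import evaluate_task

        X = np.vstack([rng.normal(3, 0.3, (60, 4)), rng.normal(-3, 0.3, (60, 4))])
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        mean, sd = evaluate_task(
            lambda: RandomForestClassifier(n_estimators=30, random_state=0),
            X, y, metric="roc_auc", seed=0,
        )
        assert mean > 0.99

    def test_chance_task_near_half(self, rng):
        from biosig.sigar import evaluate_task

        X = rng.standard_normal((300, 6))
        y = rng.integers(0, 2, 300)
        mean, sd = evaluate_task(
            lambda: RandomForestClassifier(n_estimators=30, random_state=0),
            X, y, metric="pr_auc", seed=0,
        )
        assert 0.35 < mean < 0.65


def brute_force_shapley(tree, x, n_features):
    """Exact Shapley values of the path-dependent conditional game."""
    used = sorted(
        {f for f in tree.tree_.feature if f >= 0}
    )
    phi = np.zeros(n_features)
    M = len(used)
    for i in used:
        others = [f for f in used if f != i]
        for r in range(M):
            for S in itertools.combinations(others, r):
                w = math.factorial(len(S)) * math.factorial(M - len(S) - 1) / math.factorial(M)
                gain = expected_value_conditioned(
                    tree, x, set(S) | {i}, positive_class=False
                ) - expected_value_conditioned(tree, x, set(S), positive_class=False)
                phi[i] += w * gain
    return phi


class TestTreeShap:
    def test_matches_brute_force_enumeration(self, rng):
        X = rng.standard_normal((80, 5))
        y = X[:, 0] * 2 + (X[:, 2] > 0) * 3 + rng.normal(0, 0.2, 80)
        tree = DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y)
        for x in X[:10]:
            fast = tree_shap_values(tree, x, positive_class=False)
            slow = brute_force_shapley(tree, x, 5)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_efficiency_property(self, rng):
        """SHAP values sum to prediction minus the tree's expected output."""
        X = rng.standard_normal((100, 6))
        y = (X[:, 1] - X[:, 3] > 0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=10, max_depth=4, random_state=0
        ).fit(X, y)
        shap = forest_shap_values(forest, X[:15])
        proba = forest.predict_proba(X[:15])[:, 1]
        base = np.mean(
            [
                expected_value_conditioned(t, X[0], set())
                for t in forest.estimators_
            ]
        )
        np.testing.assert_allclose(shap.sum(axis=1), proba - base, atol=1e-8)

    def test_regression_forest(self, rng):
        X = rng.standard_normal((60, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        forest = RandomForestRegressor(n_estimators=5, max_depth=3, random_state=0).fit(X, y)
        shap = forest_shap_values(forest, X[:5], positive_class=False)
        base = np.mean(
            [expected_value_conditioned(t, X[0], set(), False) for t in forest.estimators_]
        )
        np.testing.assert_allclose(shap.sum(axis=1), forest.predict(X[:5]) - base, atol=1e-8)


class TestShapTypeImportance:
    def test_planted_signal_space_attains_maximum(self, rng):
        n, d = 250, 6
        blocks = ["A1"] * d + ["B1"] * d + ["C1"] * d
        X = rng.standard_normal((n, 3 * d))
        y = (X[:, d : d + 2].sum(axis=1) > 0).astype(int)  # B1 drives labels
        clf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        profile = shap_type_importance(clf, X[:60], blocks)
        d_imp = profile.as_dict()
        assert max(d_imp.values()) == 1.0
        assert max(d_imp, key=d_imp.get) == "B1"

    def test_cap_semantics(self, rng):
        n, d = 120, 4
        blocks = ["A1"] * d + ["B1"] * d
        X = rng.standard_normal((n, 2 * d))
        y = (X[:, 0] > 0).astype(int)
        clf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        full = shap_type_importance(clf, X[:40], blocks, cap=8)
        capped = shap_type_importance(clf, X[:40], blocks, cap=1)
        # with cap=1 only the single top feature's space can score
        vals = sorted(capped.values)
        assert vals[-1] == 1.0 and vals[0] == 0.0
        assert max(full.values) == 1.0


class TestYScramble:
    def test_scrambled_near_chance_intact_above(self):
        X, y = signal_task(n=400, seed=5)
        res = y_scramble(
            X, y,
            lambda: RandomForestClassifier(n_estimators=50, random_state=0),
            n_repeats=5, seed=0,
        )
        assert abs(res["scrambled"].mean() - 0.5) < 0.1
        assert res["intact"].mean() > res["scrambled"].mean() + 0.2

    def test_zero_repeats_rejected(self):
        X, y = signal_task(n=60)
        with pytest.raises(ValueError):
            y_scramble(X, y, lambda: None, n_repeats=0)
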