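import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from biosig.analytics import (
    GlobalSignatureSet,
    cross_space_auc,
    empirical_distance_threshold,
    gini,
    high_alpha_vicinity,
    kmeans_occupancy,
    library_dendrogram,
    pairwise_label_auc,
    similarity_query,
    stack_gsig,
)
from biosig.store import SignatureSpace, Store


def inferred_space(space_id, keys, values):
    values = np.asarray(values, dtype=float)
    values = values / np.linalg.norm(values, axis=1, keepdims=True)
    return SignatureSpace(space_id, keys, values, kind="inferred")


class TestStackGsig:
    def test_full_25_space_width(self, rng):
        from biosig.synthetic import SPACE_NAMES

        keys = [f"m{i}" for i in range(6)]
        st = Store(
            {
                sid: inferred_space(sid, keys, rng.standard_normal((6, 128)))
                for sid in SPACE_NAMES
            }
        )
        gs = stack_gsig(st)
        assert gs.values.shape == (6, 3200)
        assert gs.space_ids == SPACE_NAMES

    def test_single_space_equals_signature(self, rng):
        keys = ["a", "b"]
        sp = inferred_space("A1", keys, rng.standard_normal((2, 8)))
        gs = stack_gsig(Store({"A1": sp}, width=8))
        np.testing.assert_array_equal(gs.values, sp.values)

    def test_block_slice_matches_space(self, rng):
        keys = ["a", "b", "c"]
        spaces = {
            sid: inferred_space(sid, keys, rng.standard_normal((3, 8)))
            for sid in ("A1", "B2")
        }
        gs = stack_gsig(Store(spaces, width=8))
        for sid in spaces:
            np.testing.assert_array_equal(gs.block(sid), spaces[sid].rows(keys))

    def test_experimental_space_instructs_to_predict(self, rng):
        sp = SignatureSpace("A1", ["a"], rng.standard_normal((1, 4)))
        with pytest.raises(ValueError, match="predict"):
            stack_gsig(Store({"A1": sp}, width=4))


def brute_force_cross_auc(vi, vj, top):
    """Exhaustive per-query AUC enumeration oracle (Mann-Whitney counts)."""
    n = len(vi)
    di = np.linalg.norm(vi[:, None] - vi[None], axis=2)
    dj = np.linalg.norm(vj[:, None] - vj[None], axis=2)
    aucs = []
    for q in range(n):
        order = sorted((j for j in range(n) if j != q), key=lambda j: dj[q, j])
        pos, neg = set(order[:top]), set(order[top:])
        wins = 0.0
        for p, m in itertools.product(pos, neg):
            if di[q, p] < di[q, m]:
                wins += 1
            elif di[q, p] == di[q, m]:
                wins += 0.5
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestCrossSpaceAuc:
    def test_identical_spaces_perfect(self, rng):
        keys = [f"m{i}" for i in range(30)]
        sp = inferred_space("A1", keys, rng.standard_normal((30, 8)))
        sp2 = inferred_space("A2", keys, sp.values)
        assert cross_space_auc(sp, sp2) == 1.0

    def test_independent_spaces_near_chance(self, rng):
        keys = [f"m{i}" for i in range(200)]
        a = inferred_space("A1", keys, rng.standard_normal((200, 8)))
        b = inferred_space("A2", keys, rng.standard_normal((200, 8)))
        assert abs(cross_space_auc(a, b) - 0.5) < 0.05

    def test_small_fixture_matches_enumeration(self, rng):
        keys = [f"m{i}" for i in range(25)]
        vi, vj = rng.standard_normal((25, 4)), rng.standard_normal((25, 4))
        a = inferred_space("A1", keys, vi)
        b = inferred_space("A2", keys, vj)
        assert cross_space_auc(a, b, top=3) == pytest.approx(
            brute_force_cross_auc(a.values, b.values, top=3)
        )

    def test_too_few_shared_is_nan(self, rng):
        keys = [f"m{i}" for i in range(5)]
        a = inferred_space("A1", keys, rng.standard_normal((5, 4)))
        assert np.isnan(cross_space_auc(a, a))


class TestPairwiseLabelAuc:
    def _gsigs(self, values, keys=None):
        keys = keys or [f"m{i}" for i in range(len(values))]
        return GlobalSignatureSet(
            keys=np.asarray(keys, dtype=object),
            values=np.asarray(values, dtype=float),
            space_ids=["A1"],
            d=np.asarray(values).shape[1],
        )

    def test_cluster_labels_near_perfect(self, rng):
        centers = np.array([[5.0, 0.0], [-5.0, 0.0]])
        vals = np.vstack([c + 0.1 * rng.standard_normal((20, 2)) for c in centers])
        labels = {f"m{i}": {"x" if i < 20 else "y"} for i in range(40)}
        assert pairwise_label_auc(self._gsigs(vals), labels) > 0.95

    def test_random_labels_near_chance(self, rng):
        vals = rng.standard_normal((60, 4))
        labels = {f"m{i}": {rng.choice(["a", "b", "c"])} for i in range(60)}
        assert abs(pairwise_label_auc(self._gsigs(vals), labels) - 0.5) < 0.15

    def test_four_molecule_hand_enumeration(self):
        vals = np.array([[0.0], [1.0], [4.0], [5.0]])
        labels = {"m0": {"a"}, "m1": {"a"}, "m2": {"b"}, "m3": {"b"}}
        # positive pairs: (0,1) d=1, (2,3) d=1; negatives: d in {4,5,3,4}
        # all positives score above all negatives -> AUC 1
        assert pairwise_label_auc(self._gsigs(vals), labels) == 1.0

    def test_no_positive_pair_is_nan(self):
        vals = np.array([[0.0], [1.0]])
        labels = {"m0": {"a"}, "m1": {"b"}}
        assert np.isnan(pairwise_label_auc(self._gsigs(vals), labels))


class TestEmpiricalThreshold:
    def test_p_one_is_maximum_and_monotone(self, rng):
        vals = rng.standard_normal((50, 4))
        t_all = empirical_distance_threshold(vals, 1.0, n_pairs=2000, seed=0)
        i = rng.integers(50, size=200_000)
        j = rng.integers(50, size=200_000)
        mask = i != j
        max_d = np.linalg.norm(vals[i[mask]] - vals[j[mask]], axis=1).max()
        assert t_all <= max_d * (1 + 1e-12)
        ts = [
            empirical_distance_threshold(vals, p, n_pairs=2000, seed=0)
            for p in (0.01, 0.1, 0.5, 1.0)
        ]
        assert ts == sorted(ts)

    def test_known_pair_distance_set(self):
        # two distinct points: every sampled pair distance is exactly 1
        vals = np.array([[0.0], [1.0]])
        for p in (0.01, 0.5, 1.0):
            assert empirical_distance_threshold(vals, p, n_pairs=1000) == 1.0

    def test_order_statistic_rank(self, rng):
        vals = rng.standard_normal((30, 3))
        t = empirical_distance_threshold(vals, 0.01, n_pairs=1000, seed=3)
        # reproduce the sample with the same seed: 10th smallest
        r = np.random.default_rng(3)
        i = r.integers(30, size=1000)
        j = r.integers(30, size=1000)
        clash = i == j
        while clash.any():
            j[clash] = r.integers(30, size=int(clash.sum()))
            clash = i == j
        d = np.sort(np.linalg.norm(vals[i] - vals[j], axis=1))
        assert t == d[9]

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            empirical_distance_threshold(rng.standard_normal((10, 2)), 0.001, n_pairs=100)


class TestSimilarityQuery:
    def _setup(self, rng):
        bg = rng.standard_normal((200, 4))
        queries = (np.asarray(["q0", "q1"], dtype=object), bg[:2].copy())
        targets = (np.asarray(["t0", "t1", "t2"], dtype=object),
                   np.vstack([bg[0], bg[50] + 8.0, bg[60] + 9.0]))
        return ({"A1": queries}, {"A1": targets}, {"A1": bg})

    def test_identical_pair_hits_at_smallest_p(self, rng):
        q, t, bg = self._setup(rng)
        table = similarity_query(q, t, bg, p_threshold=0.01, n_pairs=2000, seed=0)
        row = table[(table["query"] == "q0") & (table["target"] == "t0")].iloc[0]
        assert row["hit"]
        assert row["best_p"] == pytest.approx(1 / (2000 + 1), rel=0.01)

    def test_zero_threshold_no_hits(self, rng):
        q, t, bg = self._setup(rng)
        table = similarity_query(q, t, bg, p_threshold=0.0, n_pairs=2000, seed=0)
        assert not table["hit"].any()

    def test_threshold_equivalence(self, rng):
        q, t, bg = self._setup(rng)
        p = 0.05
        table = similarity_query(q, t, bg, p_threshold=p, n_pairs=2000, seed=0)
        thr = empirical_distance_threshold(bg["A1"], p, n_pairs=2000, seed=0)
        for _, row in table.iterrows():
            qv = q["A1"][1][list(q["A1"][0]).index(row["query"])]
            tv = t["A1"][1][list(t["A1"][0]).index(row["target"])]
            d = np.linalg.norm(qv - tv)
            if d < thr * 0.95:
                assert row["hit"]
            if d > thr * 1.05:
                assert not row["hit"]

    def test_empty_space_list_rejected(self):
        with pytest.raises(ValueError):
            similarity_query({}, {}, {}, p_threshold=0.01)


class TestOccupancy:
    def test_cluster_count_rule(self, rng):
        ref = rng.standard_normal((5000, 3))
        occ, km = kmeans_occupancy(ref, ref[:10], seed=0)
        assert km.n_clusters == 50

    def test_library_equals_reference(self, rng):
        ref = rng.standard_normal((200, 3))
        occ, km = kmeans_occupancy(ref, ref, seed=0)
        expected = np.bincount(km.predict(ref), minlength=km.n_clusters) / 200
        np.testing.assert_allclose(occ.frequencies, expected)
        assert occ.frequencies.sum() == pytest.approx(1.0)

    def test_empty_library_flagged(self, rng):
        ref = rng.standard_normal((100, 3))
        occ, _ = kmeans_occupancy(ref, ref[:0], seed=0)
        assert occ.empty and occ.frequencies.sum() == 0

    def test_deterministic(self, rng):
        ref = rng.standard_normal((120, 3))
        lib = rng.standard_normal((30, 3))
        a, _ = kmeans_occupancy(ref, lib, seed=4)
        b, _ = kmeans_occupancy(ref, lib, seed=4)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)


class TestGini:
    def test_uniform_zero(self):
        assert gini(np.full(10, 0.1)) == pytest.approx(0.0)

    @pytest.mark.parametrize("K", [2, 5, 50])
    def test_one_hot(self, K):
        v = np.zeros(K)
        v[0] = 1.0
        assert gini(v) == pytest.approx((K - 1) / K)

    def test_hand_evaluated(self):
        assert gini(np.array([0.75, 0.25])) == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        v = rng.random(12)
        assert gini(v) == pytest.approx(gini(1000 * v))

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            gini(np.zeros(4))


class TestHighAlphaVicinity:
    def test_matches_brute_force(self, rng):
        lib = rng.standard_normal((20, 3))
        ref = rng.standard_normal((50, 3))
        means, frac = high_alpha_vicinity(lib, ref, k=10, threshold=2.0)
        for i in range(20):
            d = np.sort(np.linalg.norm(ref - lib[i], axis=1))
            assert means[i] == pytest.approx(d[:10].mean())
        assert 0 <= frac <= 1
        assert frac == np.mean(means < 2.0)

    def test_self_exclusion(self, rng):
        ref = rng.standard_normal((30, 3))
        lib = ref[:5]
        incl, _ = high_alpha_vicinity(lib, ref, k=3, threshold=1.0)
        excl, _ = high_alpha_vicinity(lib, ref, k=3, threshold=1.0, exclude_self=True)
        assert np.all(excl > incl)
        assert np.all(excl > 0)


class TestLibraryDendrogram:
    def test_identical_libraries_merge_first(self, rng):
        v = rng.random(6)
        occ = {"lib_a": v, "lib_b": v.copy(), "lib_c": rng.random(6)}
        newick, dm, Z = library_dendrogram(occ)
        assert dm.loc["lib_a", "lib_b"] == 0.0
        first = sorted(Z[0, :2].astype(int))
        assert first == [sorted(occ).index("lib_a"), sorted(occ).index("lib_b")]
        assert newick.endswith(";") and "lib_c" in newick

    def test_hand_computed_merge_order(self):
        occ = {
            "x": np.array([1.0, 0.0]),
            "y": np.array([0.9, 0.1]),
            "z": np.array([0.0, 1.0]),
        }
        _, dm, Z = library_dendrogram(occ)
        # normalized vectors: d(x,y) = sqrt(2)*0.1, d(x,z) = sqrt(2)
        assert dm.loc["x", "y"] == pytest.approx(np.sqrt(2) * 0.1)
        ids = sorted(occ)
        assert sorted(Z[0, :2].astype(int)) == [ids.index("x"), ids.index("y")]

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        occ = {f"l{i}": rng.random(5) for i in range(4)}
        _, dm, _ = library_dendrogram(occ)
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_single_library_rejected(self, rng):
        with pytest.raises(ValueError):
            library_dendrogram({"only": rng.random(4)})
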