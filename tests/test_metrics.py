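import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import canberra as scipy_canberra
from scipy.stats import ks_2samp

import netdist as nd
from netdist.metrics import condensed_values


def ks_bruteforce(x, y):
    """Independent oracle: evaluate |F_x - F_y| at every pooled sample point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


class TestKS:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([0, 0], [1, 1], 1.0),
            ([1, 2, 3, 4], [3, 4, 5, 6], 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert nd.ks_statistic(a, b) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            nd.ks_statistic([], [1.0])

    def test_matches_bruteforce_on_random_instances(self):
        # 1,000 random small instances against the O(n^2) pooled-point oracle
        rng = np.random.default_rng(7)
        for _ in range(1000):
            nx, ny = rng.integers(1, 12, 2)
            x = rng.normal(size=nx)
            y = rng.normal(loc=rng.uniform(-1, 1), size=ny)
            if rng.random() < 0.3:  # inject ties
                x = np.round(x)
                y = np.round(y)
            assert nd.ks_statistic(x, y) == pytest.approx(ks_bruteforce(x, y))

    def test_pairwise_kernel_matches_scipy_and_scalar(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(8, 30))
        M[2] = np.round(M[2])  # exercise ties
        M[3] = np.round(M[3])
        vals, name, logged = condensed_values(M, "ks", log=False)
        assert name == "ks" and not logged
        r = 0
        for i in range(8):
            for j in range(i + 1, 8):
                assert vals[r] == pytest.approx(ks_2samp(M[i], M[j]).statistic)
                assert vals[r] == pytest.approx(nd.ks_statistic(M[i], M[j]))
                r += 1

    def test_numpy_fallback_kernel_agrees(self):
        # the searchsorted fallback must match the default (JIT) kernel
        from netdist._ks import _PAIRWISE_KS, _pairwise_ks_merge

        rng = np.random.default_rng(11)
        M = np.sort(rng.normal(size=(6, 40)), axis=1)
        M[1] = np.round(M[1])
        assert np.allclose(_pairwise_ks_merge(M), _PAIRWISE_KS(M))

    def test_log_ks_values_and_floor(self):
        assert nd.log_ks(1.0) == 0.0
        assert nd.log_ks(np.exp(-1.0)) == pytest.approx(-1.0)
        assert nd.log_ks(0.0) == pytest.approx(np.log(1e-12))
        with pytest.raises(ValueError):
            nd.log_ks(-0.1)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, jd",
        [
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([1, 1, 0, 0], [1, 0, 1, 0], 2 / 3),
            ([1, 0], [0, 1], 1.0),
        ],
    )
    def test_known_distances(self, a, b, jd):
        assert nd.jaccard_distance(a, b) == pytest.approx(jd)
        assert nd.jaccard_index(a, b) == pytest.approx(1 - jd)

    def test_both_empty_sets_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert nd.jaccard_distance([0, 0], [0, 0]) == 0.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            nd.jaccard_distance([0, 2], [0, 1])

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_distance_plus_index_is_one(self, a, seed):
        b = np.random.default_rng(seed).integers(0, 2, len(a))
        if not (any(a) or b.any()):
            return
        assert nd.jaccard_distance(a, b) + nd.jaccard_index(a, b) == pytest.approx(1.0)


class TestVectorDistances:
    @pytest.mark.parametrize(
        "a, b, p, expected",
        [
            ([3, 4], [0, 0], 2, 5.0),
            ([1, 2], [3, 5], 1, 5.0),
            ([1, 2, 3], [1, 2, 3], 2, 0.0),
        ],
    )
    def test_minkowski_known_values(self, a, b, p, expected):
        assert nd.minkowski_distance(a, b, p) == pytest.approx(expected)

    def test_minkowski_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            nd.minkowski_distance([1.0], [2.0], 0.5)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2], [3, 2], 0.5),
            ([1, 2], [1, 2], 0.0),
            ([0.0], [0.0], 0.0),  # 0/0 term contributes 0
        ],
    )
    def test_canberra_known_values(self, a, b, expected):
        assert nd.canberra_distance(a, b) == pytest.approx(expected)

    def test_canberra_matches_scipy(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 5, (2, 9))
            assert nd.canberra_distance(a, b) == pytest.approx(scipy_canberra(a, b))

    @given(st.integers(2, 15), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms(self, n, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 10, (2, n))
        for fn in (
            nd.ks_statistic,
            lambda u, v: nd.minkowski_distance(u, v, 2),
            lambda u, v: nd.minkowski_distance(u, v, 1),
            nd.canberra_distance,
        ):
            assert fn(a, a) == pytest.approx(0.0)
            assert fn(a, b) == pytest.approx(fn(b, a))
            assert fn(a, b) >= 0

    def test_euclidean_equals_explicit_formula(self, rng):
        a, b = rng.uniform(0, 10, (2, 20))
        explicit = np.sqrt(np.sum((a - b) ** 2))
        assert nd.euclidean_distance(a, b) == pytest.approx(explicit)


class TestPairwiseDistances:
    def test_pair_order_and_length(self):
        feats = [nd.DegreeVector([1.0, 2.0], subject_id=s) for s in "abc"]
        pv = nd.pairwise_distances(feats, "euclidean")
        assert len(pv) == 3
        assert pv.index.pairs() == [(0, 1), (0, 2), (1, 2)]

    def test_identical_features_give_zero(self):
        feats = [nd.DegreeVector([1.0, 2.0, 3.0]) for _ in range(4)]
        pv = nd.pairwise_distances(feats, "euclidean")
        assert np.all(pv.values == 0)

    def test_matches_scalar_operations(self):
        rows = [[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 0]]
        feats = [nd.KeyNodeVector(r) for r in rows]
        pv = nd.pairwise_distances(feats, "jaccard")
        expected = [
            nd.jaccard_distance(rows[i], rows[j])
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert np.allclose(pv.values, expected)

    def test_pairwise_jaccard_matches_scalar_on_random_sets(self, rng):
        # overlaps larger than one node must be counted, not just detected
        M = (rng.random((7, 25)) < 0.4).astype(int)
        vals, _, _ = condensed_values(M, "jaccard")
        r = 0
        for i in range(7):
            for j in range(i + 1, 7):
                assert vals[r] == pytest.approx(nd.jaccard_distance(M[i], M[j]))
                r += 1

    def test_ks_is_log_transformed_by_default(self, rng):
        feats = [nd.DegreeVector(rng.uniform(1, 2, 10)) for _ in range(3)]
        pv = nd.pairwise_distances(feats, "ks")
        assert pv.metric_name == "log_ks"
        assert pv.transform == "log"
        raw = nd.pairwise_distances(feats, "ks", log=False)
        assert np.allclose(pv.values, np.log(raw.values))

    def test_kind_mismatch_rejected(self):
        degs = [nd.DegreeVector([1.0, 2.0]) for _ in range(3)]
        with pytest.raises(ValueError):
            nd.pairwise_distances(degs, "jaccard")
        keys = [nd.KeyNodeVector([0, 1]) for _ in range(3)]
        with pytest.raises(ValueError):
            nd.pairwise_distances(keys, "euclidean")

    def test_log_on_non_ks_rejected(self):
        degs = [nd.DegreeVector([1.0, 2.0]) for _ in range(3)]
        with pytest.raises(ValueError):
            nd.pairwise_distances(degs, "euclidean", log=True)
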