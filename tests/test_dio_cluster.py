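"""DIO residuals, cosine dissimilarity, Ward.D2 agglomeration, tree cuts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dioscope.dio_cluster import (
    DIOMatrix,
    compute_dio,
    cosine_distance_matrix,
    cut_tree,
    dio_nonzero_frequency,
    scan_cuts,
    stack_dio,
    ward_d2_cluster,
)
from dioscope.md_features import FeatureMatrix


def _features(values):
    values = np.asarray(values, dtype=float)
    pairs = [(i + 1, i + 2) for i in range(values.shape[0])]
    return FeatureMatrix(pairs, values, (0.0, float(values.shape[1] - 1), 1.0))


class TestComputeDIO:
    def test_perfect_reconstruction_gives_zero(self):
        fm = _features([[1.0, 2.0, 3.0]])
        dio = compute_dio(fm, fm.values.copy())
        np.testing.assert_array_equal(dio.values, 0.0)

    def test_sign_convention_input_minus_output(self):
        fm = _features([[1.0, 2.0, 3.0]])
        dio = compute_dio(fm, np.array([[1.0, 1.0, 3.0]]))
        np.testing.assert_array_equal(dio.values, [[0.0, 1.0, 0.0]])

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        X, Y = rng.normal(size=(6, 9)), rng.normal(size=(6, 9))
        dio = compute_dio(_features(np.abs(X)), Y)
        np.testing.assert_array_equal(dio.values, np.abs(X) - Y)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_dio(_features([[1.0, 2.0]]), np.zeros((1, 3)))


class TestNonzeroFrequency:
    def test_zero_row(self):
        dio = DIOMatrix([(1, 2)], np.zeros((1, 10)))
        assert dio_nonzero_frequency(dio)[0] == 0.0

    def test_half_active_row(self):
        row = np.array([[2e-6] * 5 + [0.0] * 5])
        dio = DIOMatrix([(1, 2)], row)
        assert dio_nonzero_frequency(dio, eps=1e-6)[0] == pytest.approx(0.5)

    def test_fractions_bounded(self):
        rng = np.random.default_rng(1)
        dio = DIOMatrix([(1, 2), (1, 3)], rng.normal(size=(2, 20)))
        f = dio_nonzero_frequency(dio)
        assert np.all((0.0 <= f) & (f <= 1.0))


class TestCosineDistance:
    def test_closed_forms(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0], [0.0, 3.0]])
        D = cosine_distance_matrix(X)
        assert D[0, 1] == pytest.approx(0.0)  # identical direction
        assert D[0, 2] == pytest.approx(2.0)  # opposite
        assert D[0, 3] == pytest.approx(1.0)  # orthogonal
        assert np.all(np.diag(D) == 0.0)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        D = cosine_distance_matrix(rng.normal(size=(15, 8)))
        assert np.all((D >= 0.0) & (D <= 2.0))
        np.testing.assert_allclose(D, D.T)

    def test_zero_norm_row_policy(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        D = cosine_distance_matrix(X)
        assert D[0, 1] == 0.0  # zero rows together
        assert D[0, 2] == 2.0 and D[1, 2] == 2.0  # maximally far from nonzero


def _ward_d2_oracle(D):
    """Greedy agglomeration recomputing the Lance-Williams Ward.D2 update
    from scratch at every step (O(n^3)); independent of scipy."""
    D = D.astype(float).copy()
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        ni, nj = sizes[i], sizes[j]
        merged = clusters[i] | clusters[j]
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dij = h
            d = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            new_dist[k] = d
        del clusters[i], clusters[j], sizes[i], sizes[j]
        dist = {
            key: v for key, v in dist.items() if i not in key and j not in key
        }
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        for k, d in new_dist.items():
            dist[tuple(sorted((k, next_id)))] = d
        merges.append((merged, h))
        next_id += 1
    return merges


def _scipy_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for t, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + t] = merged
        merges.append((merged, h))
    return merges


class TestWardD2:
    def test_two_leaves(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        dend = ward_d2_cluster(D)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.7)

    def test_three_leaf_hand_computation(self):
        # d(a,b)=1, d(a,c)=d(b,c)=2; first merge (a,b) at 1, then with all
        # singleton sizes the Lance-Williams update gives
        # d(ab,c) = sqrt(((1+1)*2^2 + (1+1)*2^2 - 1*1^2) / 3) = sqrt(5)
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        dend = ward_d2_cluster(D)
        heights = [m[2] for m in dend.merges]
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(np.sqrt((2 * 4 + 2 * 4 - 1 * 1) / 3))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(12345)
        for trial in range(120):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 5))
            D = cosine_distance_matrix(X)
            dend = ward_d2_cluster(D)
            got = _scipy_merges(dend.linkage, n)
            expected = _ward_d2_oracle(D)
            for (gm, gh), (em, eh) in zip(got, expected):
                assert gm == em, f"trial {trial}: merge sets differ"
                assert gh == pytest.approx(eh, abs=1e-10)

    def test_non_symmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ward_d2_cluster(D)

    def test_merge_count(self):
        rng = np.random.default_rng(3)
        D = cosine_distance_matrix(rng.normal(size=(10, 4)))
        assert len(ward_d2_cluster(D).merges) == 9


class TestCutTree:
    @pytest.fixture(scope="class")
    def dend(self):
        rng = np.random.default_rng(4)
        return ward_d2_cluster(cosine_distance_matrix(rng.normal(size=(12, 6))))

    def test_k_one_single_cluster(self, dend):
        assert len(set(cut_tree(dend, 1))) == 1

    def test_k_n_all_singletons(self, dend):
        labels = cut_tree(dend, 12)
        assert len(set(labels)) == 12

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_exactly_k_clusters(self, dend, k):
        assert len(set(cut_tree(dend, k))) == k

    def test_nestedness(self, dend):
        """Clusters at k are unions of clusters at k+1."""
        for k in range(2, 11):
            coarse = cut_tree(dend, k)
            fine = cut_tree(dend, k + 1)
            for c in set(fine):
                parents = set(coarse[fine == c])
                assert len(parents) == 1

    def test_out_of_range(self, dend):
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 13)


class TestScanCuts:
    def test_default_range_yields_8_results(self):
        rng = np.random.default_rng(5)
        dend = ward_d2_cluster(cosine_distance_matrix(rng.normal(size=(20, 6))))
        out = scan_cuts(dend)
        assert sorted(out) == list(range(2, 10))

    def test_single_k(self):
        rng = np.random.default_rng(6)
        dend = ward_d2_cluster(cosine_distance_matrix(rng.normal(size=(6, 4))))
        assert list(scan_cuts(dend, (2, 2))) == [2]

    def test_composition_counts_sources(self):
        apo = DIOMatrix([(1, 2), (1, 3)], np.zeros((2, 4)), source="apo")
        holo = DIOMatrix([(1, 2), (1, 3)], np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]), source="holo")
        rows, leaves = stack_dio(apo, holo)
        dend = ward_d2_cluster(cosine_distance_matrix(rows), leaves=leaves)
        out = scan_cuts(dend, (2, 3))
        comp = out[2]["composition"]
        assert comp["n_pairs"].sum() == 4
        assert set(comp["source"]) == {"apo", "holo"}
        # the two zero-DIO apo rows sit together, away from the holo rows
        labels = out[2]["labels"]
        assert labels[0] == labels[1] and labels[0] != labels[2]
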