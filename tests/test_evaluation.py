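"""Metric suite checked against hand arithmetic and brute-force oracles."""

from itertools import permutations

import numpy as np
import pytest
import scipy.sparse as sp

from atacdae import PeakMatrix
from atacdae.evaluation import (cluster_and_score, hungarian_confusion,
                                library_size_table, meta_cell_distance,
                                per_cell_mse, zero_separation)
from atacdae.preprocess import CorruptionRecord


# ------------------------------------------------------------ per-cell MSE
def test_per_cell_mse_identity_is_zero():
    X = np.random.default_rng(0).random((5, 4))
    assert np.allclose(per_cell_mse(X, X), 0.0)


def test_per_cell_mse_hand_value():
    """Truth (0,2) vs imputed (1,1): (1 + 1)/2 = 1.0 for that cell."""
    truth = np.array([[0.0], [2.0]])
    imputed = np.array([[1.0], [1.0]])
    assert np.allclose(per_cell_mse(truth, imputed), [1.0])


def test_per_cell_mse_nonnegative_and_shape_checked():
    rng = np.random.default_rng(1)
    assert per_cell_mse(rng.random((6, 3)), rng.random((6, 3))).min() >= 0
    with pytest.raises(ValueError):
        per_cell_mse(np.zeros((2, 2)), np.zeros((3, 2)))


# ------------------------------------------------------- meta-cell distance
def test_meta_cell_distance_zero_for_exact_meta():
    truth = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    labels = np.array([0, 0])
    # both imputed cells equal the meta-cell (1,2,3)
    assert np.allclose(meta_cell_distance(truth, truth, labels), 0.0)


def test_meta_cell_distance_affine_invariance():
    truth = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 2))
    imputed = 2 * truth + 5
    assert np.allclose(meta_cell_distance(imputed, truth, np.array([0, 0])), 0.0)


def test_meta_cell_distance_anticorrelated_is_two():
    """Cell (3,2,1) against meta (1,2,3): 1 - (-1) = 2."""
    truth = np.array([[1.0], [2.0], [3.0]])
    imputed = np.array([[3.0], [2.0], [1.0]])
    assert np.allclose(meta_cell_distance(imputed, truth, np.array([0])), [2.0])


def test_meta_cell_distance_constant_vector_flagged_as_one():
    truth = np.array([[1.0], [2.0]])
    imputed = np.array([[5.0], [5.0]])
    assert np.allclose(meta_cell_distance(imputed, truth, np.array([0])), [1.0])


# ----------------------------------------------------------------- ARI etc.
def _ari_pair_counting(labels, clusters):
    """Independent brute-force ARI via pair counting over all cell pairs."""
    n = len(labels)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_l = labels[i] == labels[j]
            same_c = clusters[i] == clusters[j]
            ss += same_l and same_c
            sd += same_l and not same_c
            ds += (not same_l) and same_c
            dd += (not same_l) and not same_c
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


@pytest.mark.parametrize("labels,clusters", [
    ([0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2]),
    ([0, 0, 1, 1, 2, 2], [0, 0, 0, 1, 1, 1]),
    ([0, 1, 0, 1, 0, 1], [0, 0, 1, 1, 2, 2]),
    ([0, 0, 0, 1, 1, 1], [1, 1, 0, 0, 2, 2]),
])
def test_ari_matches_pair_counting_oracle(labels, clusters):
    from sklearn.metrics import adjusted_rand_score
    assert np.isclose(adjusted_rand_score(labels, clusters),
                      _ari_pair_counting(labels, clusters), atol=1e-12)


def test_cluster_and_score_perfect_separation():
    """Two widely separated blobs: every index is 1 (up to cluster
    relabeling, which the indices are invariant to)."""
    rng = np.random.default_rng(2)
    a = rng.normal(0, 0.05, size=(30, 20))
    b = rng.normal(5, 0.05, size=(30, 20))
    X = np.vstack([a, b]).T  # peaks x cells
    labels = np.repeat([0, 1], 30)
    ari, nmi, ami, sc = cluster_and_score(X, labels, seed=0)
    assert ari == pytest.approx(1.0)
    assert nmi == pytest.approx(1.0)
    assert ami == pytest.approx(1.0)
    assert 0.9 <= sc <= 1.0


def test_cluster_index_permutation_invariance():
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0


def test_cluster_and_score_k_too_large():
    with pytest.raises(ValueError):
        cluster_and_score(np.zeros((5, 3)), np.array([0, 1, 0]), k=4)


# ---------------------------------------------------------------- Hungarian
def test_hungarian_identity_partitions():
    labels = np.array([0, 0, 1, 1, 2])
    conf, assign = hungarian_confusion(labels, labels)
    assert np.trace(conf) == 5
    assert np.array_equal(assign, [0, 1, 2])


def test_hungarian_matches_brute_force_enumeration():
    """On a 3x3 contingency [[5,1,0],[0,4,2],[1,0,6]] the matched diagonal
    equals the maximum over all 3! permutations (15)."""
    cont = np.array([[5, 1, 0], [0, 4, 2], [1, 0, 6]])
    labels, clusters = [], []
    for i in range(3):
        for j in range(3):
            labels += [i] * cont[i, j]
            clusters += [j] * cont[i, j]
    conf, assign = hungarian_confusion(np.array(labels), np.array(clusters))
    best = max(sum(cont[i, p[i]] for i in range(3))
               for p in permutations(range(3)))
    assert best == 15
    assert np.trace(conf) == best


def test_hungarian_diagonal_dominates_all_permutations():
    rng = np.random.default_rng(3)
    for _ in range(5):
        labels = rng.integers(0, 4, size=40)
        clusters = rng.integers(0, 4, size=40)
        conf, assign = hungarian_confusion(labels, clusters)
        cont = np.zeros((4, 4), dtype=int)
        np.add.at(cont, (labels, clusters), 1)
        best = max(sum(cont[i, p[i]] for i in range(4))
                   for p in permutations(range(4)))
        assert np.trace(conf) == best


def test_hungarian_relabeled_partition_full_diagonal():
    labels = np.array([0, 0, 1, 1, 2, 2])
    relabeled = np.array([2, 2, 0, 0, 1, 1])
    conf, _ = hungarian_confusion(labels, relabeled)
    assert np.trace(conf) == 6


def test_hungarian_length_mismatch():
    with pytest.raises(ValueError):
        hungarian_confusion(np.array([0, 1]), np.array([0]))


# ------------------------------------------------------------- library size
def test_library_size_identity_and_scale_invariance():
    X = np.random.default_rng(4).integers(0, 3, size=(10, 6)).astype(float)
    ts, ps, corr = library_size_table(X, X)
    assert corr == pytest.approx(1.0)
    _, _, corr2 = library_size_table(X, 2 * X)
    assert corr2 == pytest.approx(1.0)


def test_library_size_hand_sums():
    X = np.array([[1.0, 2.0], [3.0, 4.0]])
    ts, ps, _ = library_size_table(X, X)
    assert ts.tolist() == [4.0, 6.0]


# ---------------------------------------------------------- zero separation
def _record(truth, rate_masked):
    rows, cols = rate_masked
    return CorruptionRecord(corrupted=None, mask_rows=np.asarray(rows),
                            mask_cols=np.asarray(cols), rate=0.4, seed=0)


def test_zero_separation_perfect_imputation():
    truth = PeakMatrix(X=sp.csr_matrix(np.array([[1, 0], [2, 1], [0, 0], [1, 0]])))
    record = _record(truth, ([0, 1], [0, 0]))
    recov, reten = zero_separation(truth, record, truth.X.toarray())
    assert recov == 100.0 and reten == 100.0


def test_zero_separation_no_imputation():
    truth = PeakMatrix(X=sp.csr_matrix(np.array([[1, 0], [2, 1], [0, 0], [1, 0]])))
    record = _record(truth, ([0, 1], [0, 0]))
    corrupted = truth.X.toarray()
    corrupted[[0, 1], [0, 0]] = 0
    recov, reten = zero_separation(truth, record, corrupted)
    assert recov == 0.0 and reten == 100.0


def test_zero_separation_enumerated_toy():
    """4x2 toy, 2 masked and 4 biological zeros, thresholded by hand:
    one of two dropout zeros recovered (50%), three of four biological
    zeros retained (75%)."""
    truth = sp.csr_matrix(np.array([[1, 0], [2, 1], [0, 0], [1, 0]]))
    truth_pm = PeakMatrix(X=truth)
    record = _record(truth_pm, ([0, 1], [0, 0]))
    # bio zeros at (0,1), (2,0), (2,1), (3,1); only (2,1) -> 0.9 flips
    imputed = np.array([[0.8, 0.1],    # masked, recovered (0.8 >= 0.5)
                        [0.2, 1.0],    # masked, not recovered
                        [0.0, 0.9],
                        [1.0, 0.3]])
    recov, reten = zero_separation(truth_pm, record, imputed)
    assert recov == pytest.approx(50.0)
    assert reten == pytest.approx(75.0)
    # recovered + unrecovered partitions the dropout zeros exactly
    assert recov + 50.0 == 100.0


def test_zero_separation_mask_inconsistent_with_truth():
    truth = PeakMatrix(X=sp.csr_matrix(np.array([[1, 0], [0, 1]])))
    record = _record(truth, ([1], [0]))  # truth[1,0] == 0: not maskable
    with pytest.raises(ValueError):
        zero_separation(truth, record, truth.X.toarray())
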