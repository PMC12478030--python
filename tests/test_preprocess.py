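"""Normalization, its inverse, outlier capping, and the masking operator."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from atacdae import (PeakMatrix, cap_outliers, denormalize, mask_corrupt,
                     normalize)


def _pm(array):
    return PeakMatrix(X=sp.csr_matrix(np.asarray(array)))


# -------------------------------------------------------------- normalize
def test_normalize_hand_example():
    """Row [1, 3, 0]: log2 -> [1, 2, 0], per-peak max 2 -> [0.5, 1, 0]."""
    norm = normalize(_pm([[1, 3, 0]]))
    assert np.allclose(norm.values.toarray(), [[0.5, 1.0, 0.0]])
    assert np.allclose(norm.peak_denominators, [2.0])


def test_normalize_all_zero_peak():
    norm = normalize(_pm([[0, 0], [1, 2]]))
    assert norm.values[0].nnz == 0
    assert norm.peak_denominators[0] == 0.0


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_normalize_range_and_argmax_attains_one(seed):
    """Values are in [0, 1] and every peak with signal attains exactly 1."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 6, size=(20, 10))
    norm = normalize(_pm(X))
    dense = norm.values.toarray()
    assert dense.min() >= 0.0 and dense.max() <= 1.0
    for i in range(20):
        if norm.peak_denominators[i] > 0:
            assert np.isclose(dense[i].max(), 1.0)
        else:
            assert not dense[i].any()


def test_denormalize_hand_values():
    assert np.isclose(denormalize(np.array([[1.0]]), np.array([2.0]))[0, 0], 3.0)
    assert denormalize(np.array([[0.0]]), np.array([5.0]))[0, 0] == 0.0


def test_denormalize_inverts_normalize_exactly():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 10, size=(100, 50))
    norm = normalize(_pm(X))
    assert np.abs(denormalize(norm) - X).max() < 1e-9


def test_denormalize_requires_denominators():
    with pytest.raises(ValueError):
        denormalize(np.zeros((2, 2)))


# ------------------------------------------------------------ cap_outliers
def test_cap_outliers_hand_percentile():
    """Nonzeros {1,1,1,1000} at the 75th percentile cap 1000 down to 1."""
    capped = cap_outliers(_pm([[1, 1, 1, 1000]]), percentile=75)
    assert capped.X.toarray().tolist() == [[1, 1, 1, 1]]


def test_cap_outliers_identity_below_threshold():
    pm = _pm([[1, 2], [2, 1]])
    assert (cap_outliers(pm, 99.9).X != pm.X).nnz == 0


def test_cap_outliers_idempotent():
    pm = _pm([[1, 1, 5, 100, 1000]])
    once = cap_outliers(pm, 80)
    twice = cap_outliers(once, 80)
    assert (once.X != twice.X).nnz == 0


def test_cap_outliers_invalid_inputs():
    with pytest.raises(ValueError):
        cap_outliers(_pm([[1]]), percentile=0)
    with pytest.raises(ValueError):
        cap_outliers(PeakMatrix(X=sp.csr_matrix((2, 2), dtype=np.int64)))


# ------------------------------------------------------------ mask_corrupt
def test_mask_rate_zero_is_identity(small_sim):
    norm = normalize(PeakMatrix(X=small_sim.matrix))
    record = mask_corrupt(norm, 0.0, seed=1)
    assert record.n_masked == 0
    assert (record.corrupted.values != norm.values).nnz == 0


def test_mask_exact_count_per_cell():
    """A cell with 10 nonzeros at rate 0.4 loses exactly round(0.4*10) = 4."""
    X = np.zeros((20, 3), dtype=np.int64)
    X[:10, 0] = 1
    X[:7, 1] = 1
    X[:1, 2] = 1
    record = mask_corrupt(_pm(X), 0.4, seed=0)
    masked_per_cell = np.bincount(record.mask_cols, minlength=3)
    assert masked_per_cell.tolist() == [4, 3, 0]  # round(.4*10), round(.4*7), round(.4*1)


def test_mask_partition_identity(small_sim):
    """Corrupted matrix plus masked entries reconstructs the source exactly,
    and no masked position was zero."""
    pm = PeakMatrix(X=small_sim.matrix)
    record = mask_corrupt(pm, 0.4, seed=3)
    source = pm.X.toarray()
    corrupted = record.corrupted.X.toarray()
    assert np.all(corrupted[record.mask_rows, record.mask_cols] == 0)
    assert np.all(source[record.mask_rows, record.mask_cols] > 0)
    restored = corrupted.copy()
    restored[record.mask_rows, record.mask_cols] = \
        source[record.mask_rows, record.mask_cols]
    assert np.array_equal(restored, source)


def test_mask_rate_out_of_range(small_sim):
    with pytest.raises(ValueError):
        mask_corrupt(PeakMatrix(X=small_sim.matrix), 1.0, seed=0)
    with pytest.raises(ValueError):
        mask_corrupt(PeakMatrix(X=small_sim.matrix), -0.1, seed=0)


def test_mask_deterministic(small_sim):
    pm = PeakMatrix(X=small_sim.matrix)
    a = mask_corrupt(pm, 0.3, seed=9)
    b = mask_corrupt(pm, 0.3, seed=9)
    assert np.array_equal(a.mask_rows, b.mask_rows)
    assert np.array_equal(a.mask_cols, b.mask_cols)
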