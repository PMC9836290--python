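import numpy as np
import pytest
from hypothesis import given, strategies as st

from tnscreen import InsertionProfile, quantile_normalize, quantile_normalize_matrix

from _oracles import quantile_normalize_oracle


def _normalize_cols(columns):
    """Run the pipeline on per-sample column lists, return same shape."""
    X = np.array(columns, dtype=float).T  # (positions, samples)
    return quantile_normalize_matrix(X).T.tolist()


def test_rank_mean_example_two_samples():
    # A=(5,2,3), B=(4,1,2): rank means are (1.5, 2.5, 4.5)
    got = _normalize_cols([[5, 2, 3], [4, 1, 2]])
    assert got[0] == pytest.approx([4.5, 1.5, 2.5])
    assert got[1] == pytest.approx([4.5, 1.5, 2.5])


def test_tied_values_get_mean_of_spanned_rank_means():
    # A=(2,2,4), B=(1,3,5): A's tied 2s share mean(1.5, 2.5) = 2.0
    got = _normalize_cols([[2, 2, 4], [1, 3, 5]])
    assert got[0] == pytest.approx([2.0, 2.0, 4.5])
    assert got[1] == pytest.approx([1.5, 2.5, 4.5])


def test_single_sample_is_unchanged():
    got = _normalize_cols([[7, 0, 3, 3]])
    assert got[0] == pytest.approx([7, 0, 3, 3])


def test_identical_samples_are_unchanged():
    col = [5.0, 1.0, 9.0, 5.0]
    got = _normalize_cols([col, col, col])
    for g in got:
        assert g == pytest.approx(col)


@given(
    st.integers(2, 6),
    st.integers(1, 60),
    st.integers(0, 2**31 - 1),
)
def test_matches_brute_force_oracle(n_samples, n_obs, seed):
    rng = np.random.default_rng(seed)
    # small value range to force plenty of ties and zeros
    X = rng.integers(0, 8, size=(n_obs, n_samples)).astype(float)
    got = quantile_normalize_matrix(X)
    expected = np.array(quantile_normalize_oracle(X.T.tolist())).T
    np.testing.assert_allclose(got, expected, atol=1e-9)


@given(st.integers(2, 8), st.integers(2, 100), st.integers(0, 2**31 - 1))
def test_sorted_vectors_identical_across_tie_free_samples(n_samples, n_obs, seed):
    rng = np.random.default_rng(seed)
    # tie-free columns: with ties, tie-averaging redistributes within a
    # column, so only the column sums stay equal (checked below)
    X = np.column_stack(
        [rng.permutation(n_obs * 10)[:n_obs] for _ in range(n_samples)]
    ).astype(float)
    out = quantile_normalize_matrix(X)
    ref = np.sort(out[:, 0])
    for j in range(1, n_samples):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)


@given(st.integers(2, 8), st.integers(2, 100), st.integers(0, 2**31 - 1))
def test_sums_identical_across_samples_even_with_ties(n_samples, n_obs, seed):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 6, size=(n_obs, n_samples)).astype(float)
    out = quantile_normalize_matrix(X)
    np.testing.assert_allclose(out.sum(axis=0), out.sum(axis=0)[0], rtol=1e-12, atol=1e-9)


@given(st.integers(2, 6), st.integers(2, 50), st.integers(0, 2**31 - 1))
def test_within_sample_rank_order_preserved(n_samples, n_obs, seed):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 50, size=(n_obs, n_samples)).astype(float)
    out = quantile_normalize_matrix(X)
    for j in range(n_samples):
        order = np.argsort(X[:, j], kind="stable")
        assert np.all(np.diff(out[order, j]) >= -1e-12)


def test_profile_normalization_keeps_own_keys_and_fills_union_zeros():
    a = InsertionProfile("A", {("chr1", 10): 5, ("chr1", 20): 2, ("chr1", 30): 3})
    b = InsertionProfile("B", {("chr1", 10): 4, ("chr1", 40): 9})
    na, nb = quantile_normalize([a, b])
    assert set(na.counts) == set(a.counts)
    assert set(nb.counts) == set(b.counts)
    # oracle over the union (10, 20, 30, 40) with zero fill
    expected = quantile_normalize_oracle([[5, 2, 3, 0], [4, 0, 0, 9]])
    assert na.counts[("chr1", 10)] == pytest.approx(expected[0][0])
    assert na.counts[("chr1", 20)] == pytest.approx(expected[0][1])
    assert na.counts[("chr1", 30)] == pytest.approx(expected[0][2])
    assert nb.counts[("chr1", 10)] == pytest.approx(expected[1][0])
    assert nb.counts[("chr1", 40)] == pytest.approx(expected[1][3])


def test_profile_normalization_requires_input():
    with pytest.raises(ValueError):
        quantile_normalize([])
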