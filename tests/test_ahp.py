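"""AHP weight derivation and consistency diagnostics.

The published comparison matrices are not available, so the engine is
validated by construction: consistent matrices built from known weight
vectors must round-trip, and perturbed reciprocal matrices are checked
against a dense eigendecomposition oracle.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquarisk import (
    MatrixError,
    PairwiseComparisonMatrix,
    consistency_index,
    consistency_ratio,
    consistency_report,
    consistent_matrix,
    derive_weights,
    lambda_max,
)


def dense_eig_oracle(a):
    """Independent reference: dominant eigenpair via full eigendecomposition."""
    vals, vecs = np.linalg.eig(a)
    k = np.argmax(vals.real)
    lam = vals[k].real
    v = np.abs(vecs[:, k].real)
    return lam, v / v.sum()


def make_perturbed(rng, n, perturb=0.3):
    """Reciprocal matrix: ratio matrix with multiplicative noise on the
    upper triangle, reciprocals mirrored below."""
    w = rng.uniform(0.1, 1.0, size=n)
    a = np.outer(w, 1.0 / w)
    for i in range(n):
        for j in range(i + 1, n):
            f = np.exp(rng.uniform(-perturb, perturb))
            a[i, j] *= f
            a[j, i] = 1.0 / a[i, j]
    return a


class TestMatrixValidation:
    def test_rejects_non_square(self):
        with pytest.raises(MatrixError, match="square"):
            PairwiseComparisonMatrix([[1.0, 2.0, 3.0], [0.5, 1.0, 1.0]])

    def test_rejects_non_positive(self):
        with pytest.raises(MatrixError):
            PairwiseComparisonMatrix([[1.0, -2.0], [-0.5, 1.0]])

    def test_rejects_broken_reciprocity(self):
        with pytest.raises(MatrixError, match="reciprocal"):
            PairwiseComparisonMatrix([[1.0, 2.0], [0.4, 1.0]])

    def test_symmetrize_repairs_reciprocity(self):
        m = PairwiseComparisonMatrix([[1.0, 2.0], [0.4, 1.0]], symmetrize=True)
        assert m.values[0, 1] == pytest.approx(np.sqrt(2.0 / 0.4))

    def test_off_saaty_scale_warns_but_passes(self):
        with pytest.warns(UserWarning, match="Saaty"):
            PairwiseComparisonMatrix([[1.0, 2.7], [1 / 2.7, 1.0]])

    def test_saaty_scale_entries_do_not_warn(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            PairwiseComparisonMatrix([[1, 3, 7], [1 / 3, 1, 5], [1 / 7, 1 / 5, 1]])


class TestDeriveWeights:
    def test_all_ones_matrix_gives_uniform_weights(self):
        wv = derive_weights(PairwiseComparisonMatrix(np.ones((3, 3))))
        assert wv.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-12)

    def test_consistent_3x3_matches_normalised_column(self):
        m = PairwiseComparisonMatrix([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        wv = derive_weights(m)
        assert wv.weights == pytest.approx((4 / 7, 2 / 7, 1 / 7), abs=1e-10)

    def test_recovers_published_weight_vector(self):
        """A consistent matrix built from the published four-way weight
        vector (0.2488, 0.5502, 0.0826, 0.1184) returns it exactly."""
        w = (0.2488, 0.5502, 0.0826, 0.1184)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wv = derive_weights(consistent_matrix(w))
        assert wv.as_array() == pytest.approx(np.array(w), abs=1e-6)

    def test_weights_sum_to_one_and_positive(self):
        rng = np.random.default_rng(7)
        for n in range(2, 10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wv = derive_weights(PairwiseComparisonMatrix(make_perturbed(rng, n)))
            w = wv.as_array()
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w > 0)


class TestLambdaMax:
    def test_consistent_matrix_lambda_equals_order(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = consistent_matrix([0.4, 0.3, 0.2, 0.1])
        assert lambda_max(m) == pytest.approx(4.0, abs=1e-9)

    def test_1x1_matrix(self):
        assert lambda_max(PairwiseComparisonMatrix([[1.0]])) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        a = np.array([[1, 2, 0.5], [0.5, 1, 4], [2, 0.25, 1]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = PairwiseComparisonMatrix(a)
        lam_ref, _ = dense_eig_oracle(a)
        assert lambda_max(m) == pytest.approx(lam_ref, abs=1e-9)


class TestConsistencyArithmetic:
    @pytest.mark.parametrize("lam, n, ci", [
        (3.0, 3, 0.0),
        (3.10, 3, 0.05),
        (4.27, 4, 0.09),
        (1.0, 1, 0.0),
    ])
    def test_consistency_index_formula(self, lam, n, ci):
        assert consistency_index(lam, n) == pytest.approx(ci, abs=1e-12)

    def test_consistency_index_rejects_bad_order(self):
        with pytest.raises(ValueError):
            consistency_index(1.0, 0)

    def test_cr_with_standard_ri_table(self):
        ri, cr, ok = consistency_ratio(0.029, 3)
        assert ri == 0.58
        assert cr == pytest.approx(0.05, abs=1e-12)
        assert ok

    def test_cr_above_threshold_is_inconsistent(self):
        ri, cr, ok = consistency_ratio(0.15, 4)
        assert ri == 0.90
        assert cr == pytest.approx(0.15 / 0.90, abs=1e-12)
        assert not ok

    def test_zero_ci_is_consistent_for_any_order(self):
        for n in range(1, 10):
            _, cr, ok = consistency_ratio(0.0, n)
            assert cr == 0.0 and ok

    def test_small_orders_consistent_iff_ci_zero(self):
        _, cr, ok = consistency_ratio(0.0, 2)
        assert cr == 0.0 and ok
        _, _, ok2 = consistency_ratio(0.01, 2)
        assert not ok2

    def test_order_outside_ri_table_instructs_user(self):
        with pytest.raises(MatrixError, match="RI table"):
            consistency_ratio(0.05, 12)

    def test_custom_ri_table_override(self):
        ri, cr, ok = consistency_ratio(0.05, 12, ri_table={12: 1.54})
        assert ri == 1.54 and cr == pytest.approx(0.05 / 1.54)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=9), st.integers(min_value=0, max_value=2**31 - 1))
def test_consistent_matrix_round_trip(n, seed):
    """For any positive weight vector, the ratio matrix w_i/w_j returns the
    vector, lambda_max = n, CI = 0 and CR = 0."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.05, 1.0, size=n)
    w /= w.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = consistent_matrix(w)
        rep = consistency_report(m)
        wv = derive_weights(m)
    assert wv.as_array() == pytest.approx(w, abs=1e-8)
    assert rep.lambda_max == pytest.approx(n, abs=1e-8)
    assert rep.ci == pytest.approx(0.0, abs=1e-8)
    assert rep.cr == pytest.approx(0.0, abs=1e-8)
    assert rep.consistent


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=9), st.integers(min_value=0, max_value=2**31 - 1))
def test_perturbed_matrix_matches_dense_oracle(n, seed):
    """lambda_max >= n and eigenvector weights agree with a full
    eigendecomposition on noisy reciprocal matrices."""
    rng = np.random.default_rng(seed)
    a = make_perturbed(rng, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = PairwiseComparisonMatrix(a)
        lam = lambda_max(m)
        wv = derive_weights(m)
    lam_ref, w_ref = dense_eig_oracle(a)
    assert lam >= n - 1e-9
    assert lam == pytest.approx(lam_ref, abs=1e-8)
    assert wv.as_array() == pytest.approx(w_ref, abs=1e-8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=7),
       st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.1, max_value=100.0))
def test_scale_invariance(n, seed, scale):
    """Multiplying the weight vector by a constant leaves the derived
    weights unchanged (the ratio matrix is identical)."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.05, 1.0, size=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w1 = derive_weights(consistent_matrix(w)).as_array()
        w2 = derive_weights(consistent_matrix(w * scale)).as_array()
    assert w1 == pytest.approx(w2, abs=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=7), st.integers(min_value=0, max_value=2**31 - 1))
def test_permutation_equivariance(n, seed):
    """Permuting rows/columns of the matrix permutes the weights identically."""
    rng = np.random.default_rng(seed)
    a = make_perturbed(rng, n)
    perm = rng.permutation(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = derive_weights(PairwiseComparisonMatrix(a)).as_array()
        wp = derive_weights(PairwiseComparisonMatrix(a[np.ix_(perm, perm)])).as_array()
    assert wp == pytest.approx(w[perm], abs=1e-9)


def test_matrix_file_round_trip(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("a,b,c\n1,3,5\n0.3333333333333333,1,3\n0.2,0.3333333333333333,1\n")
    m = PairwiseComparisonMatrix.from_file(path)
    assert m.ids == ["a", "b", "c"]
    assert m.n == 3
    rep = consistency_report(m)
    assert rep.consistent
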