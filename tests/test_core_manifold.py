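import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from slle_sc2.core_manifold import (
    CostMatrix,
    DistanceMatrix,
    WeightMatrix,
    embed,
    embedding_cost_matrix,
    euclidean_distance_matrix,
    knn_neighbors,
    lle,
    reconstruction_weights,
    slle,
    supervised_distance_matrix,
)
from slle_sc2.errors import DataValidationError, NumericalError, ParameterError

from conftest import make_matrix, random_two_class


# ---------------------------------------------------------------- distances
class TestEuclideanDistance:
    def test_three_four_five(self):
        x = make_matrix([[0.0, 0.0], [3.0, 4.0]])
        d = euclidean_distance_matrix(x)
        assert d.d[0, 1] == pytest.approx(5.0)
        assert d.kind == "euclidean"

    def test_duplicate_rows_zero(self):
        x = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        d = euclidean_distance_matrix(x)
        assert d.d[0, 1] == 0.0

    def test_matches_bruteforce(self, rng):
        vals = rng.normal(size=(3, 10))
        x = make_matrix(vals)
        d = euclidean_distance_matrix(x).d
        for i in range(3):
            for j in range(3):
                expected = np.sqrt(np.sum((vals[i] - vals[j]) ** 2))
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal(self, rng):
        x = make_matrix(rng.normal(size=(7, 4)))
        d = euclidean_distance_matrix(x).d
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)

    def test_rejects_single_sample(self):
        with pytest.raises(DataValidationError):
            euclidean_distance_matrix(make_matrix([[1.0, 2.0]]))


class TestSupervisedDistance:
    def test_lambda_zero_identity(self, two_class):
        d = euclidean_distance_matrix(two_class)
        sup = supervised_distance_matrix(d, two_class.labels, 0.0)
        assert np.array_equal(sup.d, d.d)

    def test_direct_substitution(self):
        # entries 2 and max 10: different classes -> 12, same classes -> 2
        d = DistanceMatrix(
            d=np.array([[0.0, 2.0, 10.0], [2.0, 0.0, 2.0], [10.0, 2.0, 0.0]])
        )
        labels = np.array(["a", "b", "a"])
        sup = supervised_distance_matrix(d, labels, 1.0)
        assert sup.d[0, 1] == pytest.approx(12.0)  # different classes
        assert sup.d[0, 2] == pytest.approx(10.0)  # same class, untouched
        assert sup.d[1, 2] == pytest.approx(12.0)
        assert sup.kind == "supervised"
        assert sup.lambda_s == 1.0

    def test_entrywise_oracle(self, rng):
        x = random_two_class(rng, n_per_class=3, n_genes=4)
        d = euclidean_distance_matrix(x)
        sup = supervised_distance_matrix(d, x.labels, 0.5)
        mx = d.d.max()
        for i in range(6):
            for j in range(6):
                extra = 0.5 * mx if x.labels[i] != x.labels[j] else 0.0
                assert sup.d[i, j] == pytest.approx(d.d[i, j] + extra, abs=1e-12)

    def test_dominates_euclidean(self, two_class):
        d = euclidean_distance_matrix(two_class)
        sup = supervised_distance_matrix(d, two_class.labels, 0.7)
        assert np.all(sup.d >= d.d - 1e-12)
        same = two_class.labels[:, None] == two_class.labels[None, :]
        assert np.array_equal(sup.d[same], d.d[same])

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_lambda_out_of_range(self, two_class, bad):
        d = euclidean_distance_matrix(two_class)
        with pytest.raises(ParameterError):
            supervised_distance_matrix(d, two_class.labels, bad)


# ---------------------------------------------------------------- neighbors
class TestKnnNeighbors:
    def test_collinear_points(self):
        x = make_matrix([[0.0], [1.0], [10.0]])
        g = knn_neighbors(euclidean_distance_matrix(x), k=1)
        assert g.neighbors[1, 0] == 0  # middle point's nearest is the origin

    def test_complete_graph(self, rng):
        x = make_matrix(rng.normal(size=(6, 3)))
        g = knn_neighbors(euclidean_distance_matrix(x), k=5)
        for i in range(6):
            assert sorted(g.neighbors[i]) == sorted(set(range(6)) - {i})

    def test_argsort_oracle(self, rng):
        x = make_matrix(rng.normal(size=(8, 4)))
        d = euclidean_distance_matrix(x)
        g = knn_neighbors(d, k=3)
        for i in range(8):
            row = d.d[i].copy()
            row[i] = np.inf
            expected = np.argsort(row, kind="stable")[:3]
            assert list(g.neighbors[i]) == list(expected)

    def test_self_excluded_and_length(self, rng):
        x = make_matrix(rng.normal(size=(9, 2)))
        g = knn_neighbors(euclidean_distance_matrix(x), k=4)
        for i in range(9):
            assert i not in g.neighbors[i]
            assert len(g.neighbors[i]) == 4

    def test_tie_break_by_index(self):
        # three equidistant neighbors of the origin
        x = make_matrix([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        g = knn_neighbors(euclidean_distance_matrix(x), k=2)
        assert list(g.neighbors[0]) == [1, 2]

    def test_k_too_large(self, rng):
        x = make_matrix(rng.normal(size=(5, 2)))
        with pytest.raises(ParameterError):
            knn_neighbors(euclidean_distance_matrix(x), k=5)


# ------------------------------------------------------------------ weights
def constrained_ls_weights(xi, neighbors):
    """Independent oracle: minimize ||xi - sum w_j x_j|| s.t. sum w = 1,
    by eliminating the constraint and solving an unconstrained least squares."""
    k = neighbors.shape[0]
    base = neighbors[-1]
    a = (neighbors[:-1] - base).T  # (D, k-1)
    b = xi - base
    w_head, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.append(w_head, 1.0 - w_head.sum()) if k > 1 else np.array([1.0])


class TestReconstructionWeights:
    def test_hand_example(self):
        x = make_matrix([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        g = knn_neighbors(euclidean_distance_matrix(x), k=2)
        w = reconstruction_weights(x, g, reg_tol=0.0)
        assert w.w[0, 1] == pytest.approx(0.5)
        assert w.w[0, 2] == pytest.approx(0.5)
        assert w.recon_error[0] == pytest.approx(0.5)

    def test_singular_gram_regularized_symmetric(self):
        x = make_matrix([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        g = knn_neighbors(euclidean_distance_matrix(x), k=2)
        with pytest.raises(NumericalError):
            reconstruction_weights(x, g, reg_tol=0.0)
        w = reconstruction_weights(x, g, reg_tol=1e-6)
        assert w.w[0, 1] == pytest.approx(0.5, abs=1e-9)
        assert w.w[0, 2] == pytest.approx(0.5, abs=1e-9)

    def test_constrained_ls_oracle(self, rng):
        vals = rng.normal(size=(10, 2))
        x = make_matrix(vals)
        g = knn_neighbors(euclidean_distance_matrix(x), k=2)
        w = reconstruction_weights(x, g, reg_tol=0.0)
        for i in range(10):
            expected = constrained_ls_weights(vals[i], vals[g.neighbors[i]])
            assert np.allclose(w.w[i, g.neighbors[i]], expected, atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        x = make_matrix(rng.normal(size=(12, 5)))
        g = knn_neighbors(euclidean_distance_matrix(x), k=4)
        w = reconstruction_weights(x, g)
        assert np.allclose(w.w.sum(axis=1), 1.0, atol=1e-9)

    def test_support_on_neighbors_only(self, rng):
        x = make_matrix(rng.normal(size=(9, 3)))
        g = knn_neighbors(euclidean_distance_matrix(x), k=3)
        w = reconstruction_weights(x, g)
        for i in range(9):
            off = np.setdiff1d(np.arange(9), np.append(g.neighbors[i], i))
            assert np.all(w.w[i, off] == 0.0)
            assert w.w[i, i] == 0.0


# -------------------------------------------------------------- cost matrix
def cost_matrix_sum_form(w):
    """Element-wise oracle for the quadratic-form cost matrix."""
    n = w.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            m[i, j] = (
                (1.0 if i == j else 0.0)
                - w[i, j]
                - w[j, i]
                + sum(w[k, i] * w[k, j] for k in range(n))
            )
    return m


def random_row_stochastic(rng, n, k):
    """Random sparse row-stochastic matrix with k off-diagonal entries per row."""
    w = np.zeros((n, n))
    for i in range(n):
        cols = rng.choice(np.setdiff1d(np.arange(n), [i]), size=k, replace=False)
        vals = rng.normal(size=k)
        vals = vals / vals.sum() if abs(vals.sum()) > 0.2 else np.full(k, 1.0 / k)
        w[i, cols] = vals
    return w


class TestCostMatrix:
    def _wm(self, w):
        return WeightMatrix(w=w, support=None, reg_tol=0.0)

    def test_zero_weights_identity(self):
        m = embedding_cost_matrix(self._wm(np.zeros((4, 4))))
        assert np.array_equal(m.m, np.eye(4))

    def test_ones_null_vector(self, rng):
        w = random_row_stochastic(rng, 7, 3)
        m = embedding_cost_matrix(self._wm(w))
        assert np.allclose(m.m @ np.ones(7), 0.0, atol=1e-8)

    def test_two_formula_crosscheck(self, rng):
        w = random_row_stochastic(rng, 6, 2)
        m = embedding_cost_matrix(self._wm(w))
        assert np.allclose(m.m, cost_matrix_sum_form(w), atol=1e-12)

    def test_symmetric_psd(self, rng):
        w = random_row_stochastic(rng, 8, 3)
        m = embedding_cost_matrix(self._wm(w)).m
        assert np.allclose(m, m.T, atol=1e-9)
        assert np.linalg.eigvalsh(m).min() >= -1e-8


# ---------------------------------------------------------------- embedding
class TestEmbed:
    def _cost(self, rng, n=12, k=3):
        x = make_matrix(rng.normal(size=(n, 4)))
        g = knn_neighbors(euclidean_distance_matrix(x), k=k)
        return embedding_cost_matrix(reconstruction_weights(x, g))

    def test_dense_eig_oracle(self, rng):
        m = self._cost(rng)
        emb = embed(m, d=3)
        full = np.linalg.eigvalsh(m.m)
        assert np.allclose(np.sort(emb.eigenvalues), full[1:4], atol=1e-8)

    def test_constant_vector_excluded(self, rng):
        emb = embed(self._cost(rng), d=3)
        ones = np.ones(12)
        for c in range(3):
            corr = emb.y[:, c] @ ones / (np.linalg.norm(emb.y[:, c]) * np.linalg.norm(ones))
            assert abs(corr) < 1e-6

    def test_line_manifold_recovery(self, rng):
        from scipy.stats import spearmanr

        t = np.linspace(0.0, 1.0, 20)
        direction = rng.normal(size=5)
        vals = np.outer(t, direction) + rng.normal(scale=1e-4, size=(20, 5))
        x = make_matrix(vals)
        g = knn_neighbors(euclidean_distance_matrix(x), k=2)
        emb = embed(embedding_cost_matrix(reconstruction_weights(x, g)), d=1)
        rho = spearmanr(emb.y[:, 0], t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_centering_and_covariance(self, rng):
        emb = embed(self._cost(rng), d=2)
        assert np.allclose(emb.y.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(emb.y.T @ emb.y / 12, np.eye(2), atol=1e-6)

    def test_sign_deterministic(self, rng):
        emb = embed(self._cost(rng), d=2)
        for c in range(2):
            assert emb.y[np.argmax(np.abs(emb.y[:, c])), c] > 0

    def test_d_too_large(self, rng):
        with pytest.raises(ParameterError):
            embed(self._cost(rng), d=11)


# --------------------------------------------------------------------- slle
class TestSlle:
    def test_lambda_zero_is_plain_lle(self, rng):
        x = random_two_class(rng, n_per_class=8, n_genes=5)
        a = slle(x, k=4, lambda_s=0.0, d=2)
        b = lle(x, k=4, d=2)
        assert np.array_equal(a.y, b.y)

    def test_class_pure_neighborhoods_at_lambda_one(self, rng):
        x = random_two_class(rng, n_per_class=10, n_genes=4, shift=1.0)
        d = euclidean_distance_matrix(x)
        sup = supervised_distance_matrix(d, x.labels, 1.0)
        g = knn_neighbors(sup, k=5)
        for i in range(x.n_samples):
            assert all(x.labels[j] == x.labels[i] for j in g.neighbors[i])

    def test_embedding_invariants_on_synthetic(self, rng):
        x = random_two_class(rng, n_per_class=20, n_genes=6)
        emb = slle(x, k=5, lambda_s=1.0, d=2)
        n = x.n_samples
        assert np.allclose(emb.y.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(emb.y.T @ emb.y / n, np.eye(2), atol=1e-6)

    def test_supervised_weights_option_runs(self, rng):
        x = random_two_class(rng, n_per_class=8, n_genes=5)
        emb = slle(x, k=3, lambda_s=1.0, d=2, supervised_weights=True)
        assert emb.y.shape == (16, 2)


# ----------------------------------------------------------- property tests
@settings(max_examples=25, deadline=None)
@given(
    vals=arrays(
        np.float64,
        (10, 3),
        elements=st.floats(-50, 50, allow_nan=False, width=64),
    ),
    k=st.integers(min_value=1, max_value=5),
)
def test_weight_rows_always_sum_to_one(vals, k):
    x = make_matrix(vals + np.arange(30).reshape(10, 3) * 1e-6)  # break exact dupes
    g = knn_neighbors(euclidean_distance_matrix(x), k=k)
    w = reconstruction_weights(x, g, reg_tol=1e-3)
    assert np.allclose(w.w.sum(axis=1), 1.0, atol=1e-9)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 4))
def test_cost_matrix_properties_random(seed, k):
    rng = np.random.default_rng(seed)
    w = random_row_stochastic(rng, 8, k)
    m = embedding_cost_matrix(WeightMatrix(w=w, support=None, reg_tol=0.0)).m
    assert np.allclose(m, m.T, atol=1e-9)
    assert np.linalg.eigvalsh(m).min() >= -1e-8
    assert np.allclose(m @ np.ones(8), 0.0, atol=1e-8)
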