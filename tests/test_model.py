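"""The GCN-CRF core: adjacency normalization, layers, attention, CRF
updates and losses, training behaviour."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from drivergcn import (
    GCNCRFClassifier,
    attention_coefficients,
    crf_loss,
    crf_update,
    gcn_layer,
    grid_search_cv,
    normalize_adjacency,
    weighted_bce,
)
from drivergcn.autodiff import constant

from conftest import random_symmetric_adjacency


def dense_normalized(A: np.ndarray) -> np.ndarray:
    """Independent dense oracle for the normalized adjacency."""
    a_tilde = A + np.eye(len(A))
    d = a_tilde.sum(axis=1)
    dinv = np.diag(1.0 / np.sqrt(d))
    return dinv @ a_tilde @ dinv


# ---------------------------------------------------------------------------
# normalized adjacency + layer
# ---------------------------------------------------------------------------


def test_isolated_node_normalizes_to_unit_self_loop():
    np.testing.assert_allclose(
        normalize_adjacency(sp.csr_matrix((1, 1))).toarray(), [[1.0]]
    )


def test_two_node_edge_normalization():
    A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    np.testing.assert_allclose(
        normalize_adjacency(A).toarray(), [[0.5, 0.5], [0.5, 0.5]]
    )


def test_path_graph_off_diagonal_value():
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    a_hat = normalize_adjacency(sp.csr_matrix(A)).toarray()
    assert a_hat[0, 1] == pytest.approx(1 / np.sqrt(6), abs=1e-12)


def test_asymmetric_adjacency_rejected():
    A = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
    with pytest.raises(ValueError, match="symmetric"):
        normalize_adjacency(A)


def test_nonzero_diagonal_rejected():
    with pytest.raises(ValueError, match="diagonal"):
        normalize_adjacency(sp.identity(3, format="csr"))


def test_identity_propagation_preserves_input():
    H = np.random.default_rng(0).random((4, 3))
    out = gcn_layer(H, sp.identity(4, format="csr"), np.eye(3), "identity")
    np.testing.assert_allclose(out, H)


def test_zero_input_stays_zero_under_relu():
    out = gcn_layer(np.zeros((5, 3)), sp.identity(5, format="csr"),
                    np.ones((3, 2)), "relu")
    np.testing.assert_array_equal(out, np.zeros((5, 2)))


def test_layer_matches_dense_oracle_on_random_graphs():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(3, 15))
        A = random_symmetric_adjacency(n, 0.4, rng)
        a_hat = normalize_adjacency(A)
        np.testing.assert_allclose(
            a_hat.toarray(), dense_normalized(A.toarray()), atol=1e-12
        )
        H = rng.normal(size=(n, 4))
        W = rng.normal(size=(4, 3))
        expect = np.maximum(dense_normalized(A.toarray()) @ H @ W, 0)
        np.testing.assert_allclose(gcn_layer(H, a_hat, W), expect, atol=1e-6)


def test_spectral_radius_of_normalized_adjacency_at_most_one():
    rng = np.random.default_rng(12)
    for _ in range(5):
        A = random_symmetric_adjacency(int(rng.integers(2, 12)), 0.5, rng)
        vals = np.linalg.eigvalsh(normalize_adjacency(A).toarray())
        assert np.abs(vals).max() <= 1 + 1e-9


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def _star(n_leaves=4):
    A = np.zeros((n_leaves + 1, n_leaves + 1))
    A[0, 1:] = A[1:, 0] = 1.0
    return sp.csr_matrix(A)


def test_single_neighbor_gets_full_attention():
    A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    H = np.array([[1.0, 2.0], [3.0, 4.0]])
    g = attention_coefficients(H, np.eye(2), np.ones(4), A)
    assert g[0, 1] == pytest.approx(1.0)
    assert g[1, 0] == pytest.approx(1.0)


def test_equal_scores_split_attention_evenly():
    A = sp.csr_matrix(
        np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
    )
    H = np.array([[0.5, 0.5], [1.0, 2.0], [1.0, 2.0]])  # identical neighbors
    g = attention_coefficients(H, np.eye(2), np.ones(4), A)
    assert g[0, 1] == pytest.approx(0.5)
    assert g[0, 2] == pytest.approx(0.5)


def test_star_attention_matches_manual_softmax():
    rng = np.random.default_rng(3)
    A = _star()
    H = rng.normal(size=(5, 3))
    Wt = rng.normal(size=(3, 3))
    a = rng.normal(size=6)
    g = attention_coefficients(H, Wt, a, A).toarray()
    # manual: e_ij = leakyrelu(a . [Wt h_i || Wt h_j]), softmax over row
    z = H @ Wt

    def leaky(x):
        return x if x > 0 else 0.2 * x

    for i in range(5):
        nbrs = [j for j in range(5) if A[i, j]]
        e = np.array([leaky(a[:3] @ z[i] + a[3:] @ z[j]) for j in nbrs])
        soft = np.exp(e - e.max())
        soft /= soft.sum()
        np.testing.assert_allclose(g[i, nbrs], soft, atol=1e-12)
        assert g[i].sum() == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# CRF update + energy
# ---------------------------------------------------------------------------


def _pair_g():
    return sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))


def test_beta_zero_update_is_exact_identity():
    Q = np.random.default_rng(0).normal(size=(4, 3))
    H = crf_update(Q, sp.csr_matrix((4, 4)), alpha=1.0, beta=0.0, iterations=7)
    np.testing.assert_array_equal(H, Q)


def test_two_node_hand_example_after_one_iteration():
    Q = np.array([[0.0], [1.0]])
    H = crf_update(Q, _pair_g(), alpha=1.0, beta=1.0, iterations=1)
    np.testing.assert_allclose(H, [[0.5], [0.5]])


def test_update_converges_to_fixed_point():
    rng = np.random.default_rng(4)
    A = random_symmetric_adjacency(8, 0.4, rng)
    H8 = rng.normal(size=(8, 3))
    g = attention_coefficients(H8, np.eye(3), rng.normal(size=6), A)
    Q = rng.normal(size=(8, 3))
    H_prev = crf_update(Q, g, 1.0, 1.0, iterations=60)
    H_next = crf_update(Q, g, 1.0, 1.0, iterations=61)
    assert np.abs(H_next - H_prev).max() < 1e-8
    # fixed point satisfies the update equation
    s = np.asarray(g.sum(axis=1)).ravel()[:, None]
    lhs = H_next * (1.0 + 1.0 * s)
    rhs = Q + g @ H_next
    np.testing.assert_allclose(lhs, rhs, atol=1e-7)


def test_alpha_beta_both_zero_rejected():
    with pytest.raises(ValueError):
        crf_update(np.zeros((2, 2)), _pair_g(), alpha=0.0, beta=0.0)


def test_energy_zero_when_anchored_and_no_smoothing():
    Q = np.random.default_rng(1).normal(size=(3, 2))
    assert crf_loss(Q, Q, sp.csr_matrix((3, 3)), alpha=1.0, beta=0.0) == 0.0


def test_energy_of_hand_example_is_one_half():
    Q = np.array([[0.0], [1.0]])
    H = np.array([[0.5], [0.5]])
    assert crf_loss(H, Q, _pair_g(), alpha=1.0, beta=1.0) == pytest.approx(0.5)


def test_numerical_minimizer_beats_unrolled_update_energy():
    """The CRF energy is a convex quadratic in H: its global minimum can be
    found numerically and must lower-bound the T=10 update's energy."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(6)
    A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float))
    g = attention_coefficients(rng.normal(size=(3, 2)), np.eye(2),
                               rng.normal(size=4), A)
    Q = rng.normal(size=(3, 2))
    H10 = crf_update(Q, g, 1.0, 1.0, iterations=10)
    e10 = crf_loss(H10, Q, g, 1.0, 1.0)
    res = minimize(
        lambda h: crf_loss(h.reshape(3, 2), Q, g, 1.0, 1.0),
        x0=rng.normal(size=6),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15},
    )
    assert res.fun <= e10 + 1e-9


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def test_weighted_bce_reference_values():
    assert weighted_bce([0.5], [1], positive_weight=1) == pytest.approx(np.log(2))
    assert weighted_bce([0.5], [1], positive_weight=3) == pytest.approx(3 * np.log(2))
    for p in (1, 2, 5):
        assert weighted_bce([0.5], [0], positive_weight=p) == pytest.approx(np.log(2))


def test_weighted_bce_clamps_degenerate_probabilities():
    assert np.isfinite(weighted_bce([0.0, 1.0], [1, 0], positive_weight=2))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(0.01, 0.99), min_size=3, max_size=12),
    st.floats(1.0, 10.0),
    st.floats(0.1, 5.0),
)
def test_positive_weight_monotonicity(hs, p, dp):
    """Holding scores and labels fixed, the loss is non-decreasing in the
    positive weight, strictly when a positive is imperfectly scored."""
    rng = np.random.default_rng(0)
    ys = (rng.random(len(hs)) < 0.5).astype(int)
    lo = weighted_bce(hs, ys, positive_weight=p)
    hi = weighted_bce(hs, ys, positive_weight=p + dp)
    assert hi >= lo - 1e-12
    if ys.sum() and min(h for h, y in zip(hs, ys) if y == 1) < 1:
        assert hi > lo


# ---------------------------------------------------------------------------
# estimator behaviour
# ---------------------------------------------------------------------------


def _toy_problem(seed=0, n=24):
    rng = np.random.default_rng(seed)
    A = random_symmetric_adjacency(n, 0.15, rng)
    y = (rng.random(n) < 0.4).astype(int)
    X = np.column_stack([y + rng.normal(0, 0.3, n), rng.normal(size=(n, 3))])
    return X, y, A


def test_beta_zero_reduces_to_plain_gcn():
    X, y, A = _toy_problem()
    est = GCNCRFClassifier(hidden_dim=5, beta=0.0, epochs=1, dropout=0.0)
    est.fit(X, y, adjacency=A)
    scores = est.predict_proba(X)[:, 1]
    a_hat = normalize_adjacency(A)
    h1 = gcn_layer(X, a_hat, est.params_["W1"], "relu")
    manual = gcn_layer(h1, a_hat, est.params_["W2"], "sigmoid").ravel()
    np.testing.assert_allclose(scores, manual, atol=1e-10)


def test_scores_lie_in_open_unit_interval_and_are_deterministic():
    X, y, A = _toy_problem(1)
    est = GCNCRFClassifier(hidden_dim=6, epochs=30, random_state=5)
    est.fit(X, y, adjacency=A)
    s1 = est.predict_proba(X)[:, 1]
    s2 = est.predict_proba(X)[:, 1]
    assert ((s1 > 0) & (s1 < 1)).all()
    np.testing.assert_array_equal(s1, s2)


def test_prediction_is_equivariant_to_node_permutation():
    X, y, A = _toy_problem(2)
    est = GCNCRFClassifier(hidden_dim=4, epochs=20, random_state=1)
    est.fit(X, y, adjacency=A)
    scores = est.predict_proba(X)[:, 1]
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    A_perm = A.toarray()[np.ix_(perm, perm)]
    scores_perm = est.predict_proba(X[perm], adjacency=sp.csr_matrix(A_perm))[:, 1]
    np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-10)


def test_zeroed_output_head_scores_one_half():
    X, y, A = _toy_problem(3)
    est = GCNCRFClassifier(hidden_dim=4, epochs=1, dropout=0.0)
    est.fit(X, y, adjacency=A)
    est.params_["W2"][:] = 0.0
    np.testing.assert_allclose(est.predict_proba(X)[:, 1], 0.5)


def test_training_decreases_total_loss_and_is_reproducible():
    X, y, A = _toy_problem(4)
    kw = dict(hidden_dim=8, epochs=100, random_state=7)
    est = GCNCRFClassifier(**kw).fit(X, y, adjacency=A)
    assert est.loss_trace_[-1, 0] < est.loss_trace_[0, 0]
    est2 = GCNCRFClassifier(**kw).fit(X, y, adjacency=A)
    np.testing.assert_array_equal(est.loss_trace_, est2.loss_trace_)


def test_single_class_training_mask_rejected():
    X, y, A = _toy_problem(5)
    mask = y == 0
    with pytest.raises(ValueError, match="both classes"):
        GCNCRFClassifier(epochs=1).fit(X, y, adjacency=A, train_mask=mask)


def test_feature_dimension_mismatch_rejected_at_predict():
    X, y, A = _toy_problem(6)
    est = GCNCRFClassifier(hidden_dim=4, epochs=1).fit(X, y, adjacency=A)
    with pytest.raises(ValueError, match="dimension"):
        est.predict_proba(X[:, :2])


def test_checkpoint_round_trip_is_bit_identical(tmp_path):
    X, y, A = _toy_problem(7)
    est = GCNCRFClassifier(hidden_dim=4, epochs=25, random_state=3)
    est.fit(X, y, adjacency=A)
    path = tmp_path / "model.npz"
    est.save(path)
    loaded = GCNCRFClassifier.load(path)
    np.testing.assert_array_equal(
        est.predict_proba(X)[:, 1], loaded.predict_proba(X, adjacency=A)[:, 1]
    )


def test_grid_search_returns_argmax_of_cv_aupr():
    X, y, A = _toy_problem(8, n=40)
    grid = [{"learning_rate": 0.05}, {"learning_rate": 1e-6}]
    best, results = grid_search_cv(
        X, y, A, np.ones(len(y), bool), grid,
        base_params={"hidden_dim": 4, "epochs": 30}, cv_folds=3, seed=0,
    )
    assert best == max(results, key=lambda t: t[1])[0]
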