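"""Oracle and contract tests for the differentiable model core."""

import numpy as np
import pytest
from scipy.special import gammaln

from cellmil.autodiff import Tensor
from cellmil.model import (
    AttentionModule,
    ModelState,
    attention_scores,
    bag_embedding,
    bag_softmax,
    cell_loss,
    gmm_split_scores,
    make_pseudo_labels,
    nb_negloglik,
    opl,
    sample_loss,
    weighted_bce,
)


# ---------------------------------------------------------------------------
# NB negative log-likelihood
# ---------------------------------------------------------------------------
def nb_logpmf_oracle(x, mu, theta):
    """Direct log-gamma evaluation of the NB pmf (independent oracle)."""
    return (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (theta + mu)))


def test_nb_loss_matches_pmf_oracle_on_random_matrix():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 20, size=(5, 7)).astype(float)
    mu = rng.uniform(0.5, 8.0, size=(5, 7))
    theta = rng.uniform(0.3, 5.0, size=(5, 7))
    expected = -nb_logpmf_oracle(x, mu, theta).sum(axis=1).mean()
    got = float(nb_negloglik(x, mu, theta).data)
    assert got == pytest.approx(expected, rel=1e-6)


def test_nb_loss_poisson_limit():
    # at huge dispersion the NB tends to Poisson: -log P(0 | mu) = mu
    loss = float(nb_negloglik(np.array([[0.0]]), np.array([[2.0]]),
                              np.array([[1e8]])).data)
    assert loss == pytest.approx(2.0, abs=1e-3)


def test_nb_loss_single_example_hand_value():
    # x=3, mu=2, theta=1 against the closed-form pmf
    expected = -nb_logpmf_oracle(3.0, 2.0, 1.0)
    got = float(nb_negloglik(np.array([[3.0]]), np.array([[2.0]]),
                             np.array([[1.0]])).data)
    assert got == pytest.approx(float(expected), rel=1e-9)


def test_nb_loss_gradient_zero_at_mean_equal_count():
    # MLE stationarity: d/dmu -log NB(x | mu, theta) = 0 at mu = x
    mu = Tensor(np.array([[4.0]]), requires_grad=True)
    nb_negloglik(np.array([[4.0]]), mu, np.array([[2.0]])).backward()
    assert abs(mu.grad[0, 0]) < 1e-8


def test_nb_loss_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        nb_negloglik(np.array([[1.5]]), np.array([[1.0]]), np.array([[1.0]]))
    with pytest.raises(ValueError):
        nb_negloglik(np.array([[1.0]]), np.array([[-1.0]]), np.array([[1.0]]))
    with pytest.raises(ValueError):
        nb_negloglik(np.array([[1.0]]), np.array([[1.0]]), np.array([[0.0]]))


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("n_cells", [1, 2, 10, 1000])
def test_attention_sums_to_one_and_is_permutation_equivariant(n_cells):
    rng = np.random.default_rng(n_cells)
    att = AttentionModule(6, 4, rng)
    Z = rng.normal(size=(n_cells, 6)).astype(np.float32)
    a = attention_scores(Z, att).data
    assert a.sum() == pytest.approx(1.0, abs=1e-6)
    perm = rng.permutation(n_cells)
    a_perm = attention_scores(Z[perm], att).data
    np.testing.assert_allclose(a_perm, a[perm], atol=1e-6)


def test_attention_single_cell_and_identical_latents():
    rng = np.random.default_rng(1)
    att = AttentionModule(4, 3, rng)
    one = attention_scores(np.ones((1, 4), dtype=np.float32), att).data
    assert one == pytest.approx([1.0])
    same = attention_scores(np.tile([0.3, -1.0, 2.0, 0.5], (5, 1)), att).data
    np.testing.assert_allclose(same, np.full(5, 0.2), atol=1e-6)


def test_attention_matches_hand_computed_logits():
    att = AttentionModule(2, 2, np.random.default_rng(0))
    V = np.array([[1.0, -0.5], [0.2, 0.8]])
    w = np.array([[0.7], [-1.2]])
    att.V.W.data = V.T.astype(np.float32)  # Linear stores (in, out)
    att.w.W.data = w.astype(np.float32)
    Z = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
    logits = np.tanh(Z @ V.T) @ w
    expected = np.exp(logits) / np.exp(logits).sum()
    got = attention_scores(Z, att).data
    np.testing.assert_allclose(got, expected.ravel(), rtol=1e-5)


def test_attention_rejects_empty_bag():
    att = AttentionModule(3, 2, np.random.default_rng(0))
    with pytest.raises(ValueError):
        attention_scores(np.empty((0, 3)), att)


def test_bag_embedding_cases():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(3, 5))
    onehot = np.array([0.0, 1.0, 0.0])
    np.testing.assert_allclose(bag_embedding(Z, onehot).data, Z[1])
    a = rng.dirichlet(np.ones(3))
    np.testing.assert_allclose(bag_embedding(Z, a).data, (a[:, None] * Z).sum(0))
    with pytest.raises(ValueError):
        bag_embedding(Z, np.ones(2))


# ---------------------------------------------------------------------------
# classification losses
# ---------------------------------------------------------------------------
def test_sample_loss_values():
    assert float(sample_loss(np.full(4, 0.5), np.array([0, 1, 0, 1.0])).data) \
        == pytest.approx(np.log(2), rel=1e-6)
    # hand-evaluated mixed batch
    y_hat = np.array([0.9, 0.2])
    y = np.array([1.0, 0.0])
    expected = -(np.log(0.9) + np.log(0.8)) / 2
    assert float(sample_loss(y_hat, y).data) == pytest.approx(expected, rel=1e-6)
    # perfect predictions survive clipping
    assert float(sample_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])).data) \
        <= -np.log(1 - 1e-7) + 1e-9


def test_weighted_bce_closed_forms():
    # lam = 0.5 halves the symmetric soft-target BCE
    rng = np.random.default_rng(3)
    tau_hat = rng.uniform(0.1, 0.9, 20)
    tau = rng.uniform(0, 1, 20)
    full = -(tau * np.log(tau_hat) + (1 - tau) * np.log(1 - tau_hat)).mean()
    assert float(weighted_bce(tau_hat, tau, 0.5).data) \
        == pytest.approx(0.5 * full, rel=1e-6)
    # all-zero targets at tau_hat = 0.5
    assert float(weighted_bce(np.full(8, 0.5), np.zeros(8), 0.3).data) \
        == pytest.approx(0.3 * np.log(2), rel=1e-6)
    with pytest.raises(ValueError):
        weighted_bce(tau_hat, tau, 1.5)


def test_pseudo_labels_modes():
    a = np.array([0.5, 0.3, 0.2])
    np.testing.assert_allclose(make_pseudo_labels(a, False), np.zeros(3))
    np.testing.assert_allclose(make_pseudo_labels(a, True, "none"), a)
    np.testing.assert_allclose(make_pseudo_labels(a, True, "bag_max"),
                               [1.0, 0.6, 0.4])
    with pytest.raises(ValueError):
        make_pseudo_labels(a, True, "unknown")


# ---------------------------------------------------------------------------
# OPL
# ---------------------------------------------------------------------------
def brute_force_opl(Z, high):
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    S = Zn @ Zn.T
    n = len(Z)
    same_terms, cross_terms = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if high[i] == high[j]:
                same_terms.append(S[i, j])
            else:
                cross_terms.append(S[i, j])
    return 1.0 - np.mean(same_terms) + np.mean(cross_terms)


def test_opl_ideal_geometry_is_zero():
    # identical within clusters, orthogonal across
    Z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    high = np.array([True, True, False, False])
    assert float(opl(Z, high).data) == pytest.approx(0.0, abs=1e-6)


def test_opl_all_identical_is_one():
    Z = np.tile([0.3, 0.4, 0.5], (6, 1))
    high = np.array([True] * 3 + [False] * 3)
    assert float(opl(Z, high).data) == pytest.approx(1.0, abs=1e-6)


def test_opl_matches_exhaustive_pair_enumeration():
    rng = np.random.default_rng(9)
    Z = rng.normal(size=(10, 8))
    high = rng.random(10) < 0.4
    if high.all() or (~high).all():
        high[0] = ~high[0]
    assert float(opl(Z.astype(np.float64), high).data) \
        == pytest.approx(brute_force_opl(Z, high), rel=1e-6)


def test_opl_empty_cluster_returns_zero():
    Z = np.random.default_rng(0).normal(size=(4, 3))
    assert float(opl(Z, np.array([True] * 4)).data) == 0.0


def test_opl_range_bound():
    rng = np.random.default_rng(4)
    for trial in range(20):
        Z = rng.normal(size=(8, 5))
        high = rng.random(8) < 0.5
        if high.all() or (~high).all():
            continue
        val = float(opl(Z, high).data)
        assert -1.0 - 1e-9 <= val <= 3.0 + 1e-9


def test_cell_loss_composition():
    rng = np.random.default_rng(6)
    tau_hat = rng.uniform(0.1, 0.9, 12)
    tau = rng.uniform(0, 1, 12)
    Z = rng.normal(size=(6, 4))
    high = np.array([True, False, True, False, True, False])
    base = float(cell_loss(tau_hat, tau, Z, high, 0.3, 0.0).data)
    assert base == pytest.approx(float(weighted_bce(tau_hat, tau, 0.3).data))
    l2 = float(cell_loss(tau_hat, tau, Z, high, 0.3, 2.0).data)
    l0 = float(cell_loss(tau_hat, tau, Z, high, 0.3, 0.0).data)
    opl_val = float(opl(Z, high).data)
    assert l2 - l0 == pytest.approx(2.0 * opl_val, rel=1e-5)


# ---------------------------------------------------------------------------
# GMM high/low split
# ---------------------------------------------------------------------------
def test_gmm_split_separated_clusters_exact():
    scores = np.concatenate([np.full(50, 0.01), np.full(50, 0.99)])
    high = gmm_split_scores(scores, seed=0)
    assert not high[:50].any()
    assert high[50:].all()


def test_gmm_split_planted_gaussians_recovered():
    rng = np.random.default_rng(12)
    low = rng.normal(0.2, 0.05, 100)
    hi = rng.normal(0.8, 0.05, 100)
    scores = np.concatenate([low, hi])
    truth = np.array([False] * 100 + [True] * 100)
    high = gmm_split_scores(scores, seed=0)
    assert (high == truth).mean() >= 0.99


def test_gmm_split_degenerate_falls_back_to_median():
    with pytest.warns(RuntimeWarning):
        high = gmm_split_scores(np.full(10, 0.5), seed=0)
    assert high.sum() == 5  # both groups non-empty


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(Z=arrays(np.float64, (7, 3),
                    elements=st.floats(-5, 5, allow_nan=False)),
           split=st.integers(min_value=1, max_value=6))
    def test_opl_stays_in_range_property(Z, split):
        """For any embeddings and any nonempty split, OPL lies in [-1, 3]."""
        Z = Z + 1e-3  # avoid exact zero rows
        high = np.array([True] * split + [False] * (7 - split))
        val = float(opl(Z, high).data)
        assert -1.0 - 1e-6 <= val <= 3.0 + 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(logits=arrays(np.float64, 9,
                         elements=st.floats(-30, 30, allow_nan=False)))
    def test_bag_softmax_is_probability_vector_property(logits):
        a = bag_softmax(Tensor(logits)).data
        assert abs(a.sum() - 1.0) < 1e-9
        assert (a >= 0).all()
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_bag_softmax_gradient_matches_finite_differences():
    rng = np.random.default_rng(8)
    x = rng.normal(size=5)
    t = Tensor(x, requires_grad=True)
    (bag_softmax(t) * np.array([1.0, 0, 2.0, 0, -1.0])).sum().backward()

    def f(v):
        e = np.exp(v - v.max())
        return float((e / e.sum() * np.array([1.0, 0, 2.0, 0, -1.0])).sum())

    eps = 1e-6
    num = np.array([(f(x + eps * np.eye(5)[i]) - f(x - eps * np.eye(5)[i]))
                    / (2 * eps) for i in range(5)])
    np.testing.assert_allclose(t.grad, num, atol=1e-6)


# ---------------------------------------------------------------------------
# ModelState container
# ---------------------------------------------------------------------------
def test_model_state_roundtrip(tmp_path):
    state = ModelState.build(n_genes=30, encoder_widths=(16, 8),
                             attention_hidden=4, head_hidden=(4,), seed=1)
    state.encoder.gene_scale = np.linspace(0.5, 2.0, 30).astype(np.float32)
    x = np.random.default_rng(0).integers(0, 5, (6, 30)).astype(np.float32)
    a0, _, p0 = state.bag_forward(x)
    path = str(tmp_path / "ckpt.npz")
    state.save(path)
    loaded = ModelState.load(path)
    a1, _, p1 = loaded.bag_forward(x)
    np.testing.assert_allclose(a1, a0, rtol=1e-6)
    assert p1 == pytest.approx(p0, rel=1e-6)


def test_encoder_rejects_wrong_gene_count(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.encoder(np.ones((3, 999), dtype=np.float32))


def test_encode_deterministic(tiny_model, tiny_dataset):
    x = np.asarray(tiny_dataset.cells.counts[:20], dtype=np.float32)
    z1 = tiny_model.encode(x)
    z2 = tiny_model.encode(x)
    np.testing.assert_array_equal(z1, z2)
    assert z1.shape == (20, tiny_model.encoder.latent_dim)
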