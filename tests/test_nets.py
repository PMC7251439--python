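import numpy as np
import pytest
from sklearn.cluster import KMeans

from prostate_dss.nets import (
    MLPModel,
    init_mlp,
    kmeans_centers,
    net_predict,
    rbf_activation,
    train_mlp,
    train_rbf,
)
from conftest import make_blobs_6d

# --------------------------------------------------------------------------
# k-means
# --------------------------------------------------------------------------

def test_single_center_is_the_sample_mean():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 6))
    res = kmeans_centers(X, 1, seed=0)
    assert np.allclose(res.centers[0], X.mean(axis=0))


def test_k_equal_n_distinct_points_gives_zero_inertia():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((8, 6))
    res = kmeans_centers(X, 8, seed=0)
    assert res.inertia == pytest.approx(0.0, abs=1e-12)


def test_k_larger_than_distinct_samples_is_rejected():
    X = np.zeros((5, 6))
    with pytest.raises(ValueError):
        kmeans_centers(X, 2, seed=0)


def test_two_blobs_recover_blob_means_and_inertia_decreases():
    rng = np.random.default_rng(5)
    centers = np.vstack([_shift(-5.0), _shift(5.0)])
    X, _ = make_blobs_6d(rng, centers, n_per=200, sd=1.0)
    res = kmeans_centers(X, 2, seed=3)
    history = res.inertia_history
    assert all(a >= b - 1e-9 for a, b in zip(history, history[1:]))
    se = 1.0 / np.sqrt(200)
    found = res.centers[np.argsort(res.centers[:, 0])]
    for c_found, c_true in zip(found, centers):
        assert np.all(np.abs(c_found - c_true) < 3 * se + 0.1)


def test_lloyd_inertia_is_competitive_with_sklearn():
    rng = np.random.default_rng(7)
    centers = np.vstack([_shift(-4.0), _shift(0.0), _shift(4.0)])
    X, _ = make_blobs_6d(rng, centers, n_per=100, sd=0.8)
    ours = kmeans_centers(X, 3, seed=1).inertia
    ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X).inertia_
    assert ours <= ref * 1.05


def _shift(v):
    c = np.zeros(6)
    c[0] = v
    return c


# --------------------------------------------------------------------------
# RBF activation and network
# --------------------------------------------------------------------------

def test_rbf_activation_closed_forms():
    c = np.ones(6)
    assert rbf_activation(c, c, beta=2.0) == 1.0
    x = c + np.array([1, 0, 0, 0, 0, 0])  # beta * d^2 = 1
    assert rbf_activation(x, c, beta=1.0) == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        rbf_activation(x, c, beta=0.0)


def test_rbf_activation_fourth_power_at_double_distance():
    c = np.zeros(6)
    x1 = _shift(1.0)
    x2 = _shift(2.0)
    a1 = rbf_activation(x1, c, beta=0.37)
    a2 = rbf_activation(x2, c, beta=0.37)
    assert a2 == pytest.approx(a1**4, rel=1e-12)


def test_rbf_interpolates_noise_free_clusters():
    rng = np.random.default_rng(2)
    centers = np.vstack([_shift(-6.0), _shift(-2.0), _shift(2.0), _shift(6.0)])
    X, y = make_blobs_6d(rng, centers, n_per=20, sd=0.05)
    stages = y + 1
    model = train_rbf(4, X, stages, epsilon=0.2, seed=0)
    scores = model.predict_scores(X)
    assert scores.shape == (80, 4)
    assert np.allclose(scores.sum(axis=1), 1.0)
    assert np.all(scores >= 0)
    assert np.array_equal(scores.argmax(axis=1) + 1, stages)


def test_rbf_hidden_width_matches_request():
    rng = np.random.default_rng(3)
    X, y = make_blobs_6d(rng, np.vstack([_shift(-3), _shift(-1), _shift(1), _shift(3)]),
                         n_per=30, sd=0.3)
    for k in (10, 14, 16):
        model = train_rbf(k, X, y + 1, epsilon=0.5, seed=0)
        assert model.centers.shape == (k, 6)
        assert np.all(model.betas > 0)


def test_rbf_rejects_more_centers_than_samples():
    with pytest.raises(ValueError):
        train_rbf(10, np.zeros((5, 6)), np.array([1, 2, 3, 4, 1]), 0.1, seed=0)


# --------------------------------------------------------------------------
# MLP
# --------------------------------------------------------------------------

def test_mlp_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    model = init_mlp((6, 9, 7, 4), seed=1)
    X = rng.standard_normal((10, 6))
    Y = np.eye(4)[rng.integers(0, 4, 10)]
    loss, gW, gB = model.loss_and_grads(X, Y)
    h = 1e-6
    for layer in range(len(model.weights)):
        W = model.weights[layer]
        idx = [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]
        for i, j in idx:
            W[i, j] += h
            lp, _, _ = model.loss_and_grads(X, Y)
            W[i, j] -= 2 * h
            lm, _, _ = model.loss_and_grads(X, Y)
            W[i, j] += h
            numeric = (lp - lm) / (2 * h)
            assert gW[layer][i, j] == pytest.approx(numeric, rel=1e-5, abs=1e-8)
        b = model.biases[layer]
        b[0] += h
        lp, _, _ = model.loss_and_grads(X, Y)
        b[0] -= 2 * h
        lm, _, _ = model.loss_and_grads(X, Y)
        b[0] += h
        assert gB[layer][0] == pytest.approx((lp - lm) / (2 * h), rel=1e-5, abs=1e-8)


@pytest.mark.parametrize("arch", [(6, 9, 7, 4), (6, 10, 7, 5, 4), (6, 7, 5, 4)])
def test_mlp_learns_well_separated_clusters(arch):
    rng = np.random.default_rng(4)
    centers = np.vstack([_shift(-6.0), _shift(-2.0), _shift(2.0), _shift(6.0)])
    X, y = make_blobs_6d(rng, centers, n_per=40, sd=0.3)
    model = train_mlp(arch, X, y + 1, epsilon=0.05, seed=0)
    scores = model.predict_scores(X)
    assert np.allclose(scores.sum(axis=1), 1.0)
    assert np.mean(scores.argmax(axis=1) + 1 == y + 1) >= 0.95


def test_mlp_rejects_bad_architecture_and_empty_input():
    with pytest.raises(ValueError):
        train_mlp((5, 4), np.zeros((4, 6)), np.array([1, 2, 3, 4]), 0.1, seed=0)
    with pytest.raises(ValueError):
        train_mlp((6, 9, 7, 4), np.zeros((0, 6)), np.array([]), 0.1, seed=0)


def test_net_predict_is_deterministic_and_normalized():
    rng = np.random.default_rng(6)
    X, y = make_blobs_6d(rng, np.vstack([_shift(-2), _shift(-1), _shift(1), _shift(2)]),
                         n_per=20, sd=0.2)
    model = train_mlp((6, 7, 5, 4), X, y + 1, epsilon=0.5, seed=0)
    x = X[0]
    s1 = net_predict(model, x)
    s2 = net_predict(model, x)
    assert np.array_equal(s1, s2)
    assert s1.shape == (4,)
    assert s1.sum() == pytest.approx(1.0)
    assert np.all(s1 >= 0)
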