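"""Neural base learners: fixed-architecture MLPs and RBF networks.

Both net families map the six standardized markers to a four-dimensional
stage score vector (non-negative, summing to one).

MLPs use ReLU hidden layers and a softmax output trained with cross-entropy
by plain full-batch gradient descent.  The three architectures are fixed:
6-9-7-4, 6-10-7-5-4 and 6-7-5-4.

RBF networks have a single hidden layer of Gaussian units
f(x, c_i) = exp(-beta_i ||x - c_i||^2) whose centers come from k-means
(10, 14 or 16 units); output weights are fitted by ridge-regularized least
squares against one-hot stage targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .core import MALIGNANT_STAGES, StageLabel, Standardizer


# ---------------------------------------------------------------------------
# k-means (Lloyd's algorithm with per-iteration inertia tracking)
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    centers: np.ndarray  # (k, d)
    inertia: float
    inertia_history: list[float]


def kmeans_centers(
    X: np.ndarray, k: int, seed: int, max_iter: int = 300
) -> KMeansResult:
    """Lloyd iteration from a seeded random subset of distinct points.

    Inertia (sum of squared distances to the assigned center) is recorded
    after every assignment step and verified non-increasing.  Empty clusters
    are reseeded to the point currently farthest from its center.
    """
    X = np.asarray(X, dtype=float)
    distinct = np.unique(X, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds the number of distinct samples ({len(distinct)})")
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(len(distinct), size=k, replace=False)].copy()
    history: list[float] = []
    assign = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(len(X)), new_assign].sum())
        if history and inertia > history[-1] + 1e-9:
            raise AssertionError("k-means inertia increased")  # pragma: no cover
        history.append(inertia)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = X[assign == j]
            if len(members) == 0:
                worst = int(np.argmax(d2[np.arange(len(X)), assign]))
                centers[j] = X[worst]
            else:
                centers[j] = members.mean(axis=0)
    return KMeansResult(centers=centers, inertia=history[-1], inertia_history=history)


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

def rbf_activation(x: np.ndarray, center: np.ndarray, beta: float) -> float:
    """Gaussian bump exp(-beta ||x - c||^2); equals 1 iff x = c."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    return float(np.exp(-beta * np.sum((x - center) ** 2)))


@dataclass
class RBFModel:
    centers: np.ndarray  # (k, 6)
    betas: np.ndarray  # (k,)
    W: np.ndarray  # (k, 4) output weights
    b: np.ndarray  # (4,) output bias
    scaler: Standardizer | None = None
    diagnostics: dict = field(default_factory=dict)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.betas[None, :] * d2)

    def predict_scores(self, X: np.ndarray, *, apply_scaler: bool = True) -> np.ndarray:
        """(n, 4) non-negative scores summing to one per row.

        Raw least-squares outputs are clipped at zero and renormalized
        (uniform fallback when a row clips to all zeros).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if apply_scaler and self.scaler is not None:
            X = self.scaler.transform(X)
        raw = self.hidden(X) @ self.W + self.b
        clipped = np.maximum(raw, 0.0)
        sums = clipped.sum(axis=1, keepdims=True)
        out = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), 0.25)
        return out


def _rbf_widths(centers: np.ndarray) -> np.ndarray:
    """beta_i = 1 / (2 m_i^2), m_i = mean distance to the two nearest other centers."""
    k = len(centers)
    if k == 1:
        return np.array([0.5])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    betas = np.empty(k)
    for i in range(k):
        nearest = np.sort(d[i])[: min(2, k - 1)]
        m = float(np.mean(nearest))
        m = max(m, 1e-6)
        betas[i] = 1.0 / (2.0 * m * m)
    return betas


def _stage_onehot(stages: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(stages), 4))
    Y[np.arange(len(stages)), stages - 1] = 1.0
    return Y


def _fit_rbf_weights(
    Phi: np.ndarray, Y: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    design = np.hstack([Phi, np.ones((len(Phi), 1))])
    A = design.T @ design + ridge * np.eye(design.shape[1])
    coef = np.linalg.solve(A, design.T @ Y)
    return coef[:-1], coef[-1]


def train_rbf(
    hidden_count: int,
    X: np.ndarray,
    stages: np.ndarray,
    epsilon: float,
    seed: int,
    ridge: float = 1e-6,
    scaler: Standardizer | None = None,
) -> RBFModel:
    """Fit one RBF network: k-means centers, heuristic widths, ridge output fit.

    stages are integer labels 1-4.  The held-out error reported in the
    diagnostics comes from an internal 4:1 split; the delivered weights are
    refitted on all data.
    """
    X = np.asarray(X, dtype=float)
    stages = np.asarray(stages, dtype=int)
    if hidden_count > len(X):
        raise ValueError("hidden_count exceeds the number of training samples")
    if scaler is not None:
        X = scaler.transform(X)
    Y = _stage_onehot(stages)
    km = kmeans_centers(X, hidden_count, seed)
    betas = _rbf_widths(km.centers)

    def scores(Xq, W, b):
        d2 = ((Xq[:, None, :] - km.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-betas[None, :] * d2) @ W + b

    idx_tr, idx_va = train_test_split(
        np.arange(len(X)), test_size=0.2, random_state=seed, stratify=stages
    )
    Phi_tr = np.exp(
        -betas[None, :]
        * ((X[idx_tr, None, :] - km.centers[None, :, :]) ** 2).sum(axis=2)
    )
    W, b = _fit_rbf_weights(Phi_tr, Y[idx_tr], ridge)
    pred_va = np.argmax(scores(X[idx_va], W, b), axis=1) + 1
    err = float(np.mean(pred_va != stages[idx_va]))
    if err > epsilon:
        warnings.warn(
            f"RBF held-out error {err:.3f} above epsilon {epsilon:.3f}", stacklevel=2
        )
    Phi = np.exp(
        -betas[None, :] * ((X[:, None, :] - km.centers[None, :, :]) ** 2).sum(axis=2)
    )
    W, b = _fit_rbf_weights(Phi, Y, ridge)
    return RBFModel(
        centers=km.centers,
        betas=betas,
        W=W,
        b=b,
        scaler=scaler,
        diagnostics={
            "held_out_error": err,
            "epsilon_ok": bool(err <= epsilon),
            "kmeans_inertia": km.inertia,
        },
    )


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


@dataclass
class MLPModel:
    """Feed-forward net with ReLU hidden layers and a softmax output."""

    sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler: Standardizer | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray, *, apply_scaler: bool = True) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if apply_scaler and self.scaler is not None:
            X = self.scaler.transform(X)
        A = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            A = np.maximum(A @ W + b, 0.0)
        return _softmax(A @ self.weights[-1] + self.biases[-1])

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean cross-entropy and its analytic gradients (backpropagation)."""
        n = len(X)
        acts = [np.asarray(X, dtype=float)]
        pre: list[np.ndarray] = []
        A = acts[0]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            Z = A @ W + b
            pre.append(Z)
            A = np.maximum(Z, 0.0)
            acts.append(A)
        Z_out = A @ self.weights[-1] + self.biases[-1]
        P = _softmax(Z_out)
        loss = float(-np.mean(np.sum(Y * np.log(P + 1e-12), axis=1)))
        dZ = (P - Y) / n
        gW: list[np.ndarray] = [None] * len(self.weights)
        gB: list[np.ndarray] = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            gW[layer] = acts[layer].T @ dZ
            gB[layer] = dZ.sum(axis=0)
            if layer > 0:
                dA = dZ @ self.weights[layer].T
                dZ = dA * (pre[layer - 1] > 0)
        return loss, gW, gB


def init_mlp(architecture: tuple[int, ...], seed: int) -> MLPModel:
    """He-initialized MLP with zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(architecture, architecture[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return MLPModel(sizes=tuple(architecture), weights=weights, biases=biases)


def train_mlp(
    architecture: tuple[int, ...],
    X: np.ndarray,
    stages: np.ndarray,
    epsilon: float,
    seed: int,
    learning_rate: float = 0.01,
    max_epochs: int = 2000,
    scaler: Standardizer | None = None,
) -> MLPModel:
    """Full-batch gradient descent with cross-entropy against one-hot targets.

    Training stops early once the internal held-out error (a stratified
    fifth of the data, checked every 25 epochs) drops to epsilon or below;
    otherwise the best-held-out weights seen are kept and a warning issued.
    """
    if len(architecture) < 2 or architecture[0] != 6 or architecture[-1] != 4:
        raise ValueError(f"architecture must run from 6 inputs to 4 outputs, got {architecture}")
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    stages = np.asarray(stages, dtype=int)
    if scaler is not None:
        X = scaler.transform(X)
    Y = _stage_onehot(stages)
    idx_tr, idx_va = train_test_split(
        np.arange(len(X)), test_size=0.2, random_state=seed, stratify=stages
    )
    model = init_mlp(tuple(architecture), seed)
    best_err = np.inf
    best_params: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    stopped_epoch = max_epochs
    for epoch in range(1, max_epochs + 1):
        _, gW, gB = model.loss_and_grads(X[idx_tr], Y[idx_tr])
        for layer in range(len(model.weights)):
            model.weights[layer] -= learning_rate * gW[layer]
            model.biases[layer] -= learning_rate * gB[layer]
        if epoch % 25 == 0 or epoch == max_epochs:
            pred = np.argmax(model.predict_scores(X[idx_va], apply_scaler=False), axis=1) + 1
            err = float(np.mean(pred != stages[idx_va]))
            if err < best_err:
                best_err = err
                best_params = (
                    [W.copy() for W in model.weights],
                    [b.copy() for b in model.biases],
                )
            if err <= epsilon:
                stopped_epoch = epoch
                break
    if best_params is not None:
        model.weights, model.biases = best_params
    if best_err > epsilon:
        warnings.warn(
            f"MLP held-out error {best_err:.3f} above epsilon {epsilon:.3f} "
            f"after {max_epochs} epochs",
            stacklevel=2,
        )
    model.scaler = scaler
    model.diagnostics = {
        "held_out_error": best_err,
        "epsilon_ok": bool(best_err <= epsilon),
        "stopped_epoch": stopped_epoch,
    }
    return model


def net_predict(model: MLPModel | RBFModel, x: np.ndarray) -> np.ndarray:
    """Four-dimensional stage score vector (>= 0, summing to 1) for one input."""
    return model.predict_scores(np.asarray(x, dtype=float)[None, :])[0]
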