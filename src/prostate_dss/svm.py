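"""Soft-margin SVMs: kernels, binary dual-form models, one-vs-one committees.

The binary classifier is the standard soft-margin SVM.  In the dual, the
coefficients alpha solve

    max  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)
    s.t. sum_i y_i alpha_i = 0,   0 <= alpha_i <= C,

and the decision function is sign(sum_i alpha_i y_i K(x_i, x) + b).  The QP
itself is solved by scikit-learn's SVC on a precomputed Gram matrix built
from the kernel implementations below; the fitted model is stored in
explicit dual form so the box and equality constraints can be audited.

Staging uses one-vs-one committees: one binary SVM per unordered pair of the
four malignant stages (six per committee), combined by majority voting into
a four-dimensional one-hot vector.  Three committees with different kernel
kinds (linear, polynomial, Gaussian) provide the kernel perturbation that
differentiates the ensemble's SVM base learners.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .core import (
    MALIGNANT_STAGES,
    LabeledSample,
    StageLabel,
    Standardizer,
    profiles_to_matrix,
)

KERNEL_KINDS = ("linear", "polynomial", "gauss", "sigmoid", "laplace")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel kind plus exactly the parameters that kind requires.

    linear      k(x,z) = x.z
    polynomial  k(x,z) = (x.z)^d                 (degree d >= 1)
    gauss       k(x,z) = exp(-||x-z||^2 / 2 sigma^2)
    laplace     k(x,z) = exp(-||x-z|| / sigma)
    sigmoid     k(x,z) = tanh(beta x.z + theta)

    The exponential-of-distance formula is the Laplace kernel and the tanh
    formula the sigmoid kernel (their conventional names), whichever order a
    reference table happens to print them in.
    """

    kind: str
    degree: int | None = None
    sigma: float | None = None
    beta: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial":
            if self.degree is None or self.degree < 1 or self.degree != int(self.degree):
                raise ValueError("polynomial kernel requires integer degree >= 1")
        if self.kind in ("gauss", "laplace"):
            if self.sigma is None or self.sigma <= 0:
                raise ValueError(f"{self.kind} kernel requires sigma > 0")
        if self.kind == "sigmoid":
            if self.beta is None or self.theta is None:
                raise ValueError("sigmoid kernel requires beta and theta")


def kernel_gram(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Z[j]), vectorized."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("dimension mismatch between x and z")
    if spec.kind == "linear":
        return X @ Z.T
    if spec.kind == "polynomial":
        return (X @ Z.T) ** spec.degree
    if spec.kind == "gauss":
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Z**2, axis=1)[None, :]
            - 2.0 * X @ Z.T
        )
        return np.exp(-np.maximum(d2, 0.0) / (2.0 * spec.sigma**2))
    if spec.kind == "laplace":
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Z**2, axis=1)[None, :]
            - 2.0 * X @ Z.T
        )
        return np.exp(-np.sqrt(np.maximum(d2, 0.0)) / spec.sigma)
    # sigmoid
    return np.tanh(spec.beta * (X @ Z.T) + spec.theta)


def kernel_eval(spec: KernelSpec, x: np.ndarray, z: np.ndarray) -> float:
    """k(x, z) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have equal dimension")
    return float(kernel_gram(spec, x[None, :], z[None, :])[0, 0])


@dataclass
class BinarySVMModel:
    """Fitted soft-margin SVM in dual form.

    sv_x / sv_y / alpha hold the support vectors, their labels (+-1) and
    dual coefficients; b is the offset of the decision function.  The box
    constraint 0 <= alpha_i <= C and the equality sum_i alpha_i y_i = 0
    hold for every fit (asserted in the test suite).
    """

    sv_x: np.ndarray
    sv_y: np.ndarray
    alpha: np.ndarray
    b: float
    C: float
    kernel: KernelSpec
    scaler: Standardizer | None = None
    diagnostics: dict = field(default_factory=dict)


def train_binary_svm(
    X: np.ndarray, y: np.ndarray, C: float, kernel: KernelSpec
) -> BinarySVMModel:
    """Fit the dual soft-margin SVM on (X, y) with y in {-1, +1}.

    X is used as given (standardize upstream); the returned model keeps the
    dual objective value among its diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if C <= 0:
        raise ValueError("C must be > 0")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        raise ValueError("need both labels -1 and +1 in the training data")
    K = kernel_gram(kernel, X, X)
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(K, y)
    sv = clf.support_
    dual = clf.dual_coef_[0]  # = alpha_i * y_i over support vectors
    sv_y = y[sv]
    alpha = dual * sv_y  # recover alpha_i >= 0
    K_sv = K[np.ix_(sv, sv)]
    objective = float(alpha.sum() - 0.5 * dual @ K_sv @ dual)
    model = BinarySVMModel(
        sv_x=X[sv].copy(),
        sv_y=sv_y.copy(),
        alpha=alpha.copy(),
        b=float(clf.intercept_[0]),
        C=float(C),
        kernel=kernel,
        diagnostics={"dual_objective": objective, "n_support": int(len(sv))},
    )
    return model


def decision_values(model: BinarySVMModel, X: np.ndarray) -> np.ndarray:
    """Raw decision values f(x) = sum_i alpha_i y_i K(x_i, x) + b for each row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.scaler is not None:
        X = model.scaler.transform(X)
    K = kernel_gram(model.kernel, X, model.sv_x)
    return K @ (model.alpha * model.sv_y) + model.b


def svm_decision(model: BinarySVMModel, x: np.ndarray) -> tuple[float, int]:
    """(raw value, sign) for one input; the sign is +1 when raw >= 0."""
    raw = float(decision_values(model, np.asarray(x, dtype=float)[None, :])[0])
    return raw, (1 if raw >= 0 else -1)


def dual_objective(model: BinarySVMModel) -> float:
    dual = model.alpha * model.sv_y
    K = kernel_gram(model.kernel, model.sv_x, model.sv_x)
    return float(model.alpha.sum() - 0.5 * dual @ K @ dual)


#: Unordered stage pairs of the one-vs-one decomposition, in canonical order.
STAGE_PAIRS: tuple[tuple[StageLabel, StageLabel], ...] = tuple(
    itertools.combinations(MALIGNANT_STAGES, 2)
)


@dataclass
class OvOGroup:
    """Six pairwise SVMs over stages I-IV sharing one kernel kind."""

    models: dict[tuple[StageLabel, StageLabel], BinarySVMModel]
    kernel_kind: str
    scaler: Standardizer | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.models) != set(STAGE_PAIRS):
            raise ValueError("a one-vs-one group needs exactly the 6 stage pairs")


def expand_kernel_grid(
    kind: str,
    *,
    sigma_grid: tuple[float, ...] = (1.0, 2.0),
    degree_grid: tuple[int, ...] = (2, 3),
    sigmoid_beta: float = 0.5,
    sigmoid_theta: float = -1.0,
) -> list[KernelSpec]:
    """Candidate KernelSpecs for a hyperparameter search over one kind."""
    if kind == "linear":
        return [KernelSpec("linear")]
    if kind == "polynomial":
        return [KernelSpec("polynomial", degree=d) for d in degree_grid]
    if kind in ("gauss", "laplace"):
        return [KernelSpec(kind, sigma=s) for s in sigma_grid]
    if kind == "sigmoid":
        return [KernelSpec("sigmoid", beta=sigmoid_beta, theta=sigmoid_theta)]
    raise ValueError(f"unknown kernel kind {kind!r}")


def search_binary_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...],
    kernel_candidates: list[KernelSpec],
    epsilon: float,
    seed: int,
) -> tuple[BinarySVMModel, float, bool]:
    """Grid-search (C, kernel) on a held-out fifth, refit the best on all data.

    Returns (model, held-out error of the winner, error <= epsilon flag).
    A warning is recorded when no grid point reaches epsilon.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=0.2, random_state=seed, stratify=y
    )
    best: tuple[float, float, KernelSpec] | None = None  # (err, C, spec)
    for spec in kernel_candidates:
        K_tr = kernel_gram(spec, X[idx_tr], X[idx_tr])
        K_va = kernel_gram(spec, X[idx_va], X[idx_tr])
        for C in c_grid:
            clf = SVC(C=C, kernel="precomputed")
            clf.fit(K_tr, y[idx_tr])
            err = float(np.mean(clf.predict(K_va) != y[idx_va]))
            if best is None or err < best[0] - 1e-12:
                best = (err, C, spec)
    err, C, spec = best
    ok = err <= epsilon
    if not ok:
        warnings.warn(
            f"binary SVM held-out error {err:.3f} above epsilon {epsilon:.3f} "
            f"after grid search (kept best found)",
            stacklevel=2,
        )
    model = train_binary_svm(X, y, C, spec)
    model.diagnostics.update({"held_out_error": err, "epsilon_ok": bool(ok)})
    return model, err, ok


def train_ovo_group(
    samples: list[LabeledSample],
    c_grid: tuple[float, ...],
    kernel_candidates: list[KernelSpec],
    epsilon: float,
    seed: int,
    scaler: Standardizer | None = None,
) -> OvOGroup:
    """Train the six pairwise stage classifiers of one committee.

    Each pairwise model sees only its two classes.  When no scaler is
    supplied one is fitted on all malignant samples given here.
    """
    staged = [s for s in samples if s.label in MALIGNANT_STAGES]
    present = {s.label for s in staged}
    missing = set(MALIGNANT_STAGES) - present
    if missing:
        raise ValueError(f"stages missing from one-vs-one training data: {missing}")
    X = profiles_to_matrix([s.profile for s in staged])
    labels = np.array([int(s.label) for s in staged])
    if scaler is None:
        scaler = Standardizer.fit(X)
    Xs = scaler.transform(X)
    kinds = {k.kind for k in kernel_candidates}
    if len(kinds) != 1:
        raise ValueError("all kernel candidates of a group must share one kind")
    models: dict[tuple[StageLabel, StageLabel], BinarySVMModel] = {}
    diagnostics: dict = {"held_out_errors": {}, "epsilon_ok": {}}
    for j, (a, b) in enumerate(STAGE_PAIRS):
        mask = (labels == int(a)) | (labels == int(b))
        # +1 for the lower stage of the pair, -1 for the higher
        y = np.where(labels[mask] == int(a), 1.0, -1.0)
        model, err, ok = search_binary_svm(
            Xs[mask], y, c_grid, kernel_candidates, epsilon, seed + j
        )
        models[(a, b)] = model
        diagnostics["held_out_errors"][f"{a}-{b}"] = err
        diagnostics["epsilon_ok"][f"{a}-{b}"] = ok
    return OvOGroup(
        models=models, kernel_kind=kinds.pop(), scaler=scaler, diagnostics=diagnostics
    )


def votes_to_onehot(counts: np.ndarray) -> np.ndarray:
    """Majority vote over stages I-IV; ties go to the lowest tied stage.

    The conservative tie-break (never over-stage on a tie) is a fixed,
    documented convention.
    """
    counts = np.asarray(counts)
    onehot = np.zeros(4)
    onehot[int(np.argmax(counts))] = 1.0  # argmax takes the first = lowest stage
    return onehot


def ovo_vote_counts(group: OvOGroup, X: np.ndarray) -> np.ndarray:
    """(n, 4) vote counts; each of the six classifiers casts one vote per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = group.scaler.transform(X) if group.scaler is not None else X
    counts = np.zeros((len(Xs), 4))
    for (a, b), model in group.models.items():
        K = kernel_gram(model.kernel, Xs, model.sv_x)
        raw = K @ (model.alpha * model.sv_y) + model.b
        win_a = raw >= 0
        counts[win_a, int(a) - 1] += 1
        counts[~win_a, int(b) - 1] += 1
    return counts


def ovo_onehot_matrix(group: OvOGroup, X: np.ndarray) -> np.ndarray:
    counts = ovo_vote_counts(group, X)
    out = np.zeros_like(counts)
    out[np.arange(len(counts)), np.argmax(counts, axis=1)] = 1.0
    return out


def ovo_predict_onehot(group: OvOGroup, x: np.ndarray) -> np.ndarray:
    """Four-dimensional one-hot committee vote for a single input."""
    return ovo_onehot_matrix(group, np.asarray(x, dtype=float)[None, :])[0]
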