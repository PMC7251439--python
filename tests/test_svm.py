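import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from prostate_dss.cohort import generate_cohort
from prostate_dss.core import MALIGNANT_STAGES, StageLabel, profiles_to_matrix
from prostate_dss.svm import (
    STAGE_PAIRS,
    KernelSpec,
    dual_objective,
    expand_kernel_grid,
    kernel_eval,
    kernel_gram,
    ovo_predict_onehot,
    ovo_vote_counts,
    svm_decision,
    train_binary_svm,
    train_ovo_group,
    votes_to_onehot,
)

# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def _pad6(*coords):
    v = np.zeros(6)
    v[: len(coords)] = coords
    return v


@pytest.mark.parametrize(
    "spec,x,z,expected",
    [
        (KernelSpec("linear"), _pad6(1, 2), _pad6(3, 4), 11.0),
        (KernelSpec("polynomial", degree=2), _pad6(1, 1), _pad6(1, 1), 4.0),
        (KernelSpec("gauss", sigma=0.7), _pad6(1, 2, 3), _pad6(1, 2, 3), 1.0),
        (KernelSpec("laplace", sigma=1.0), _pad6(1), _pad6(1), 1.0),
        (KernelSpec("sigmoid", beta=1.0, theta=0.0), _pad6(0), _pad6(0), 0.0),
    ],
)
def test_kernel_eval_closed_forms(spec, x, z, expected):
    assert kernel_eval(spec, x, z) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("kind", ["linear", "polynomial", "gauss", "laplace", "sigmoid"])
def test_kernel_symmetry_and_range(kind):
    spec = {
        "linear": KernelSpec("linear"),
        "polynomial": KernelSpec("polynomial", degree=3),
        "gauss": KernelSpec("gauss", sigma=1.3),
        "laplace": KernelSpec("laplace", sigma=0.8),
        "sigmoid": KernelSpec("sigmoid", beta=0.5, theta=-1.0),
    }[kind]
    rng = np.random.default_rng(0)
    X = rng.standard_normal((12, 6))
    K = kernel_gram(spec, X, X)
    assert np.allclose(K, K.T, atol=1e-12)
    if kind in ("gauss", "laplace"):
        assert np.all(K > 0) and np.all(K <= 1 + 1e-12)


@pytest.mark.parametrize("kind", ["linear", "gauss"])
def test_mercer_kernels_are_positive_semidefinite(kind):
    spec = KernelSpec(kind) if kind == "linear" else KernelSpec("gauss", sigma=1.0)
    rng = np.random.default_rng(3)
    K = kernel_gram(spec, rng.standard_normal((15, 6)), rng.standard_normal((15, 6)))
    # symmetric gram on one point set
    X = rng.standard_normal((15, 6))
    K = kernel_gram(spec, X, X)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


def test_kernel_spec_requires_its_parameters():
    with pytest.raises(ValueError):
        KernelSpec("gauss")
    with pytest.raises(ValueError):
        KernelSpec("polynomial", degree=0)
    with pytest.raises(ValueError):
        KernelSpec("unknown")
    with pytest.raises(ValueError):
        kernel_eval(KernelSpec("linear"), np.zeros(6), np.zeros(5))


# --------------------------------------------------------------------------
# binary SVM
# --------------------------------------------------------------------------

def test_two_point_problem_separates_at_the_origin():
    X = np.array([_pad6(-1.0), _pad6(1.0)])
    y = np.array([-1.0, 1.0])
    model = train_binary_svm(X, y, C=10.0, kernel=KernelSpec("linear"))
    raw_mid, _ = svm_decision(model, _pad6(0.0))
    assert raw_mid == pytest.approx(0.0, abs=1e-6)
    _, sign = svm_decision(model, _pad6(2.0))
    assert sign == 1
    for xi, yi in zip(X, y):
        assert svm_decision(model, xi)[1] == yi


def test_training_rejects_single_class_and_bad_C():
    X = np.zeros((3, 6))
    with pytest.raises(ValueError):
        train_binary_svm(X, np.ones(3), 1.0, KernelSpec("linear"))
    with pytest.raises(ValueError):
        train_binary_svm(X, np.array([1.0, -1.0, 1.0]), -1.0, KernelSpec("linear"))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_dual_constraints_hold_on_random_toy_sets(seed):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((6, 6)) - 1.0, rng.standard_normal((6, 6)) + 1.0]
    )
    y = np.repeat([-1.0, 1.0], 6)
    C = float(rng.choice([0.5, 1.0, 10.0]))
    kernel = KernelSpec("gauss", sigma=1.0) if seed % 2 else KernelSpec("linear")
    model = train_binary_svm(X, y, C, kernel)
    assert np.all(model.alpha >= -1e-8)
    assert np.all(model.alpha <= C + 1e-8)
    assert abs(np.sum(model.alpha * model.sv_y)) <= 1e-6


def _slsqp_dual(K, y, C):
    """Independent brute-force solution of the soft-margin dual QP."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        x0=np.full(n, 0.5 * min(C, 1.0)),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success
    alpha = res.x
    # offset from the KKT conditions at free support vectors
    free = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    fx = K @ (alpha * y)
    b = float(np.mean(y[free] - fx[free])) if free.any() else float(np.mean(y - fx))
    return -res.fun, alpha, b


@pytest.mark.parametrize("kind", ["linear", "gauss"])
def test_dual_objective_matches_brute_force_qp(kind):
    rng = np.random.default_rng(11)
    X = np.vstack(
        [rng.standard_normal((4, 6)) - 1.5, rng.standard_normal((4, 6)) + 1.5]
    )
    y = np.repeat([-1.0, 1.0], 4)
    kernel = KernelSpec("linear") if kind == "linear" else KernelSpec("gauss", sigma=1.0)
    C = 10.0
    model = train_binary_svm(X, y, C, kernel)
    K = kernel_gram(kernel, X, X)
    obj_oracle, alpha_oracle, b_oracle = _slsqp_dual(K, y, C)
    assert dual_objective(model) == pytest.approx(obj_oracle, rel=1e-4)
    # decision signs agree on the training points
    fx_oracle = np.sign(K @ (alpha_oracle * y) + b_oracle)
    for xi, fo in zip(X, fx_oracle):
        assert svm_decision(model, xi)[1] == fo


# --------------------------------------------------------------------------
# one-vs-one committee
# --------------------------------------------------------------------------

def test_votes_to_onehot_matches_exhaustive_enumeration():
    """Every outcome of the 6 pairwise duels maps to the lowest tied maximum."""
    for wins in itertools.product([0, 1], repeat=6):
        counts = np.zeros(4)
        for (a, b), w in zip(STAGE_PAIRS, wins):
            counts[int(a) - 1 if w else int(b) - 1] += 1
        assert counts.sum() == 6
        onehot = votes_to_onehot(counts)
        # independent re-derivation of the rule
        best = min(i for i in range(4) if counts[i] == counts.max())
        expected = np.zeros(4)
        expected[best] = 1
        assert np.array_equal(onehot, expected)


def test_tied_vote_goes_to_the_lowest_stage():
    assert np.array_equal(votes_to_onehot([2, 2, 2, 0]), [1, 0, 0, 0])


@pytest.fixture(scope="module")
def trained_group(clean_spec_module):
    return train_ovo_group(
        [s for s in clean_spec_module if s.label in MALIGNANT_STAGES],
        c_grid=(1.0, 10.0),
        kernel_candidates=expand_kernel_grid("gauss", sigma_grid=(1.0, 2.0)),
        epsilon=0.1,
        seed=0,
    )


@pytest.fixture(scope="module")
def clean_spec_module():
    from prostate_dss.cohort import CohortSpec

    spec = CohortSpec(
        n_per_class={s: 40 for s in StageLabel},
        severity_sd=0.05,
        noise_sd=0.01,
        seed=9,
    )
    return generate_cohort(spec)


def test_group_has_six_pairwise_models(trained_group):
    assert len(trained_group.models) == 6
    assert set(trained_group.models) == set(STAGE_PAIRS)


def test_group_accuracy_on_well_separated_clusters(trained_group, clean_spec_module):
    staged = [s for s in clean_spec_module if s.label in MALIGNANT_STAGES]
    X = profiles_to_matrix([s.profile for s in staged])
    onehots = np.array([ovo_predict_onehot(trained_group, x) for x in X])
    pred = onehots.argmax(axis=1) + 1
    truth = np.array([int(s.label) for s in staged])
    assert np.mean(pred == truth) >= 0.95


def test_vote_counts_sum_to_six_and_onehot_is_valid(trained_group):
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 100, size=(20, 6))
    counts = ovo_vote_counts(trained_group, X)
    assert np.all(counts.sum(axis=1) == 6)
    for x in X:
        onehot = ovo_predict_onehot(trained_group, x)
        assert onehot.sum() == 1 and set(np.unique(onehot)) <= {0.0, 1.0}


def test_pairwise_model_never_sees_other_stages(clean_spec_module):
    staged = [s for s in clean_spec_module if s.label in MALIGNANT_STAGES]
    group = train_ovo_group(
        staged,
        c_grid=(1.0,),
        kernel_candidates=[KernelSpec("linear")],
        epsilon=0.5,
        seed=0,
    )
    model = group.models[(StageLabel.I, StageLabel.II)]
    n_pair = sum(s.label in (StageLabel.I, StageLabel.II) for s in staged)
    assert len(model.sv_x) <= n_pair


def test_ovo_requires_all_four_stages(clean_spec_module):
    partial = [s for s in clean_spec_module if s.label in (StageLabel.I, StageLabel.II)]
    with pytest.raises(ValueError, match="missing"):
        train_ovo_group(partial, (1.0,), [KernelSpec("linear")], 0.1, seed=0)
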