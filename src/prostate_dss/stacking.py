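"""Stacked feature construction and the exponential linear regression (ELR).

The nine base learners each emit a four-dimensional stage vector; their
concatenation is the 36-dimensional stacked feature

    z = [SVM group 1..3 one-hots | MLP 1..3 scores | RBF 1..3 scores].

The secondary learner is an affine map read through an exponential:
ln EM = w.z + b is fitted by least squares against the manually assigned
supervising values (3, 4, 5, 6 for stages I-IV), and the malignancy score
is EM = exp(ln EM) — linear fitting on the log scale, exponential growth of
the reported score.  A raw-scale variant (targets fitted as EM directly) is
available via ``target_scale="raw"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MALIGNANT_STAGES, StageLabel
from .nets import MLPModel, RBFModel
from .svm import OvOGroup, ovo_onehot_matrix

STACKED_DIM = 36  # 9 learners x 4 stage coordinates

_EM_FLOOR = 1e-9  # raw-scale guard: EM stays positive


def stack_matrix(
    X: np.ndarray,
    groups: list[OvOGroup],
    mlps: list[MLPModel],
    rbfs: list[RBFModel],
) -> np.ndarray:
    """(n, 36) stacked features for raw marker rows X."""
    if len(groups) != 3 or len(mlps) != 3 or len(rbfs) != 3:
        raise ValueError("stacking expects 3 SVM groups, 3 MLPs and 3 RBF networks")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    blocks = [ovo_onehot_matrix(g, X) for g in groups]
    blocks += [m.predict_scores(X) for m in mlps]
    blocks += [r.predict_scores(X) for r in rbfs]
    return np.hstack(blocks)


def stack_features(
    x: np.ndarray,
    groups: list[OvOGroup],
    mlps: list[MLPModel],
    rbfs: list[RBFModel],
) -> np.ndarray:
    """36-dimensional stacked feature for a single profile vector."""
    return stack_matrix(np.asarray(x, dtype=float)[None, :], groups, mlps, rbfs)[0]


@dataclass(frozen=True)
class EMScore:
    """Continuous malignancy score EM = exp(lnEM)."""

    em: float
    ln_em: float


@dataclass
class ELRModel:
    w: np.ndarray  # (36,)
    b: float
    target_scale: str = "ln"
    training_loss: float = 0.0
    diagnostics: dict = field(default_factory=dict)


def fit_elr(
    Z: np.ndarray,
    stages: list[StageLabel] | np.ndarray,
    supervising_values: dict[StageLabel, float],
    target_scale: str = "ln",
) -> ELRModel:
    """Least-squares fit of the meta-learner on stacked malignant features.

    Minimizes the mean squared loss between the model's evaluation and the
    supervising value of each sample's stage.  The solution is the minimum-
    norm least-squares solution (the one-hot blocks make the design rank
    deficient, which lstsq handles exactly).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    stages = [StageLabel(int(s)) for s in np.asarray(stages).ravel()]
    if any(s not in MALIGNANT_STAGES for s in stages):
        raise ValueError("fit_elr accepts malignant stages I-IV only")
    missing = {s for s in stages if s not in supervising_values}
    if missing:
        raise ValueError(f"no supervising value for stages: {missing}")
    if target_scale not in ("ln", "raw"):
        raise ValueError("target_scale must be 'ln' or 'raw'")
    t = np.array([supervising_values[s] for s in stages], dtype=float)
    if len(Z) >= 2 and np.allclose(Z, Z[0]) and not np.allclose(t, t[0]):
        warnings.warn(
            "all stacked features identical but targets differ: "
            "irreducible training loss",
            stacklevel=2,
        )
    design = np.hstack([Z, np.ones((len(Z), 1))])
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)
    pred = design @ coef
    loss = float(np.mean((pred - t) ** 2))
    return ELRModel(
        w=coef[:-1],
        b=float(coef[-1]),
        target_scale=target_scale,
        training_loss=loss,
        diagnostics={"n_train": int(len(Z))},
    )


def elr_lnem(model: ELRModel, Z: np.ndarray) -> np.ndarray:
    """Vectorized lnEM for stacked feature rows."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    raw = Z @ model.w + model.b
    if model.target_scale == "ln":
        return raw
    return np.log(np.maximum(raw, _EM_FLOOR))


def predict_em(model: ELRModel, z: np.ndarray) -> EMScore:
    """EM and lnEM for one stacked feature; EM is always positive."""
    ln_em = float(elr_lnem(model, np.asarray(z, dtype=float)[None, :])[0])
    return EMScore(em=float(np.exp(ln_em)), ln_em=ln_em)
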