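"""End-to-end decision pipeline.

Flow per patient: a benign-vs-malignant SVM gate routes the record; benign
cases get a follow-up-examination recommendation, malignant cases go through
the stacked ensemble to an EM score, a stage read off the lnEM thresholds,
and a stage-specific treatment recommendation.  Re-testing after therapy is
tracked by comparing EM scores: a large relative drop means the plan works
(maintain), a small change means it does not (change).

Training (``train_system``) follows a fixed protocol: one stratified 80/20
split of the cohort, shared standardization fitted on the training split,
the gate trained on benign (+1) vs malignant (-1), the nine base learners
trained on the malignant training samples only, and the ELR meta-learner
fitted on their stacked outputs.  All randomness derives from the config
seed, so a seed determines the trained system bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .core import (
    MALIGNANT_STAGES,
    LabeledSample,
    MarkerProfile,
    StageLabel,
    Standardizer,
    SystemConfig,
    profile_to_vector,
    profiles_to_matrix,
)
from .nets import MLPModel, RBFModel, train_mlp, train_rbf
from .stacking import ELRModel, EMScore, elr_lnem, fit_elr, predict_em, stack_matrix
from .svm import (
    BinarySVMModel,
    OvOGroup,
    decision_values,
    expand_kernel_grid,
    search_binary_svm,
    train_ovo_group,
)

#: Default stage -> recommended modality lookup. The modality vocabulary is
#: fixed (chemotherapy, radiotherapy, excision, drug method, hospital charge,
#: next examination); the mapping itself is an editable convention.
DEFAULT_TREATMENT_TABLE: dict[StageLabel, tuple[str, ...]] = {
    StageLabel.BENIGN: ("next_examination",),
    StageLabel.I: ("excision",),
    StageLabel.II: ("excision", "radiotherapy"),
    StageLabel.III: ("radiotherapy", "chemotherapy"),
    StageLabel.IV: ("chemotherapy", "drug method", "hospital charge"),
}

ADVISORY = "auxiliary suggestion, not a prescription"


@dataclass(frozen=True)
class TreatmentPlan:
    modalities: tuple[str, ...]
    advisory: str = ADVISORY


@dataclass(frozen=True)
class Diagnosis:
    verdict: StageLabel
    em: EMScore | None
    recommendation: TreatmentPlan
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TreatmentAssessment:
    em_before: float
    em_after: float
    relative_drop: float
    verdict: str  # "maintain" | "change"
    flags: tuple[str, ...] = ()


@dataclass
class TrainingReport:
    """Per-learner held-out errors and epsilon flags, plus the split bookkeeping."""

    learner_errors: dict[str, float] = field(default_factory=dict)
    epsilon_ok: dict[str, bool] = field(default_factory=dict)
    train_indices: list[int] = field(default_factory=list)
    test_indices: list[int] = field(default_factory=list)


@dataclass
class TrainedSystem:
    scaler: Standardizer
    gate: BinarySVMModel
    groups: list[OvOGroup]
    mlps: list[MLPModel]
    rbfs: list[RBFModel]
    elr: ELRModel
    config: SystemConfig
    report: TrainingReport = field(default_factory=TrainingReport)
    audit_log: list[dict] = field(default_factory=list)


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def train_system(cohort: list[LabeledSample], config: SystemConfig) -> TrainedSystem:
    """Train gate, base learners and meta-learner on one stratified split."""
    labels = [s.label for s in cohort]
    if any(l is None for l in labels):
        raise ValueError("every training sample needs a stage label")
    present = set(labels)
    needed = {StageLabel.BENIGN, *MALIGNANT_STAGES}
    if not needed <= present:
        raise ValueError(f"cohort is missing classes: {needed - present}")

    seeds = _derived_seeds(config.seed, 10)
    y_all = np.array([int(l) for l in labels])
    idx_train, idx_test = train_test_split(
        np.arange(len(cohort)),
        train_size=config.split_train,
        random_state=seeds[0],
        stratify=y_all,
    )
    idx_train = np.sort(idx_train)
    idx_test = np.sort(idx_test)
    train = [cohort[i] for i in idx_train]

    X_train = profiles_to_matrix([s.profile for s in train])
    y_train = y_all[idx_train]
    scaler = Standardizer.fit(X_train)
    Xs_train = scaler.transform(X_train)

    report = TrainingReport(
        train_indices=[int(i) for i in idx_train],
        test_indices=[int(i) for i in idx_test],
    )

    # Gate: benign labeled +1, malignant labeled -1; kernel kind searched too.
    gate_candidates = []
    for kind in ("linear", "polynomial", "gauss"):
        gate_candidates += expand_kernel_grid(
            kind,
            sigma_grid=config.gauss_sigma_grid,
            degree_grid=config.poly_degree_grid,
        )
    y_gate = np.where(y_train == int(StageLabel.BENIGN), 1.0, -1.0)
    gate, err, ok = search_binary_svm(
        Xs_train, y_gate, config.c_grid, gate_candidates, config.epsilon, seeds[1]
    )
    gate.scaler = scaler
    report.learner_errors["gate"] = err
    report.epsilon_ok["gate"] = ok

    malignant = [s for s in train if s.label in MALIGNANT_STAGES]
    X_mal = profiles_to_matrix([s.profile for s in malignant])
    stages_mal = np.array([int(s.label) for s in malignant])

    groups: list[OvOGroup] = []
    for g, kind in enumerate(config.group_kernels):
        candidates = expand_kernel_grid(
            kind,
            sigma_grid=config.gauss_sigma_grid,
            degree_grid=config.poly_degree_grid,
            sigmoid_beta=config.sigmoid_beta,
            sigmoid_theta=config.sigmoid_theta,
        )
        group = train_ovo_group(
            malignant,
            config.c_grid,
            candidates,
            config.epsilon,
            seeds[2 + g],
            scaler=scaler,
        )
        groups.append(group)
        errs = group.diagnostics["held_out_errors"]
        report.learner_errors[f"svm_group_{kind}"] = float(np.mean(list(errs.values())))
        report.epsilon_ok[f"svm_group_{kind}"] = all(
            group.diagnostics["epsilon_ok"].values()
        )

    mlps: list[MLPModel] = []
    for m, arch in enumerate(config.mlp_architectures):
        mlp = train_mlp(
            tuple(arch),
            X_mal,
            stages_mal,
            config.epsilon,
            seeds[5 + m],
            learning_rate=config.mlp_learning_rate,
            max_epochs=config.mlp_max_epochs,
            scaler=scaler,
        )
        mlps.append(mlp)
        name = "mlp_" + "-".join(map(str, arch))
        report.learner_errors[name] = mlp.diagnostics["held_out_error"]
        report.epsilon_ok[name] = mlp.diagnostics["epsilon_ok"]

    rbfs: list[RBFModel] = []
    for r, k in enumerate(config.rbf_hidden_units):
        rbf = train_rbf(
            k,
            X_mal,
            stages_mal,
            config.epsilon,
            (seeds[8] + r) % (2**31 - 1),
            ridge=config.rbf_ridge,
            scaler=scaler,
        )
        rbfs.append(rbf)
        name = f"rbf_{k}"
        report.learner_errors[name] = rbf.diagnostics["held_out_error"]
        report.epsilon_ok[name] = rbf.diagnostics["epsilon_ok"]

    Z = stack_matrix(X_mal, groups, mlps, rbfs)
    elr = fit_elr(
        Z,
        stages_mal,
        config.supervising_values,
        target_scale=config.elr_target_scale,
    )

    return TrainedSystem(
        scaler=scaler,
        gate=gate,
        groups=groups,
        mlps=mlps,
        rbfs=rbfs,
        elr=elr,
        config=config,
        report=report,
    )


def stage_from_lnem(
    ln_em: float, thresholds: tuple[float, float, float, float]
) -> tuple[StageLabel, tuple[str, ...]]:
    """Half-open lnEM binning: [t0,t1) I, [t1,t2) II, [t2,t3) III, >= t3 IV.

    Values below t0 still map to stage I (the gate, not the score, owns the
    benign call) but carry a "below stage-I range" flag.
    """
    if not math.isfinite(ln_em):
        raise ValueError("ln_em must be finite")
    t0, t1, t2, t3 = thresholds
    if ln_em < t0:
        return StageLabel.I, ("below stage-I range",)
    if ln_em < t1:
        return StageLabel.I, ()
    if ln_em < t2:
        return StageLabel.II, ()
    if ln_em < t3:
        return StageLabel.III, ()
    return StageLabel.IV, ()


def recommend_treatment(
    stage: StageLabel, table: dict[StageLabel, tuple[str, ...]] | None = None
) -> TreatmentPlan:
    """Deterministic stage -> modality lookup with the fixed advisory."""
    table = DEFAULT_TREATMENT_TABLE if table is None else table
    return TreatmentPlan(modalities=tuple(table[stage]))


def em_scores(system: TrainedSystem, X: np.ndarray) -> np.ndarray:
    """lnEM for raw marker rows through the full stacked ensemble (no gate)."""
    Z = stack_matrix(np.atleast_2d(np.asarray(X, dtype=float)),
                     system.groups, system.mlps, system.rbfs)
    return elr_lnem(system.elr, Z)


def diagnose(system: TrainedSystem, profile: MarkerProfile) -> Diagnosis:
    """Gate the record, then stage malignant cases by their EM value."""
    x = profile_to_vector(profile)
    _, sign = _gate_sign(system, x)
    if sign > 0:
        return Diagnosis(
            verdict=StageLabel.BENIGN,
            em=None,
            recommendation=recommend_treatment(StageLabel.BENIGN),
        )
    ln_em = float(em_scores(system, x[None, :])[0])
    em = EMScore(em=float(np.exp(ln_em)), ln_em=ln_em)
    stage, flags = stage_from_lnem(ln_em, system.config.stage_thresholds)
    return Diagnosis(
        verdict=stage, em=em, recommendation=recommend_treatment(stage), flags=flags
    )


def _gate_sign(system: TrainedSystem, x: np.ndarray) -> tuple[float, int]:
    raw = float(decision_values(system.gate, x[None, :])[0])
    return raw, (1 if raw >= 0 else -1)


def assess_treatment(
    system: TrainedSystem,
    profile_before: MarkerProfile,
    profile_after: MarkerProfile,
    delta: float | None = None,
    patient_id: str | None = None,
) -> TreatmentAssessment:
    """Compare EM before/after therapy; maintain the plan iff the relative
    drop reaches delta ("decreases greatly"), otherwise change it.

    EM is computed through the stacked ensemble for both profiles (the gate
    is bypassed: the question is the malignancy trend, not a re-diagnosis).
    Every call appends exactly one record to the system's audit log.
    """
    if delta is None:
        delta = system.config.treatment_delta
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    ln_before, ln_after = em_scores(
        system,
        np.vstack([profile_to_vector(profile_before), profile_to_vector(profile_after)]),
    )
    em_before = float(np.exp(ln_before))
    em_after = float(np.exp(ln_after))
    drop = (em_before - em_after) / em_before
    verdict = "maintain" if drop >= delta else "change"
    flags = ("deterioration",) if drop < 0 else ()
    assessment = TreatmentAssessment(
        em_before=em_before,
        em_after=em_after,
        relative_drop=float(drop),
        verdict=verdict,
        flags=flags,
    )
    system.audit_log.append(
        {
            "patient_id": patient_id,
            "em_before": em_before,
            "em_after": em_after,
            "relative_drop": float(drop),
            "verdict": verdict,
        }
    )
    return assessment
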