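"""Core domain types: marker profiles, normal ranges, stage labels, system configuration.

Six serum markers drive every decision in the system: prostate-specific
antigen (PSA), prostate-specific membrane antigen (PSMA), total PSA (tPSA),
red blood cell level (RBC), hemoglobin (HB) and prostatic acid phosphatase
(PAP).  A patient record is a fixed-order six-vector over these markers;
stages form the total order BENIGN < I < II < III < IV.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical feature order. Every vector in the system follows it.
MARKER_NAMES: tuple[str, ...] = ("psa", "psma", "tpsa", "rbc", "hb", "pap")

#: Units as printed in the clinical reference table (RBC's unit is kept
#: verbatim even though g/100 mL reads like a hemoglobin unit).
MARKER_UNITS: dict[str, str] = {
    "psa": "ng/mL",
    "psma": "ng/mL",
    "tpsa": "ug/L",
    "rbc": "g/100 mL",
    "hb": "g/L",
    "pap": "U/L",
}


class StageLabel(enum.IntEnum):
    """Ordinal diagnosis: benign, then clinical stages I (earliest) to IV."""

    BENIGN = 0
    I = 1
    II = 2
    III = 3
    IV = 4

    @classmethod
    def from_string(cls, s: str) -> "StageLabel":
        key = s.strip().upper()
        if key in ("BENIGN", "B", "0"):
            return cls.BENIGN
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown stage label: {s!r}") from None

    def __str__(self) -> str:  # CSV-friendly form
        return "benign" if self is StageLabel.BENIGN else self.name


#: The four malignant stages in increasing order of severity.
MALIGNANT_STAGES: tuple[StageLabel, ...] = (
    StageLabel.I,
    StageLabel.II,
    StageLabel.III,
    StageLabel.IV,
)


@dataclass(frozen=True)
class MarkerProfile:
    """One patient's six tumor-marker levels (fixed units, see MARKER_UNITS)."""

    psa: float
    psma: float
    tpsa: float
    rbc: float
    hb: float
    pap: float

    def __post_init__(self) -> None:
        for name in MARKER_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"marker {name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"marker {name} is negative: {v!r}")


def profile_to_vector(profile: MarkerProfile) -> np.ndarray:
    """Six-vector in canonical order (psa, psma, tpsa, rbc, hb, pap)."""
    return np.array([getattr(profile, m) for m in MARKER_NAMES], dtype=float)


def vector_to_profile(x: np.ndarray) -> MarkerProfile:
    x = np.asarray(x, dtype=float)
    if x.shape != (len(MARKER_NAMES),):
        raise ValueError(f"expected a 6-vector, got shape {x.shape}")
    return MarkerProfile(**{m: float(v) for m, v in zip(MARKER_NAMES, x)})


def profiles_to_matrix(profiles: list[MarkerProfile]) -> np.ndarray:
    return np.array([profile_to_vector(p) for p in profiles], dtype=float)


@dataclass(frozen=True)
class MarkerRange:
    """Closed normal interval [low, high] in the marker's own unit."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"need low < high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class NormalRanges:
    """Per-marker normal reference intervals.

    Defaults are the printed clinical reference values, adopted verbatim:
    PSA 0-4.0 ng/mL, tPSA 4-20 ug/L, HB 120-165 g/L, RBC 12-15 g/100 mL,
    PAP 0-9 U/L, PSMA 0-4 ng/mL.  (The RBC unit and tPSA's floor above
    PSA's ceiling look clinically odd but are kept as printed; override
    via configuration if needed.)
    """

    psa: MarkerRange = MarkerRange(0.0, 4.0)
    psma: MarkerRange = MarkerRange(0.0, 4.0)
    tpsa: MarkerRange = MarkerRange(4.0, 20.0)
    rbc: MarkerRange = MarkerRange(12.0, 15.0)
    hb: MarkerRange = MarkerRange(120.0, 165.0)
    pap: MarkerRange = MarkerRange(0.0, 9.0)

    def for_marker(self, name: str) -> MarkerRange:
        return getattr(self, name)


DEFAULT_NORMAL_RANGES = NormalRanges()


@dataclass(frozen=True)
class MarkerFlag:
    """Range-check verdict for one marker.

    ``status`` is "below", "in" or "above"; ``fold_of_upper`` is
    value/upper-bound when above range (e.g. 10.0 for PAP at 90 U/L
    against a 9 U/L ceiling), else None.
    """

    status: str
    fold_of_upper: float | None = None


def validate_profile(
    profile: MarkerProfile, ranges: NormalRanges = DEFAULT_NORMAL_RANGES
) -> dict[str, MarkerFlag]:
    """Flag each marker as below / in / above its closed normal interval.

    Pure report; the profile is not mutated. Non-finite or negative values
    are rejected at MarkerProfile construction, naming the marker.
    """
    report: dict[str, MarkerFlag] = {}
    for name in MARKER_NAMES:
        v = getattr(profile, name)
        r = ranges.for_marker(name)
        if v < r.low:
            report[name] = MarkerFlag("below")
        elif v > r.high:
            report[name] = MarkerFlag("above", fold_of_upper=v / r.high)
        else:
            report[name] = MarkerFlag("in")
    return report


@dataclass
class LabeledSample:
    """A patient record: marker profile, optional stage label and covariates."""

    profile: MarkerProfile
    label: StageLabel | None = None
    diet: str | None = None  # "high_fat" | "normal"
    family_history: int | None = None  # 1 = cancer case among family members
    year: int | None = None
    patient_id: str | None = None
    #: Generator-side latent severity on the lnEM scale (diagnostic only;
    #: absent for real records).
    latent_severity: float | None = None


class Standardizer:
    """Train-split mean/scale standardization shared by every learner.

    Markers span three orders of magnitude; kernels and gradient descent
    both need comparable coordinates.
    """

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant column guard
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


#: Regression targets ("supervising values") on the lnEM scale per stage.
DEFAULT_SUPERVISING_VALUES: dict[StageLabel, float] = {
    StageLabel.I: 3.0,
    StageLabel.II: 4.0,
    StageLabel.III: 5.0,
    StageLabel.IV: 6.0,
}

#: lnEM stage boundaries: <2.7 below stage-I range, [2.7,3.6) I,
#: [3.6,4.5) II, [4.5,5.3) III, >=5.3 IV.
DEFAULT_STAGE_THRESHOLDS: tuple[float, float, float, float] = (2.7, 3.6, 4.5, 5.3)

DEFAULT_MLP_ARCHITECTURES: tuple[tuple[int, ...], ...] = (
    (6, 9, 7, 4),
    (6, 10, 7, 5, 4),
    (6, 7, 5, 4),
)

DEFAULT_RBF_HIDDEN_UNITS: tuple[int, int, int] = (10, 14, 16)

#: Kernel kinds that differentiate the three one-vs-one SVM groups.
DEFAULT_GROUP_KERNELS: tuple[str, str, str] = ("linear", "polynomial", "gauss")


@dataclass
class SystemConfig:
    """All tunable knobs of the decision system with their defaults.

    epsilon            target held-out error fraction for each base learner
    split_train        training fraction of the stratified split (rest is test)
    supervising_values lnEM regression target per malignant stage
    stage_thresholds   ordered lnEM boundaries for staging
    group_kernels      kernel kind of each of the three one-vs-one SVM groups
    c_grid             soft-margin penalty grid searched per binary SVM
    gauss_sigma_grid / poly_degree_grid / sigmoid_beta / sigmoid_theta
                       kernel-parameter grids/values (on standardized inputs)
    mlp_architectures  layer-size tuples, input 6 and output 4 fixed
    rbf_hidden_units   hidden-layer widths of the three RBF networks
    mlp_learning_rate / mlp_max_epochs   plain full-batch gradient descent
    rbf_ridge          ridge used for the RBF output-weight least squares
    elr_target_scale   "ln": supervising values are lnEM targets (default);
                       "raw": fit them on the EM scale directly
    treatment_delta    relative EM drop counted as "decreases greatly"
    seed               master seed; all randomness derives from it
    """

    epsilon: float = 0.1
    split_train: float = 0.8
    supervising_values: dict[StageLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERVISING_VALUES)
    )
    stage_thresholds: tuple[float, float, float, float] = DEFAULT_STAGE_THRESHOLDS
    group_kernels: tuple[str, str, str] = DEFAULT_GROUP_KERNELS
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gauss_sigma_grid: tuple[float, ...] = (1.0, 2.0)
    poly_degree_grid: tuple[int, ...] = (2, 3)
    sigmoid_beta: float = 0.5
    sigmoid_theta: float = -1.0
    mlp_architectures: tuple[tuple[int, ...], ...] = DEFAULT_MLP_ARCHITECTURES
    rbf_hidden_units: tuple[int, ...] = DEFAULT_RBF_HIDDEN_UNITS
    mlp_learning_rate: float = 0.01
    mlp_max_epochs: int = 2000
    rbf_ridge: float = 1e-6
    elr_target_scale: str = "ln"
    treatment_delta: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_train < 1.0:
            raise ValueError("split_train must be in (0, 1)")
        th = self.stage_thresholds
        if len(th) != 4 or any(a >= b for a, b in zip(th, th[1:])):
            raise ValueError("stage_thresholds must be 4 strictly increasing values")
        if self.elr_target_scale not in ("ln", "raw"):
            raise ValueError("elr_target_scale must be 'ln' or 'raw'")
        if len(set(self.group_kernels)) != len(self.group_kernels):
            raise ValueError("SVM group kernel kinds must be pairwise distinct")
        for arch in self.mlp_architectures:
            if arch[0] != 6 or arch[-1] != 4:
                raise ValueError(f"MLP architecture must be 6-...-4, got {arch}")
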