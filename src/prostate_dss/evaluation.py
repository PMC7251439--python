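"""Evaluation analyses: EM calibration, learning curves, covariate contrasts.

These reproduce, on synthetic cohorts, the three desk-scale analyses the
system supports: how tightly held-out lnEM clusters around each stage's
supervising value (the calibration table), how test accuracy grows with
training-set size (the learning curve), and how covariates such as high-fat
diet or family history shift the EM score (group contrasts with bootstrap
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .core import (
    MALIGNANT_STAGES,
    LabeledSample,
    StageLabel,
    SystemConfig,
    profiles_to_matrix,
)
from .pipeline import TrainedSystem, diagnose, em_scores, train_system


def em_calibration_table(
    system: TrainedSystem, samples: list[LabeledSample]
) -> pd.DataFrame:
    """Per-stage lnEM statistics on labeled malignant samples.

    Columns: n, lnem_min/mean/max, and quantiles of the absolute deviation
    |lnEM - supervising value| (median, 90th percentile, max).
    """
    staged = [s for s in samples if s.label in MALIGNANT_STAGES]
    present = {s.label for s in staged}
    missing = set(MALIGNANT_STAGES) - present
    if missing:
        raise ValueError(f"stages absent from the evaluation samples: {missing}")
    X = profiles_to_matrix([s.profile for s in staged])
    ln = em_scores(system, X)
    labels = np.array([int(s.label) for s in staged])
    sup = system.config.supervising_values
    rows = []
    for stage in MALIGNANT_STAGES:
        mask = labels == int(stage)
        v = ln[mask]
        dev = np.abs(v - sup[stage])
        rows.append(
            {
                "stage": str(stage),
                "n": int(mask.sum()),
                "lnem_min": float(v.min()),
                "lnem_mean": float(v.mean()),
                "lnem_max": float(v.max()),
                "dev_median": float(np.quantile(dev, 0.5)),
                "dev_p90": float(np.quantile(dev, 0.9)),
                "dev_max": float(dev.max()),
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def five_class_accuracy(system: TrainedSystem, samples: list[LabeledSample]) -> float:
    """Fraction of samples whose diagnosed verdict (benign or EM-derived
    stage) matches the true label."""
    hits = sum(diagnose(system, s.profile).verdict == s.label for s in samples)
    return hits / len(samples)


@dataclass
class LearningCurve:
    sizes: list[int]  # total cohort sizes (5 balanced classes)
    accuracies: np.ndarray  # (n_sizes, n_seeds)

    @property
    def means(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sds(self) -> np.ndarray:
        return self.accuracies.std(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "mean_accuracy": self.means,
                "sd_accuracy": self.sds,
                "n_seeds": self.accuracies.shape[1],
            }
        )


def learning_curve(
    spec: CohortSpec,
    sizes: list[int],
    seeds: list[int],
    config: SystemConfig,
    test_pool_per_class: int = 200,
) -> LearningCurve:
    """Test accuracy versus training-cohort size.

    For each (size, seed) a fresh balanced cohort of ``size`` samples is
    generated and a full system trained on it; accuracy is measured on one
    fixed held-out pool drawn from the same distribution.  Means over seeds
    are expected to be non-decreasing in size (tested, not enforced here).
    """
    if len(sizes) < 2 or len(seeds) < 1:
        raise ValueError("need at least 2 sizes and 1 seed")
    if any(s != sorted(sizes)[i] for i, s in enumerate(sizes)):
        raise ValueError("sizes must be increasing")
    if min(sizes) < 5 * 5:
        raise ValueError("smallest size cannot represent all five classes usefully")
    pool_spec = replace(
        spec,
        n_per_class={s: test_pool_per_class for s in StageLabel},
        seed=(spec.seed + 987_654) % (2**31 - 1),
    )
    pool = generate_cohort(pool_spec)
    acc = np.zeros((len(sizes), len(seeds)))
    for i, size in enumerate(sizes):
        per_class = size // 5
        for j, seed in enumerate(seeds):
            run_spec = replace(
                spec,
                n_per_class={s: per_class for s in StageLabel},
                seed=(spec.seed + 7919 * seed + size) % (2**31 - 1),
            )
            run_config = replace(config, seed=(config.seed + 104729 * seed + size) % (2**31 - 1))
            system = train_system(generate_cohort(run_spec), run_config)
            acc[i, j] = five_class_accuracy(system, pool)
    return LearningCurve(sizes=list(sizes), accuracies=acc)


@dataclass
class CovariateContrast:
    grouping: str
    group_names: tuple[str, str]
    means: tuple[float, float]  # mean EM (raw scale) per group
    intervals: tuple[tuple[float, float], tuple[float, float]]  # bootstrap 95% CIs
    positive_direction: bool  # first group's mean EM above the second's
    separated: bool  # bootstrap intervals do not overlap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_names,
                "mean_em": self.means,
                "ci_low": [iv[0] for iv in self.intervals],
                "ci_high": [iv[1] for iv in self.intervals],
            }
        )


def covariate_contrast(
    system: TrainedSystem,
    cohort: list[LabeledSample],
    grouping: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> CovariateContrast:
    """Mean EM per covariate group with bootstrap intervals.

    grouping is "diet" (high_fat vs normal) or "family_history" (1 vs 0).
    EM runs through the stacked ensemble for every sample.  A direction is
    only claimed (``separated``) when the 95% bootstrap intervals disjoin.
    """
    if grouping == "diet":
        in_first = [s.diet == "high_fat" for s in cohort]
        names = ("high_fat", "normal")
    elif grouping == "family_history":
        in_first = [bool(s.family_history) for s in cohort]
        names = ("family_history", "no_family_history")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    mask = np.array(in_first)
    if mask.all() or not mask.any():
        raise ValueError("both covariate groups must be non-empty")
    X = profiles_to_matrix([s.profile for s in cohort])
    em = np.exp(em_scores(system, X))
    rng = np.random.default_rng(seed)
    means, intervals = [], []
    for m in (mask, ~mask):
        vals = em[m]
        means.append(float(vals.mean()))
        boot = np.array(
            [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
        )
        intervals.append((float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975))))
    positive = means[0] > means[1]
    separated = intervals[0][0] > intervals[1][1] or intervals[1][0] > intervals[0][1]
    return CovariateContrast(
        grouping=grouping,
        group_names=names,
        means=(means[0], means[1]),
        intervals=(intervals[0], intervals[1]),
        positive_direction=positive,
        separated=separated,
    )
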