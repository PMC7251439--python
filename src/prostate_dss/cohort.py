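"""Synthetic tumor-marker cohort generator.

Real staged marker panels are not publicly available, so the package ships a
seeded generator built on a single scalar latent severity L (on the lnEM
scale).  L is drawn per patient around a stage-specific center — the same
values later used as regression targets (3, 4, 5, 6; benign center 2.0) —
and each marker grows exponentially with L:

    marker_j = upper_normal_j * exp(a_j * (L - L_benign)) * exp(noise_j)

with log-normal multiplicative noise.  Tumor antigens (PSA, PSMA, tPSA, PAP)
get positive gains so malignant values run several-fold to tens-fold above
the normal ceiling, while RBC and HB get small negative gains (a mild
anemia-like decline).  Benign patients therefore sit near the top of the
normal range ("elevated, but not by much"), stage-IV patients far above it.

High-fat diet and family history act as additive shifts on L, giving the
covariate-contrast analyses a known ground-truth direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_NORMAL_RANGES,
    MALIGNANT_STAGES,
    MARKER_NAMES,
    LabeledSample,
    MarkerProfile,
    NormalRanges,
    StageLabel,
)

_DEFAULT_SEVERITY = {
    StageLabel.BENIGN: 2.0,
    StageLabel.I: 3.0,
    StageLabel.II: 4.0,
    StageLabel.III: 5.0,
    StageLabel.IV: 6.0,
}

_DEFAULT_GAIN = {
    "psa": 0.6,
    "psma": 0.6,
    "tpsa": 0.6,
    "rbc": -0.05,
    "hb": -0.05,
    "pap": 0.6,
}


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    n_per_class        samples requested per stage (default 300 each)
    severity_location  latent severity center per stage (lnEM scale)
    severity_sd        within-stage spread of L
    marker_gain        per-marker exponential gain a_j
    noise_sd           sd of the per-marker multiplicative log-noise
    diet_shift         added to L for high-fat-diet patients
    inheritance_shift  added to L for patients with a family cancer case
    p_high_fat / p_family_history   covariate prevalence (default 0: the
                       plain cohort carries no covariate effects)
    seed               generator seed; identical specs give identical cohorts
    """

    n_per_class: dict[StageLabel, int] = field(
        default_factory=lambda: {s: 300 for s in StageLabel}
    )
    severity_location: dict[StageLabel, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEVERITY)
    )
    severity_sd: float = 0.35
    marker_gain: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GAIN))
    noise_sd: float = 0.15
    diet_shift: float = 0.6
    inheritance_shift: float = 0.5
    p_high_fat: float = 0.0
    p_family_history: float = 0.0
    year: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.severity_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("severity_sd and noise_sd must be > 0")
        locs = [
            self.severity_location[s]
            for s in StageLabel
            if s in self.severity_location
        ]
        if any(a >= b for a, b in zip(locs, locs[1:])):
            raise ValueError("severity_location must increase strictly with stage")


def sample_latent_severity(
    stage: StageLabel,
    spec: CohortSpec,
    rng: np.random.Generator,
    *,
    high_fat: bool = False,
    family_history: bool = False,
) -> float:
    """Draw one latent severity L ~ N(center(stage) + covariate shifts, sd)."""
    if stage not in spec.severity_location:
        raise ValueError(f"stage {stage} has no severity center in the spec")
    loc = spec.severity_location[stage]
    if high_fat:
        loc += spec.diet_shift
    if family_history:
        loc += spec.inheritance_shift
    return float(rng.normal(loc, spec.severity_sd))


def severity_to_profile(
    L: float,
    spec: CohortSpec,
    ranges: NormalRanges = DEFAULT_NORMAL_RANGES,
    rng: np.random.Generator | None = None,
) -> MarkerProfile:
    """Map a latent severity to a six-marker profile.

    At the benign reference severity every positive-gain marker sits exactly
    at its upper normal bound (before noise); four units of severity above it
    a 0.6-gain marker is ~11x the bound.  Outputs are clipped at 0.
    """
    if not np.isfinite(L):
        raise ValueError("latent severity must be finite")
    if rng is None:
        rng = np.random.default_rng()
    l_ref = spec.severity_location[StageLabel.BENIGN]
    values = {}
    for name in MARKER_NAMES:
        upper = ranges.for_marker(name).high
        gain = spec.marker_gain[name]
        noise = rng.normal(0.0, spec.noise_sd)
        values[name] = float(max(0.0, upper * np.exp(gain * (L - l_ref)) * np.exp(noise)))
    return MarkerProfile(**values)


def generate_cohort(
    spec: CohortSpec, ranges: NormalRanges = DEFAULT_NORMAL_RANGES
) -> list[LabeledSample]:
    """Generate the requested counts per class, reproducibly from spec.seed."""
    total = sum(spec.n_per_class.values())
    if total == 0:
        raise ValueError("cohort spec requests zero samples")
    rng = np.random.default_rng(spec.seed)
    samples: list[LabeledSample] = []
    for stage in StageLabel:
        n = spec.n_per_class.get(stage, 0)
        for i in range(n):
            high_fat = bool(rng.random() < spec.p_high_fat)
            fam = bool(rng.random() < spec.p_family_history)
            L = sample_latent_severity(
                stage, spec, rng, high_fat=high_fat, family_history=fam
            )
            profile = severity_to_profile(L, spec, ranges, rng)
            samples.append(
                LabeledSample(
                    profile=profile,
                    label=stage,
                    diet=("high_fat" if high_fat else "normal"),
                    family_history=int(fam),
                    year=spec.year,
                    patient_id=f"{stage}-{i:04d}",
                    latent_severity=L,
                )
            )
    return samples
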