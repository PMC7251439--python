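import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from prostate_dss.cohort import (
    CohortSpec,
    generate_cohort,
    sample_latent_severity,
    severity_to_profile,
)
from prostate_dss.core import (
    DEFAULT_NORMAL_RANGES,
    MARKER_NAMES,
    StageLabel,
    profiles_to_matrix,
)


def test_degenerate_severity_distribution_hits_the_stage_center():
    spec = CohortSpec(severity_sd=1e-12)
    rng = np.random.default_rng(0)
    L = sample_latent_severity(StageLabel.II, spec, rng)
    assert L == pytest.approx(4.0, abs=1e-9)


def test_monte_carlo_severity_mean_matches_the_normal_law():
    spec = CohortSpec(seed=0)
    rng = np.random.default_rng(42)
    draws = np.array(
        [sample_latent_severity(StageLabel.III, spec, rng) for _ in range(10_000)]
    )
    se = spec.severity_sd / np.sqrt(len(draws))
    assert abs(draws.mean() - 5.0) < 3 * se


def test_covariate_shifts_raise_latent_severity():
    spec = CohortSpec()
    rng = np.random.default_rng(1)
    plain = np.mean(
        [sample_latent_severity(StageLabel.I, spec, rng) for _ in range(2000)]
    )
    rng = np.random.default_rng(1)
    shifted = np.mean(
        [
            sample_latent_severity(StageLabel.I, spec, rng, high_fat=True)
            for _ in range(2000)
        ]
    )
    assert shifted == pytest.approx(plain + spec.diet_shift, abs=0.05)


def test_profile_at_benign_reference_sits_at_the_upper_normal_bound():
    spec = CohortSpec(noise_sd=1e-12)
    rng = np.random.default_rng(0)
    p = severity_to_profile(2.0, spec, rng=rng)  # L == benign center
    for name in ("psa", "psma", "tpsa", "pap"):
        upper = DEFAULT_NORMAL_RANGES.for_marker(name).high
        assert getattr(p, name) == pytest.approx(upper, rel=1e-6)


def test_psa_four_severity_units_up_is_eleven_fold_elevated():
    # 4.0 ng/mL * exp(0.6 * 4) = 44.12 -> "tens of times beyond the range"
    spec = CohortSpec(noise_sd=1e-12)
    p = severity_to_profile(6.0, spec, rng=np.random.default_rng(0))
    assert p.psa == pytest.approx(4.0 * np.exp(2.4), rel=1e-6)
    assert p.psa / 4.0 > 10


def test_markers_monotone_in_severity_without_noise():
    spec = CohortSpec(noise_sd=1e-12)
    lo = severity_to_profile(3.0, spec, rng=np.random.default_rng(0))
    hi = severity_to_profile(6.0, spec, rng=np.random.default_rng(0))
    assert hi.psa > lo.psa
    assert hi.rbc < lo.rbc  # negative-gain marker declines


def test_cohort_counts_determinism_and_metadata():
    spec = CohortSpec(
        n_per_class={StageLabel.I: 10, StageLabel.IV: 10}, seed=5
    )
    cohort = generate_cohort(spec)
    again = generate_cohort(spec)
    assert len(cohort) == 20
    assert sum(s.label is StageLabel.I for s in cohort) == 10
    assert [s.profile for s in cohort] == [s.profile for s in again]
    with pytest.raises(ValueError):
        generate_cohort(dataclasses.replace(spec, n_per_class={}))


def test_benign_vs_stage_iv_psa_fold_change():
    spec = CohortSpec(
        n_per_class={StageLabel.BENIGN: 400, StageLabel.IV: 400}, seed=8
    )
    cohort = generate_cohort(spec)
    upper = DEFAULT_NORMAL_RANGES.psa.high
    folds = {
        stage: np.median(
            [s.profile.psa / upper for s in cohort if s.label is stage]
        )
        for stage in (StageLabel.BENIGN, StageLabel.IV)
    }
    assert folds[StageLabel.BENIGN] < 2  # benign elevation "not large"
    assert folds[StageLabel.IV] > 5  # late stage far beyond the range


def test_mean_psa_strictly_increases_with_stage():
    spec = CohortSpec(n_per_class={s: 500 for s in StageLabel}, seed=13)
    cohort = generate_cohort(spec)
    means = [
        np.mean([s.profile.psa for s in cohort if s.label is stage])
        for stage in StageLabel
    ]
    assert all(a < b for a, b in zip(means, means[1:]))


def test_latent_severity_recoverable_from_log_markers():
    """OLS of L on log-markers must leave enough signal for the pipeline."""
    spec = CohortSpec(n_per_class={s: 500 for s in StageLabel}, seed=21)
    cohort = generate_cohort(spec)
    X = np.log(profiles_to_matrix([s.profile for s in cohort]) + 1e-9)
    L = np.array([s.latent_severity for s in cohort])
    r2 = LinearRegression().fit(X, L).score(X, L)
    assert r2 > 0.8


def test_high_fat_subgroup_has_higher_mean_latent_severity():
    spec = CohortSpec(
        n_per_class={s: 300 for s in StageLabel}, p_high_fat=0.5, seed=17
    )
    cohort = generate_cohort(spec)
    hf = [s.latent_severity for s in cohort if s.diet == "high_fat"]
    nf = [s.latent_severity for s in cohort if s.diet == "normal"]
    assert len(hf) > 0 and len(nf) > 0
    assert np.mean(hf) > np.mean(nf)


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(severity_sd=0.0)
    with pytest.raises(ValueError):
        CohortSpec(
            severity_location={
                StageLabel.BENIGN: 2.0,
                StageLabel.I: 3.0,
                StageLabel.II: 3.0,
                StageLabel.III: 5.0,
                StageLabel.IV: 6.0,
            }
        )
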