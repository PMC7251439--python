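"""Train the full decision system and diagnose two synthetic patients.

The gate SVM routes the benign-looking record to a follow-up examination;
the malignant one flows through the stacked ensemble to an EM score, a
stage, and a treatment recommendation.
"""

import warnings

import numpy as np

from prostate_dss import (
    CohortSpec,
    StageLabel,
    SystemConfig,
    generate_cohort,
    diagnose,
    train_system,
)
from prostate_dss.cohort import severity_to_profile

warnings.filterwarnings("ignore")

spec = CohortSpec(n_per_class={s: 150 for s in StageLabel}, seed=0)
system = train_system(generate_cohort(spec), SystemConfig(seed=0))
print("held-out error per learner:")
for name, err in system.report.learner_errors.items():
    print(f"  {name:<22} {err:.3f}")

quiet = CohortSpec(noise_sd=1e-9)  # noise-free probes at known severities
for severity, note in [(2.0, "benign severity center"), (5.0, "stage-III center")]:
    profile = severity_to_profile(severity, quiet, rng=np.random.default_rng(1))
    d = diagnose(system, profile)
    em = "-" if d.em is None else f"lnEM={d.em.ln_em:.2f} EM={d.em.em:.1f}"
    print(f"severity {severity} ({note}): verdict={d.verdict} {em} "
          f"plan={'+'.join(d.recommendation.modalities)}")
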