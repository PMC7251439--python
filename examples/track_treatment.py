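"""Evaluate a treatment plan by the change in EM value.

A large relative EM drop means the therapy works (plan maintained); a small
change or an increase means it does not (plan changed).
"""

import warnings

import numpy as np

from prostate_dss import CohortSpec, StageLabel, SystemConfig, generate_cohort, train_system
from prostate_dss.cohort import severity_to_profile
from prostate_dss.pipeline import assess_treatment

warnings.filterwarnings("ignore")

spec = CohortSpec(n_per_class={s: 150 for s in StageLabel}, seed=0)
system = train_system(generate_cohort(spec), SystemConfig(seed=0))

quiet = CohortSpec(noise_sd=1e-9)
rng = np.random.default_rng(3)
before = severity_to_profile(6.0, quiet, rng=rng)  # advanced disease
responding = severity_to_profile(4.0, quiet, rng=rng)
stalling = severity_to_profile(5.9, quiet, rng=rng)

for after, label in [(responding, "responding patient"), (stalling, "stalling patient")]:
    a = assess_treatment(system, before, after)
    print(
        f"{label}: EM {a.em_before:6.1f} -> {a.em_after:6.1f} "
        f"(drop {a.relative_drop:+.0%}) => {a.verdict} the plan"
    )
print(f"audit log holds {len(system.audit_log)} assessment records")
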