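# prostate-dss

Auxiliary decision support for prostate cancer built on six inexpensive serum
tumor markers — PSA, PSMA, tPSA, RBC, HB and PAP. The package is aimed at
settings where cheap marker panels are plentiful but specialist time is not:
it diagnoses benign vs. malignant disease, stages malignant cases, recommends
a coarse treatment plan and tracks whether a therapy is working, always as an
*auxiliary* suggestion to a clinician, never a prescription.

## The model

A patient is the vector `x = (x_PSA, x_PSMA, x_tPSA, x_RBC, x_HB, x_PAP)`.

1. **Gate.** A soft-margin SVM (benign labeled +1, malignant −1) decides
   whether the tumor is malignant. Benign records exit with a
   follow-up-examination recommendation.
2. **Stacked ensemble.** Malignant records are scored by nine base learners:
   three one-vs-one SVM committees (6 pairwise classifiers each, majority
   voting to a 4-d one-hot), differentiated by kernel (linear, polynomial,
   Gaussian); three ReLU MLPs (6-9-7-4, 6-10-7-5-4, 6-7-5-4, softmax
   output); and three RBF networks (10, 14, 16 Gaussian hidden units with
   k-means centers). Their outputs concatenate into a 36-d vector `z`.
3. **Exponential linear regression (ELR).** The meta-learner fits
   `lnEM = w·z + b` by least squares against manually assigned supervising
   values 3, 4, 5, 6 for stages I–IV, and reports the malignancy score
   `EM = exp(lnEM)` — linear on the log scale, exponential growth of the
   score, matching the observation that marker levels grow exponentially as
   the cancer develops.
4. **Decisions.** Stage from lnEM (`[2.7,3.6) → I`, `[3.6,4.5) → II`,
   `[4.5,5.3) → III`, `≥ 5.3 → IV`), a stage-specific treatment plan, and
   treatment tracking: maintain the plan iff the relative EM drop between
   two visits reaches `treatment_delta` (default 0.3).

Because staged marker panels with outcomes are not publicly available, the
package includes a seeded synthetic cohort generator: a scalar latent
severity per patient (normal around each stage's supervising value; benign
center 2.0) drives all six markers exponentially, with log-normal noise and
optional diet / family-history severity shifts.

## Worked example

```
$ python examples/train_and_diagnose.py
held-out error per learner:
  gate                   0.025
  svm_group_linear       0.038
  ...
severity 2.0 (benign severity center): verdict=benign - plan=next_examination
severity 5.0 (stage-III center): verdict=III lnEM=5.06 EM=157.3 plan=radiotherapy+chemotherapy
```

A noise-free probe at the benign severity center is gated benign; a probe at
the stage-III center (latent severity 5) gets lnEM ≈ 5.06 — right at the
stage-III supervising value — hence EM ≈ 157 and the stage-III plan.
`examples/` contains one short script per capability (cohort simulation,
diagnosis, treatment tracking, calibration table, covariate contrasts); each
prints the numbers it computes and a line on what they mean.

The same workflow is available from the shell:

```
prostate-dss simulate --n-per-class 300 --seed 1 --out cohort.csv
prostate-dss train    --data cohort.csv --seed 1 --out model.json
prostate-dss predict  --model model.json --data cohort.csv --out diagnoses.csv
prostate-dss track    --model model.json --before a.csv --after b.csv --out fx.csv
prostate-dss evaluate --seed 1 --out report/
```

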