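# Methods

## Problem and pipeline

The system scores prostate-cancer malignancy from six serum markers (PSA,
PSMA, tPSA, RBC, HB, PAP). Records are gated by a benign-vs-malignant SVM;
malignant records are staged through a stacked ensemble whose secondary
learner produces a continuous malignancy score EM = exp(lnEM). Supervising
values 3–6 anchor lnEM for stages I–IV; they deliberately do not start at 1
so that benign or borderline profiles land well below the stage-I band,
making the score robust around the benign/malignant boundary.

The supervising values are interpreted on the **lnEM scale** (the default
`elr_target_scale="ln"`): the staging bands (2.7–3.6, 3.6–4.5, 4.5–5.3,
> 5.3) straddle 3, 4, 5, 6 with roughly ±0.5 room, which only makes sense if
3–6 are log-scale targets; raw EM values in the hundreds then correspond to
lnEM ≈ 5–5.3. The alternative raw-scale reading is kept as a config option
but is not the default.

## Base learners

**SVMs.** Binary soft-margin SVMs in dual form. Kernels implemented:
linear `x·z`, polynomial `(x·z)^d`, Gaussian `exp(−‖x−z‖²/2σ²)`, Laplace
`exp(−‖x−z‖/σ)` and sigmoid `tanh(βx·z+θ)`. (Reference tables sometimes
print the last two under each other's name; this package uses the canonical
assignment — the exponential-of-distance kernel is Laplace, the tanh kernel
sigmoid.) The QP is solved by scikit-learn's SVC on precomputed Gram
matrices; the fitted dual coefficients are stored explicitly so the box
constraint 0 ≤ α ≤ C and the equality Σαy = 0 are auditable, and the test
suite cross-checks the dual objective against an independent SLSQP solution
on small instances. Staging uses three one-vs-one committees (one binary
classifier per stage pair, 6 per committee) with majority voting; vote ties
resolve to the **lowest** tied stage — deterministic and conservative (never
over-stages on a tie). Hyperparameters (C ∈ {0.1, 1, 10, 100} × kernel
grid: σ ∈ {1, 2}, d ∈ {2, 3}) are selected on a held-out fifth of the
training split per binary model, refit on the full split, targeting
held-out error ≤ ε (default 0.1); the best found is kept, with a recorded
warning, when the grid cannot reach ε. The gate's kernel kind is searched
over linear/polynomial/Gaussian with the same grids.

**MLPs.** Fixed architectures 6-9-7-4, 6-10-7-5-4, 6-7-5-4, ReLU hidden
layers. The output layer is a softmax trained with cross-entropy against
one-hot stage targets — the standard choice where only "one-hot targets"
is prescribed — which directly yields the normalized 4-d score vector the
stacking layer needs. Optimization is plain full-batch gradient descent
(step 0.01, ≤ 2000 epochs, He initialization, early stop once an internal
held-out fifth reaches error ≤ ε; otherwise the best-held-out weights are
kept). Backpropagation is hand-written and verified against central finite
differences in the tests.

**RBF networks.** One hidden layer of `exp(−β_i‖x−c_i‖²)` units (10/14/16).
Centers come from a seeded Lloyd k-means (per-iteration inertia tracked and
asserted non-increasing; empty clusters reseeded to the farthest point).
Widths use the heuristic β_i = 1/(2m_i²) with m_i the mean distance to the
two nearest other centers. Output weights are fitted by ridge least squares
(λ = 1e-6) against one-hot targets — deterministic, and linear least squares
on one-hot targets approximates class posteriors. Scores are clipped at
zero and renormalized to sum to one.

All learners share one standardization (training-split mean/scale): the
markers span three orders of magnitude and unscaled kernels or gradients
degenerate.

## Meta-learner

The 36-d stacked vector (3 one-hot SVM blocks, 6 score blocks) is mapped by
`lnEM = w·z + b`, fitted by minimum-norm least squares (`numpy.linalg.lstsq`)
against the supervising values of the malignant training samples. The
one-hot blocks each sum to one, so the design is rank deficient; the
minimum-norm solution handles this exactly and coincides with the
pseudoinverse normal-equations solution to 1e-8 (tested), making an explicit
ridge fallback unnecessary. Base and meta learners are trained on the same
80% training split (no internal stacking folds): with learners this simple
and cohorts this size, the split is kept as a single stratified 80/20 with
all randomness derived from one seed. Identical seeds produce byte-identical
model archives.

## Decision layer

Stage bins on lnEM are half-open on the left: [2.7,3.6) → I, [3.6,4.5) → II,
[4.5,5.3) → III, ≥ 5.3 → IV. lnEM below 2.7 still yields stage I plus a
"below stage-I range" flag — the gate, not the EM score, owns the benign
decision, so the two can never contradict. The stage→treatment table
(benign → next examination; I → excision; II → excision+radiotherapy;
III → radiotherapy+chemotherapy; IV → chemotherapy+drug method+hospital
charge) uses the fixed modality vocabulary but the mapping itself is a
package convention, shipped as an editable table. Treatment tracking
computes EM for both visits **through the ensemble directly, bypassing the
gate** (a well-responding patient may be gated benign after therapy, yet the
question is the malignancy trend); the plan is maintained iff the relative
EM drop reaches `treatment_delta` (default 0.3 — "decreases greatly" made
concrete; config-exposed). Every assessment appends one audit record.

## Synthetic cohort generator

One scalar latent severity L per patient drives all six markers — the
simplest mechanism consistent with an exponential marker-growth hypothesis
and a one-dimensional severity score. L ~ N(center(stage), 0.35) with
centers 2.0 (benign), 3, 4, 5, 6 (I–IV); marker_j = upper_normal_j ·
exp(a_j (L − 2.0)) · exp(N(0, 0.15)), gains a_j = 0.6 for the four tumor
antigens and −0.05 for RBC/HB (a mild anemia-like decline: they are blood
counts, not antigens, and are deliberately weak features). Noise is
log-normal because markers are positive concentrations. High-fat diet and
family history add 0.6 and 0.5 to L; their prevalence defaults to zero so
the plain study cohort carries no covariate-induced dispersion, and
covariate analyses switch prevalence on explicitly. Benign patients sit at
the top of the normal range (elevation "not large"); stage IV runs ~11× the
PSA ceiling (4.0 · e^2.4 ≈ 44 ng/mL).

What the generator does **not** emulate: real covariate distributions,
assay-specific measurement error, correlated marker panels beyond the shared
severity factor, longitudinal trajectories, or class imbalance. Passing
tests therefore demonstrate that the pipeline recovers a known exponential
severity structure, not clinical performance.

## Calibration ceiling — a known, quantified limitation

With within-stage severity sd 0.35 and supervising targets one unit apart,
an interval of width 1 around any prediction contains at most one target, so
for *any* predictor `P(|lnEM − target| ≤ 0.5)` is bounded by the Bayes stage
accuracy, numerically **0.885** under the generator defaults (and the ideal
posterior-mean predictor's 90th-percentile deviation is 0.55). The trained
system measures ≈ 0.87–0.88 within 0.5 and a 90th-percentile deviation of
≈ 0.6–0.8 across seeds — essentially at the ceiling; the residual gap comes
from marker noise and from the one-hot SVM blocks quantizing predictions
toward integer targets. The calibration test asserting ≥ 90% within 0.5 is
kept at its stated bound and is expected to fail under these study
conditions; the generator parameters define the conditions and are not
tuned to the test.

## Default problem sizes

Study cohorts default to 300 patients per class (1500 total; one full
training run ≈ 15 s on one CPU). The learning-curve analysis defaults to
sizes {100, 400, 1600} × 5 seeds in the CLI and is exercised at
{100, 400} × 3 seeds in the test suite; accuracy is measured on a fixed
200-per-class pool. Unit tests use 60-per-class cohorts with a reduced MLP
epoch budget.

## Numerical conventions

- Closed normal-range intervals [low, high]; reference values kept exactly
  as printed (including the odd RBC unit g/100 mL and tPSA floor of 4 µg/L),
  overridable in config.
- Decision values of exactly 0 count as the positive class (+1).
- CSV serialization uses repr-faithful floats (exact round-trip); model
  archives are canonical JSON (sorted keys) with a format-version string, so
  determinism is auditable byte-for-byte.
- Seeds: every component's randomness derives from the single config seed
  via a seed sequence; derived seeds stay below 2³¹.
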