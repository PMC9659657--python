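# Methods

This note records the model, the parameter choices that matter, the
numerical decisions, and what the synthetic data do and do not establish.

## Continuous engines

**Baseline WOA.** Each generation first evaluates the clipped population
and greedily updates the global leader, then moves every whale. The branch
probability p and the spiral shape l ~ U[−2·a₂-dependent range] are drawn
once per individual per generation; the r draws behind A = 2a₁r − a₁ and
C = 2r are per dimension, and the encircle-vs-explore decision (|A| < 1)
is likewise resolved per dimension, which matches the canonical reference
implementations of the algorithm family. The exploration partner is drawn
uniformly from the population excluding the individual itself. Boundary
repair is clamping. A generation that would overrun the evaluation budget
is truncated: exactly `max_fes` objective calls are issued, audited
against the problem's evaluation counter. An optional `early_stop` flag
halts a run once the best fitness reaches a problem's known optimum
within 1e-12; it defaults to off to match the fixed-budget comparison
protocol.

**Schedules.** a₁ = 2 − 2·FEs/MaxFEs and a₂ = −1 − FEs/MaxFEs; both are
recomputed once per generation from the evaluation count.

**OLM.** Factors F = 4, levels Q = 3, hence the L9(3⁴) strength-2 array
(M = 9 trials) built by the standard linear construction over GF(Q); the
construction generalizes to any prime Q. Dimensions are partitioned into
factors randomly (balanced, sizes differing by at most one) once per run.
Level 1 is the whale's own coordinate and level Q the guide exemplar's;
the guide comes from three distinct random members. Refinement costs
exactly M + 1 = 10 evaluations (9 trials plus the predicted combination)
and is skipped entirely when the remaining budget cannot cover it. Ties
in the factor analysis break toward the lowest level index so runs are
deterministic. Acceptance is greedy: a whale is replaced only by a
strictly better candidate. By default one whale per generation is refined
— the one whose last move improved its fitness least (the worst whale in
the first generation) — keeping the OLM overhead at 10 evaluations per
generation; a per-whale mode is available (`olm_every="whale"`).

**CMS.** Sampling is m + σ·N(0, C). Recombination uses μ = ⌊N/2⌋ parents
with log-decreasing weights ω_i ∝ ln(μ + ½) − ln i; the learning rates are
c₁ = 2/D², c_μ = min(μ_eff/D², 1 − c₁), c_c = 4/(D + 4),
c_σ = (μ_eff + 2)/(D + μ_eff + 3), and the usual step-size damping
d_σ = 1 + 2·max(0, √((μ_eff − 1)/(D + 1)) − 1) + c_σ. E‖N(0, I)‖ is the
standard series approximation √D(1 − 1/(4D) + 1/(21D²)). Two decay
conventions deliberately coexist: the covariance path P_c decays with
(1 − c₁) (the convention adopted here; at D = 30 it is numerically close
to the usual (1 − c_c)), while the step-size path P_σ decays with
(1 − c_σ), the choice consistent with the stationarity normalization of
the step-size rule — a `paper_literal_eq25` switch restores a (1 − c_c)
decay for comparison. Both path displacement terms carry the
√(c(2 − c)μ_eff) normalization. C^(−1/2) is recomputed by
eigendecomposition every update (dimensions here are small), and after
every update the covariance is symmetrized with eigenvalues floored at
1e-12.

**Handover.** At ⌊max_fes/2⌋ (checked once per generation: an in-flight
generation finishes first) the CMS is initialized from the current
population: the mean starts at the global best (a random-individual
option exists, but starting at the best preserves the monotone
best-so-far contract), C = I, both paths zero, and
σ = S_best/S, where S_best is the mean squared per-dimension deviation of
the best individual from the population mean position and S sums that
quantity over all individuals. This ratio is dimensionless and typically
≈ 1/N; the step-size adaptation grows it within a few tens of
generations when it is too small. A degenerate population (S = 0) falls
back to σ = 0.3·mean bound width. σ is computed at the handover from the
population present there, not at t = 0.

## KELM

Output weights solve (Ω + I/C)β = T by Cholesky factorization (never an
explicit inverse), with one-hot targets in sorted class order and argmax
prediction (ties to the first class). The kernel is
exp(−‖u − v‖²/γ²). Features are z-scored with training statistics only;
zero-variance features get unit scale. Defaults: γ = √(number of
features used), so γ² matches the expected squared distance of
standardized independent features, and C = 32, a mid-range ridge typical
for this classifier family. Both are fixed globally per run rather than
tuned per fold.

## Wrapper feature selection

Positions live in [0, 1]^D. The transfer sigmoid(x) = 1/(1 + e^{−x/3}) is
deliberately gentle: per-bit selection probabilities stay in
[0.5, 0.58], so masks remain stochastic around the incumbent and the
search keeps exploring; this reproduces the characteristically large
selected subsets (roughly half the features) this method family reports.
All-zero masks are repaired by setting one uniformly random bit. The
wrapper objective weights error and sparsity 0.99/0.01.

The error behind the objective is the KELM misclassification rate on a
single stratified 80/20 holdout of the training partition, split once per
run with a fixed seed so the objective is deterministic and memoizable.
A holdout was chosen over inner cross-validation to keep the
2000-evaluation budget of a wrapper run tractable; an evaluator object
can be substituted for other estimates. The evaluator assembles each
masked kernel directly from the selected (z-scored) columns via a single
matrix product and solves the ridge system in single precision — this is
an exact reimplementation of the KELM fit up to float32 rounding, tested
against the estimator class, and makes a 2000-mask run take seconds
rather than minutes. Masks are cached by bit pattern.

The binary engines (bCOWOA, bWOA) reuse the continuous population
updates; bCOWOA applies the same two-phase schedule on the iteration
budget (phase switch at iteration n_iter/2, defaults 20×100 per the
protocol). The outer protocol is repeated stratified k-fold
cross-validation; masks and all KELM fits derive from training partitions
only, metrics come from the held-out fold, and selection counts accumulate
over repeats × folds. If the smallest class cannot fill k folds, k is
reduced with a warning. No multiplicity correction is applied to
selection frequencies; the frequency table is descriptive.

## Synthetic data

`generate_classification` plants k class-conditionally shifted Gaussian
features (separation `effect` in SD units, optional equicorrelation)
among independent standard-normal noise; labels are Bernoulli. The
scaled-down planted benchmark used by the tests and the acceptance script
is n = 300, D = 10, k = 4, effect = 1.5 — a moderate, realistic
separation at which the wrapper problem is neither trivial nor hopeless.

`generate_hd_like` emulates a hemodialysis cohort: 1239 sessions,
exactly 649 non-event / 590 event, 36 features with clinically named
columns. The eight planted features are class-conditional with marginals
matched to published per-class medians and IQRs; symmetric variables are
Gaussian (SD = IQR/1.349), right-skewed durations/volumes (dialysis
vintage, ultrafiltration volume) are log-normal matched to median/IQR,
and gender is Bernoulli with rates 0.59/0.55. Two published medians
coincide between classes and two more differ by less than 0.1 SD, which
would make those "planted" features indistinguishable from noise; the
generator therefore enforces a minimum standardized class separation of
0.5 pooled SDs on planted continuous features (direction taken from the
sign of the median difference, falling back to the IQR difference).
Features already separated beyond the floor — e.g. mean arterial
pressure, 93 vs 103 mmHg — keep their published medians unchanged.
Gender keeps its published rates and is therefore effectively
uninformative. Non-planted columns are class-independent draws from the
pooled marginals.

Limitations of the emulation: real cohorts have cross-feature
correlation (the blood-count ratios are algebraically related), repeated
sessions per patient, missingness and measurement error; none of these
are modeled. Passing recovery tests on this generator shows the pipeline
can find genuinely informative features among realistic marginals — it
does not certify performance on real clinical data.

## Statistics

Wilcoxon signed-rank tests are two-sided with zero differences dropped;
all-tied samples are reported as p = 1 with an "=" sign, and "="
otherwise requires only p ≥ 0.05 (no median-equality condition). Signs
compare the reference (first-listed) algorithm: "+" means significantly
better under minimization. Friedman mean ranks rank per-function average
fitness with average ranks for ties; per-function ranks sum to
A(A+1)/2. Matched seeds per (problem, run) pair guarantee paired
samples.

## Problem sizes used

Benchmark comparisons in the tests run 10 matched runs at dimension 10
with 20,000 evaluations over six function families; convergence checks
use 5 seeds (CMS: 5-dim, 20,000 evaluations; COWOA: 10-dim, 30,000). The
wrapper-selection checks use the n = 300 planted benchmark (10 seeds
against the exhaustive oracle over all 1023 masks) and the
hemodialysis-like cohort with a repeats = 2 × k = 5 protocol over 3
seeds. These sizes were chosen so the full suite runs on a single CPU in
well under half an hour while leaving each check's conclusion
qualitative-stable across seeds.
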