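# Methods

`swarmsvm` implements a two-stage gene-selection and classification scheme
for two-class expression data (e.g. tumor vs healthy microarray profiles):
a mutual-information filter preselects a gene panel, then a particle swarm
jointly assigns per-gene kernel weights and tunes the SVM hyperparameters,
discarding low-weight genes through a hard threshold before the final
weighted RBF-kernel SVM is trained.

## Model and procedure

**Stage 1 — mRMR preselection.** Every gene is discretized and scored by its
mutual information with the class variable `T` (relevance, in bits). Genes
are then chosen greedily: the first maximizes `I(T, g)`; each subsequent gene
maximizes

    I(T, g) - (1/|S|) * sum_{s in S} I(g, s),

relevance minus mean redundancy against the already selected set `S`
(first-order incremental search; no exhaustive subset enumeration). The
default panel size is k = 50.

**Stage 2 — swarm-weighted SVM.** A particle position concatenates k raw
weights `a_i` in [0, 1] with `C` in [0.01, 5000] and `gamma` in
[0.0001, 32] (k + 2 decision variables). Velocities follow the classic
update `v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)`, `x <- x + cf v`,
with defaults swarm 50, inertia `w = 0.9`, `c1 = c2 = 2`, 70 iterations and
constraint factor `cf = 1`. A position's weights pass the gate

    U_delta(a_i) = 0 if a_i <= delta else a_i,

are renormalized to `alpha` with `sum alpha = 1`, and parameterize the
weighted RBF kernel

    K'(x_i, x_j) = exp(-gamma * sum_k alpha_k (x_ik - x_jk)^2),

a valid PSD kernel for any non-negative weights (it is an RBF in the
coordinates `sqrt(alpha_k) x_k`). Uniform weights recover the standard RBF
at width `gamma / d`, so the unweighted SVM is the degenerate case. The
soft-margin dual is solved by scikit-learn's SVC on the precomputed Gram
matrix; decision value 0 maps to class +1 by convention.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `preselect_k` | 50 | mRMR panel size fed to the swarm |
| `delta` | 0.3 | weight-gate threshold in [0, 1]; `delta_search` scans 0.2, 0.3, ... |
| swarm size / iterations | 50 / 70 | search budget; the heavy tests run reduced swarms (see below) |
| `inertia`, `c1`, `c2` | 0.9, 2, 2 | velocity update coefficients |
| `vmax_fraction` | 0.2 | velocity clamp as a fraction of each dimension's range |
| `C`, `gamma` bounds | [0.01, 5000], [0.0001, 32] | swarm search ranges |
| `cv_scheme` / `n_repeats` | LOOCV / 10 | evaluation protocol; repeats use derived seeds |

`delta = 0.3` is the low end of the threshold range that the grid search
typically favors; smaller values keep more genes, `delta = 1` removes all of
them (every raw weight is <= 1) and is reported as degenerate.

## Fitness evaluation

Fitness is classification accuracy, `classified / total`. Two evaluation
modes exist:

* `training` — accuracy on the training samples themselves, the literal
  protocol reading;
* `internal-kfold` (pipeline default) — accuracy over stratified internal
  folds of the training set.

The pipeline defaults to `internal-kfold` because training accuracy is
degenerate in this search space: almost any particle reaches training
accuracy 1.0 (a large `gamma` shrinks the Gram matrix toward the identity
and memorizes the samples), so the "best" particle is arbitrary, and
memorizer particles predict held-out samples at or below chance (their
decision collapses to the training majority, which in LOOCV is biased
*against* the held-out sample's class). Internal CV rejects memorizers.
The number of internal folds (`fitness_n_folds`, default 5) trades fitness
resolution against runtime.

A related, unavoidable limitation: accuracy-only fitness plateaus at 1.0
whenever the training data are separable. Past that point the swarm's
global best freezes (updates require strict improvement), so the *weights*
of well-separated problems are largely the random initialization filtered
through the gate — the method determines *which genes suffice*, not a
canonical importance ranking. Consequences of this plateau are visible in
the planted-gene recovery simulations: with strongly separated planted
genes, the surviving set reliably contains *enough* informative genes to
classify perfectly, but not necessarily *all* of them.

## Thresholding inside or after the search

By default `U_delta` is applied inside every fitness evaluation and again
when decoding the global best (`threshold_in_fitness=True`), so the search
"sees" the gene selection it will end with. Setting it to `False`
reproduces the literal protocol in which weights are gated only once, after
the best position is chosen.

## Cross-validation protocol and selection bias

`selection_scope="whole-dataset"` (default) runs mRMR once on all samples
before folds are formed — this reproduces the published step order but
carries selection bias, since the filter has seen the held-out samples.
`selection_scope="per-fold"` re-runs mRMR inside every training fold
(nested CV) and is the recommendation for honest accuracy estimates.
Repeat seeds are `master_seed + repeat_index`; per-fold swarm seeds are
derived from the repeat seed and the sorted held-out sample ids (crc32), so
cross-validated accuracy is invariant to the row order of the input.

## Synthetic data: what it emulates and what it does not

The generator draws unit-variance Gaussians within class; `n_informative`
planted genes have class means at `+/- effect_size / 2` (separation of
`effect_size` within-class SDs), labels balanced to within one sample.
This captures the signal structure mRMR and the margins respond to, and
provides planted ground truth for recovery tests. It does **not** emulate
real microarray data in three relevant ways: intensities are standardized
(real intensities have arbitrary, often huge scales, where fixed kernel
defaults are miscalibrated and hyperparameter search pays off), effects are
homogeneous (all planted genes equally informative, so weighting them
unequally cannot help), and genes are independent (no co-expression
blocks). Passing tests on this generator therefore validate the mechanics
and contracts of the method — they do not demonstrate that weighting beats
an unweighted baseline, which on this generator is already near-optimal:
the fixed baseline `gamma = 1/k` on standardized data behaves like a
near-linear, well-calibrated kernel, which is Bayes-optimal-adjacent for
homoscedastic mean-shift classes. The ablation simulations reflect
exactly that.

## Numerical choices

* Mutual information in bits; entropies are summed over *sorted* cell
  probabilities, making `I(X, Y)` bitwise symmetric and
  `I(X, X) = H(X)` exact. Tiny negative rounding is clamped to 0.
* Default discretization: per-gene three levels at `mu +/- sigma`
  (population SD); a constant gene collapses to one state and carries zero
  information. Equal-width and equal-frequency k-bin schemes are available.
* Greedy ties (scores within 1e-12 of the step maximum) break toward the
  lower column index, for determinism.
* Velocity clamped to `vmax_fraction` of each dimension's range and
  positions clipped to bounds after every update; without clamping the
  standard coefficients diverge on ranges as wide as C's.
* Gram matrices are symmetrized exactly and given a unit diagonal;
  negative squared distances from floating cancellation are clipped at 0.
* A position whose gate zeroes every weight scores fitness 0; if the final
  global best is degenerate the pipeline raises and points to
  `delta_search`.
* Weight vectors must sum to 1 within 1e-9; model serialization uses JSON
  shortest-repr floats (exact round trip).

## Problem sizes in the shipped experiments

The repeated simulations in the test suite and `scripts/acceptance.py` use
reduced swarms (6-20 particles, 6-30 iterations), 3 internal fitness
folds, panels of 20-50 genes and 20-40 samples; these sizes keep the
repeated LOOCV-with-embedded-search experiments to minutes while preserving
the qualitative behavior of the full-size protocol.

## Known limitations

* Binary classification only; no probability calibration.
* The accuracy plateau (above) makes recovered weight vectors
  non-identifiable on separable data.
* Whole-dataset preselection (the default, for protocol fidelity)
  overestimates accuracy; use `per-fold` for unbiased estimates.
* No raw-intensity preprocessing (normalization/log transforms) is applied
  or required; an optional per-gene z-scoring helper exists on the dataset
  object.
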