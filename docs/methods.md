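# Methods

## Model and objective

`RSDNetClassifier` is a fully-connected feed-forward network for binary
classification: tanh hidden layers (default widths 5 and 3) and a 2-unit
softmax output. Kernels are initialized i.i.d. Normal(0, `init_std`²)
(default `init_std = 0.05`) from a seeded generator; biases start at zero.
The per-batch objective is

    L = mean cross-entropy over the batch  +  Σ_layers penalty(kernel_l)

with the penalty applied to kernel matrices only, never to biases, and added
once per batch (not scaled by batch size). Predicted probabilities are
floored at 1e-12 inside the log; the predicted class is the softmax argmax,
with an exact 0.5/0.5 tie resolved to the lower class label.

### Penalties

With λ ≥ 0 and all sums over a kernel's entries:

| family  | penalty | gradient |
|---------|---------|----------|
| l1      | λ·Σ\|w\| | λ·sign(w), sign(0)=0 |
| l2      | λ·Σw²   | 2λw |
| elastic | λ·Σ[((1−α)/2)w² + α\|w\|] | λ[(1−α)w + α·sign(w)] |
| rsd     | λ·σ(w), population sd of the flattened kernel | λ(w−mean)/(N(σ+ε)) |

The elastic form is the canonical one whose α=1 and α=0 limits are exactly
the lasso and half the ridge penalty. The RSD sigma uses the population
divisor N (both moments divided by the entry count); ε = 1e-12 guards the
gradient at constant kernels, where the numerator is identically zero, so
the gradient there is exactly 0. An alternative `rsd_mode="rowwise"` treats
each kernel row as its own weight vector and sums per-row sigmas; the
default "flat" mode matches the reading of the penalty as "the weight
matrix's standard deviation". The subgradient at w = 0 for l1/elastic is 0,
keeping exactly-zero weights at zero.

The RSD penalty's distinguishing algebra — translation invariance
(penalty(W + c) = penalty(W)) and absolute homogeneity
(penalty(cW) = |c|·penalty(W)) — is asserted in the test suite, along with
the failure of translation invariance for all three baselines.

### Optimizer

"Nadam" here is the common Adam-with-Nesterov-lookahead update (step index
t ≥ 1):

    m ← β₁m + (1−β₁)g            v ← β₂v + (1−β₂)g²
    θ ← θ − lr·(β₁·m/(1−β₁ᵗ) + (1−β₁)g/(1−β₁ᵗ)) / (√(v/(1−β₂ᵗ)) + ε)

Defaults: lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8. Training runs 100 epochs of
mini-batches of 4; each epoch reshuffles with the same seeded generator that
initialized the kernels, the last incomplete batch is kept, and the whole
run is bit-reproducible from `random_state`. Per-epoch history records the
full-training-set penalized loss, training accuracy and (when validation
data is supplied) validation accuracy.

A practical note on scale: at the λ values the comparison study sweeps
(1e-8, 1e-6) every penalty's gradient contribution is orders of magnitude
below the cross-entropy gradient, so runs that share a seed produce
essentially identical trajectories across families; differences between
families only emerge at larger λ or across seeds.

## Preprocessing

Non-numeric columns are label-encoded by lexicographic token order
(deterministic across runs). Exact duplicate rows (features *and* label)
are dropped, first occurrence kept. Min–max scaling maps each column
through (x − min)/(max − min) with the min/max of the *fitting* rows;
constant columns map to 0 with a warning, and out-of-range values at apply
time extrapolate beyond [0, 1] rather than being clipped. PCA is computed
by eigendecomposition of the sample covariance (divisor n−1), components
sorted by explained variance, each axis's sign fixed so its
largest-magnitude loading is positive.

By default scaling and PCA are fitted on the training rows of each split
only and applied to held-out rows, avoiding leakage; `fit_on_all=True`
reproduces the leakier fit-once-on-everything variant some studies use.
Which variant a published figure used is rarely stated, so both are exposed
and neither is asserted as canonical.

## Evaluation protocol

Splits are stratified by label (the data this tool targets is small and
mildly imbalanced, ~55:45). Holdout takes round(0.8·n_c) training rows per
class; stratified k-fold deals each class's shuffled indices round-robin,
so per-class test-fold sizes differ by at most one and the test folds
partition the index set. Metrics come from the confusion matrix with
"disease present" (label 1) positive: accuracy, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), F-score = harmonic mean of precision and
sensitivity; any 0/0 ratio is reported as 0.

`lambda_sweep` evaluates a λ grid with `repeats` independent seeds
(base_seed … base_seed+repeats−1; each seed drives the split, the
initialization and the shuffles) and reports mean ± sd validation accuracy
plus per-fold accuracies. `compare_regularizers` assembles the
family × {with, without PCA} grid at each family's best swept λ, shaped
like the comparison tables such studies print. Holdout and 10-fold results
are always reported separately, never merged.

## Synthetic data

`heart_schema()` emulates the 13-attribute clinical heart schema: truncated
normals inside the declared supports for continuous features (age in
[25, 80], resting blood pressure ≥ 94, cholesterol ≥ 126, maximum heart
rate in [71, 202], ST depression in [0, 6.2], …) and fixed category
probabilities for the discrete ones (ECG ∈ {0,1,2}, thallium ∈ {3,6,7},
…). Labels follow a logistic model on the [0, 1]-scaled features,

    y ~ Bernoulli( sigmoid( effect · x + intercept + N(0, noise_scale) ) ),

with the intercept solved by root-finding on the drawn sample so the
expected absent-class share equals `class_balance` (default 150/270). The
moderate default effect vector puts its weight on age, maximum heart rate
and ST depression (coefficients 2.5, −2.5, 2.5) with smaller contributions
from chest pain, angina, vessel count and thallium — the features such data
is known to correlate with outcome — and supports roughly 70% 10-fold
accuracy at n=270. `effect_scale=8` is the frozen "strong signal" preset:
its Monte-Carlo Bayes accuracy is ≈0.945, chosen at design time so signal
recovery is cleanly testable. Values `0, 10, 30` are the noise probe levels
used in tests (the strong preset's logit has sd ≈ 9.7, so the levels span
negligible, signal-comparable and signal-drowning noise).

What the generator does **not** imitate: the real data's marginal shapes,
feature correlations (features are drawn independently), measurement error
or missingness. Passing tests therefore demonstrate that the pipeline
learns a planted conditional-probability signal under the declared schema —
not that any particular accuracy will be attained on real clinical data.

`generate_separable` produces two Gaussian blobs at ±margin·u (random unit
direction u, per-axis sd `scale`, balanced labels) as a learning-sanity
fixture; its Bayes accuracy is Φ(margin/scale).

## Numerical and design choices

- Probabilities floored at 1e-12 before logs; softmax computed with the
  row-max subtracted.
- PCA sign fix and lexicographic label encoding make every fitted object
  reproducible bit-for-bit.
- Holdout per-stratum train counts are clamped so both sides keep at least
  one member; classes with fewer than two members refuse to split.
- The separable learning checks use margin 5 (sd 1) for the full-protocol
  accuracy floor and margin 1 with sd 0.25 for the tight-blob variant; both
  are genuinely separable (Bayes ≈ 1).
- Problem sizes in the test suite and acceptance script (n = 270 for the
  comparison grid, n = 2000 for 10-fold recovery, 3 repeats per sweep cell)
  are the package's chosen study sizes for synthetic experiments.

## Known limitations

- Binary classification only; the output layer is fixed at two units.
- No missing-value handling: rows must be complete.
- The λ sweep is a plain grid; there is no nested model selection, so the
  reported best-λ accuracy is mildly optimistic as an estimate of
  generalization at a pre-chosen λ.
- Accuracies published for the classic UCI heart data are not reproduction
  targets: they depend on external data and unseeded stochastic training.
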