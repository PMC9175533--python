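# Methods

This note records the models and procedures the package implements, the
choices made where the published description of the algorithm family is
ambiguous, what the synthetic data does and does not emulate, and the
package's known limitations.

## The optimizer

### Population dynamics

The marine predators algorithm maintains a prey matrix `X ∈ R^{N×D}` and
an Elite matrix whose rows all replicate the best-so-far position. The
iteration budget splits into three regimes, dispatched by iteration
thirds (phase 1 for `it < ⌈it_max/3⌉`, phase 2 up to `⌈2·it_max/3⌉`,
phase 3 afterwards — the published strict inequalities leave the boundary
iterations ambiguous; ceiling boundaries are used so every iteration
belongs to exactly one regime):

- **Phase 1** `step = R_B ⊙ (Elite − R_B ⊙ X)`, `X += P·R ⊙ step` with
  `R_B` standard normal and `R` uniform in [0,1];
- **Phase 2** first `N/2` rows use the phase-1 form with Lévy factors
  `R_L`; rows `N/2+1..N` use `step = R_B ⊙ (R_B ⊙ Elite − X)`,
  `X = Elite + P·CF·step`;
- **Phase 3** all rows: `step = R_L ⊙ (R_L ⊙ Elite − X)`,
  `X = Elite + P·CF·step`,

with `CF(it) = (1 − it/it_max)^{2·it/it_max}` decaying from 1 to 0 and
`P = 0.5`. Each equation prints its random factor twice; whether the two
occurrences share one draw is unspecified, so **independent draws** are
used, isolated in pure step kernels (`phase*_kernel`) that accept pinned
samples — the tests hand-evaluate the closed forms through the same
kernels the driver calls.

The FADs perturbation fires per row with one uniform scalar `r`: if
`r ≤ FADs = 0.2` the row jumps by `CF·(lb + r·(ub − lb))` masked per
dimension by independent Bernoulli(FADs) indicators; otherwise it drifts
along the difference of two distinct random rows (drawn without
replacement, indices computed against the pre-perturbation population)
scaled by `FADs·(1 − r) + r`.

Memory saving keeps, per row, the better of the current and
previous-iteration (position, fitness) pair; the Elite updates only on a
*strict* improvement, so ties keep the incumbent and the best-so-far
trajectory is non-increasing by construction.

### Lévy sampler

The heavy-tailed step factor uses Mantegna's two-Gaussian construction
with tail index α = 1.5: `u/|v|^{1/α}` with `u ~ N(0, σ_u²)`,
`v ~ N(0,1)` and σ_u the standard Mantegna scale. The published
description names the Lévy distribution without a generator; Mantegna's
is the established convention for this algorithm family. α is
configurable in (1, 2].

### Opposition-based learning

The opposite of an in-bounds point is the box reflection `lb + ub − x`.
OBL is applied twice per run: at initialization (sample, score, reflect,
score, keep the rowwise fitter) and once per iteration **after** the FADs
step and its memory save (the published ordering — "after completing
these phases" — is followed; applying it before FADs is the plausible
alternative and would change only the rng stream). The merge is a
whole-population rowwise greedy comparison; ties keep the original.
Opposition uses the *static* search-space bounds, not the population's
dynamic extent, and acts in the optimizer's own coordinate system, so a
log-scaled dimension reflects on its exponent.

A consequence worth knowing: on objectives symmetric about the box
centre (e.g. the sphere on `[−10, 10]^D`), every opposite has exactly
the original's fitness, the merge never fires, and IMPA reproduces plain
MPA's trajectory bit for bit. OBL earns its extra `N·(it_max + 1)`
evaluations only on asymmetric landscapes.

### Evaluation accounting

IMPA spends `N` evaluations on the initial sample, `N` on its opposite
population, and `3N` per iteration (phase update, FADs, opposition):
`N·(3·it_max + 2)` in total. Plain MPA spends `N·(2·it_max + 1)`. Both
identities are asserted inside every run.

### Search space and decoding

Dimensions are continuous, log-continuous (optimizer moves in log10
coordinates; the learning-rate range spans four decades, so uniform
sampling on the exponent is the only sensible parameterization) or
integer (real-valued positions rounded half-away-from-zero, then
clamped). Positions are hard-clamped to the box after every update —
boundary handling is unspecified in the source material, and clamping is
consistent with the FADs jump's explicit use of `lb`/`ub`. Decoding is
invariant to clamping, so any real 8-vector yields a valid
configuration.

## The classification harness

### Backbone and head

The harness follows the transfer-learning recipe: a pretrained
convolutional base, its classifier replaced by a fresh 8-layer head —
flatten, three ReLU dense layers (widths from the search) each followed
by dropout (rates from the search), and a final 1-unit output. The
published head description ends in "one neuron with a softmax", which is
degenerate (softmax of a single logit is constant 1); a single sigmoid
unit with binary cross-entropy is used instead, which is the standard
two-class head.

The bundled backbone is `surrogate_cnn`: three conv(3×3)-ReLU-maxpool
blocks (8, 8, 16 channels) over 32×32 grayscale inputs, with fixed
He-initialized weights drawn from a dedicated seed. Fixed random
convolutional features are the desk-scale stand-in for a pretrained
base: they are shared by every candidate, never retrained during feature
extraction, and sufficient for the synthetic task. The `resnet50`
backbone name is reserved for externally supplied pretrained weights and
raises an explicit error when they are absent. "Last two blocks" for the
surrogate means its final two convolutional stages, mirroring the
convention for residual backbones.

Training is two-stage: **feature extraction** (all backbone blocks
frozen, head trains) for `⌈stage_split·epochs⌉` epochs, then
**fine-tuning** (last two blocks unfrozen, joint training) for the rest.
The split is configurable; the default is half/half since the stage
boundary is not specified by the recipe. The optimizer's Adam state is
keyed by parameter identity, so unfreezing mid-run simply adds
parameters to the update set. Freezing is verifiable: frozen parameters
are bit-identical before and after training, and the tests check this
against a freshly built backbone.

The network engine (`impa.nn`) is a small numpy implementation with
manual backprop — im2col convolution, max pooling, dense, inverted
dropout, stable sigmoid/BCE, Adam. At 32×32 with ~10⁵ parameters a
full search-plus-training pipeline runs in seconds on one CPU.

### Preprocessing and augmentation

Inputs are collapsed to one channel, rescaled to [0,1], median-filtered
(3×3, switchable off — "noise removal" is otherwise unspecified) and
resized to the backbone's input size. The augmentation defaults are
shear 0.1, zoom 0.1, width/height shifts 0.3, rotation 15°, both flips,
reflect fill, and featurewise centring/std-normalization. The
featurewise statistics are *fitted on the training split* and applied
deterministically to both streams (the normalization is preprocessing,
not augmentation); the random geometric transforms touch the training
stream only, so validation and test metrics are always computed on
untransformed images.

### The fitness function

A candidate position decodes to (learning rate, batch size, dropouts,
widths), trains on a stratified 80% of the training images under a
reduced epoch budget, and scores `1 − accuracy` on the held-out 20%.
The scalar the published procedure minimizes is never named; accuracy is
its headline metric, so `1 − validation accuracy` is the natural choice.
The test split is reserved for final evaluation only. Fitness is a pure
function of (position, dataset, seed, budget); a run whose loss goes
non-finite scores the sentinel worst fitness 1.0 and is logged. The
final training after the search uses the full epoch budget (30 by
default in the decoded configuration; 10 in the desk-scale pipeline
runs).

## Metrics

Accuracy, sensitivity, specificity and precision are the standard 2×2
ratios, with NaN as the undefined marker on empty denominators. The
F-score is the macro average over classes of the harmonic mean of
precision and sensitivity; the source's printed per-class formula
reduces to precision alone (its numerator/denominator are precision's),
which is treated as a typographical slip — the implemented F-score
behaves consistently with how F-score columns relate to
precision/sensitivity columns in the published comparisons. AUC uses
the Mann–Whitney rank-sum form `(ΣR₊ − I_t(I_t+1)/2)/(I_t·I_f)` with
mid-ranks for ties; the printed denominator `I_t + I_f` is not bounded
by 1 and is likewise treated as a misprint. The rank formula is tested
against exhaustive pair counting (ties counted ½) to 1e−12, and against
an independent library implementation.

Improvement tables report percentage-point differences (optimized −
baseline) to two decimals; dataset accounting reproduces per-split and
grand totals from class-count tables.

## Synthetic data

The image generator emulates only the *structure* of a screening task:
class 0 is Gaussian noise smoothed with σ = 1.5; class 1 adds one bright
elliptical blob (semi-axes 18–28% of the image side, random eccentricity
0.6–1.0 and orientation, centre in the middle half) whose peak contrast
is `separation` texture standard deviations ±10% jitter. The applied
per-image contrast is recorded, making the generator's distributional
contract (class-mean contrast tracks the separation dial within 5%)
directly testable. At separation ≥ 3 a mean-intensity threshold already
classifies a 200-image set at ≥ 95% accuracy — the geometry was
calibrated against that oracle — so a small CNN must only rediscover a
smoothed intensity feature.

What this does **not** emulate: mammographic texture statistics,
calcification morphology, lesion/parenchyma superposition, acquisition
variability, class imbalance, or label noise. Passing pipeline tests
therefore demonstrates that the optimizer, harness and metrics are
implemented correctly and interact correctly — not that the approach
reaches any particular accuracy on real mammograms.

Desk-scale study conditions used by the pipeline runs and the
reproduction script: 128 images per class at 32×32, separation 5, 25%
test split; search with population 4 and 3 iterations at 2 epochs per
candidate (44 trainings); final training 10 epochs. Benchmarks run the
published optimizer settings (population 30, 50 iterations) on the 8-D
sphere.

## Numerical and design notes

- All randomness flows from explicit `numpy.random.Generator` objects
  seeded at the driver boundary; no global state. Fixed seeds reproduce
  every result bit for bit, including training histories.
- Fitness orientation is internal minimization; maximization objectives
  are negated at the adapter boundary.
- The planted-optimum recovery check uses the quadratic on
  *box-normalized* coordinates. On the raw mixed scales of the default
  space the dense-unit dimensions (range 450) dominate the loss and the
  small-range dimensions are recovered only incidentally; normalizing
  weights all eight dimensions equally, matching the box-normalized
  distance in which recovery is measured.
- Dropout-rate and width dimensions are independent per layer (8 search
  dimensions total).
- Epochs are fixed, not searched.
- Termination is by `it_max` only; no stagnation-based early stopping.
- In the comparison harness each optimizer/seed pair gets a fresh
  objective adapter so evaluation counters cannot leak across runs.

## Limitations

- The OBL overhead makes IMPA ~50% more expensive than MPA per
  iteration; on centre-symmetric objectives the overhead buys nothing
  (see above).
- The surrogate backbone is not a pretrained network; conclusions about
  *which* hyperparameters win on the synthetic task do not transfer to
  real backbones or data.
- Only two-class heads, single-channel images and flat (non-conditional)
  search spaces are supported; competitor metaheuristics are accommodated
  through the optimizer registry but not implemented.
- Reproducing published headline accuracies on real mammography
  collections requires the external datasets and GPU-scale residual
  backbones, both outside this package's scope.
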