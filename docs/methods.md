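# Methods

This note documents the models implemented in `nriqa`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the design decisions taken where the architecture was genuinely open.

## Synthetic phantom study

Every quantitative claim the test suite makes is evaluated on synthetic
phantoms: piecewise-constant overlapping ellipses (intensities 0.3–0.9 on
a 0.1 background) plus a difference-of-Gaussians bandpass field scaled by
`texture_strength` (default 0.3), rendered at 64×64. Degradation is
additive Gaussian noise (default) or Rician magnitude noise, with
variance on the [0, 1] intensity scale. The study grid is
v ∈ {0.2, 0.4, 0.6, 0.8, 1.0}; these variances are large (σ up to 1 on a
unit intensity range), so clipping to [0, 1] is substantial and accepted.
Ground truth is defined as `true_score = 1 − v/v_max` with
`v_max = max(1.0, max(variances))`, a monotone, bounded target that makes
parameter recovery checkable; an image is labelled High when its score is
at least 0.5.

The default dataset is 200 phantoms split 75% / 15% / 10% into
training / test / validation. Integer partition sizes floor the exact
products and assign the remainder to training, so the realized sizes
always sum to the total while the exact (possibly fractional) products
remain available.

What the phantoms do **not** emulate: anatomy-specific structure,
scanner artifacts other than noise (bias fields, motion, ghosting),
3-D context, and — most importantly — human opinion scores. Passing the
recovery tests shows the pipeline can track a known monotone corruption
parameter through its own feature space; it does not show agreement with
radiologist judgment on clinical images.

## Hybrid denoising

The bilateral stage computes, per pixel, the normalized product-kernel
average with Gaussian spatial kernel (σ_s, default 1.5 px), Gaussian
range kernel (σ_r, default 0.1 intensity units) and square neighborhood
radius 3. The output is a convex combination of neighborhood values, so
it is bounded by the input range and exactly fixes constant images. The
Wiener stage re-centres on the local mean over a 5×5 window and shrinks
by P/(P+σ²), where P is the local variance (mean of squares minus
squared mean, clamped at zero) and σ² is the mean local variance unless
overridden. σ² = 0 gives the identity. Composition order is bilateral
first — edge preservation before stationary-noise suppression. All
borders use edge-duplicating ("symmetric") reflection.

## Run-length texture block

Intensities are binned uniformly into 16 levels numbered 1..16
(left-closed bins; a value exactly on a boundary goes to the higher bin),
so the j² and 1/j² descriptor weights are finite and discriminative.
Runs are maximal constant-level segments along the scan lines of each
direction; run-length matrices satisfy the pixel-conservation identity
Σ k·Q[j,k] = M, which is property-tested. The seven descriptors (SRE,
LGLRE, LRE, RLN, GLN, RP, HGRE) use the standard semantics — LRE weights
by squared run length, RLN squares run-length marginals, GLN squares
gray-level marginals, HGRE is normalized by the run count — except that
LGLRE is computed as Σ j²Q/k² / ΣQ, i.e. with the gray-level weight in
the numerator. Per-direction vectors are averaged arithmetically over
the four directions by default; the per-direction vectors remain
available. A region-of-interest mask may be supplied; masked-out pixels
break runs and are excluded from M. Note that a constant image is
isotropic only within the axis pair and within the diagonal pair: the
diagonal scan lines of a finite image vary in length, so the two
families differ.

## Deep structural features

The deep block is a *pluggable* extractor. The default backend is a
stack of depthwise-separable convolution blocks (3×3 depthwise, 1×1
pointwise, leaky-ReLU, 2×2 average pooling) whose block layout comes
from the compound-scaling transform — repeats scale as ceil(a·T),
channels as ceil(b·R) rounded to even, resolution by c, with estimated
FLOPs and parameter counts checked against configurable budgets — with
He-style weights drawn once from a fixed seed and a random projection to
64 output features. These random-projection features are a deterministic
structural descriptor, not a trained network's representation: they are
sensitive to image structure and corruption (tested), reproducible
everywhere, and require no downloads. Any trained extractor can be
plugged in through the same interface (name, output_dim, input_side,
forward).

Texture and deep blocks are fused by concatenation (texture first) and
min-max normalized per feature using training-partition statistics only;
constant training columns map to 0 and out-of-range values on new data
are clipped.

## Reptile search optimizer

A population of M candidates in a box follows the four-phase schedule
over n_max iterations: high walk and belly walk (encircling, first
half), hunting coordination and cooperation (second half), with phase
boundaries half-open at the top so every iteration lies in exactly one
phase. The operators use the hunting ratio
q = α + (x − M(f))/(best·(upper−lower) + ε), the reduction function
H = (best − x_r2)/(best + ε) with one neighbor row drawn per candidate,
and the evolutionary ratio D = 2·r3·(1 − 1/N), |D| ≤ 2. Constants:
α = β = 0.1, ε = 1e-10. Positions are clamped to the box after every
update.

Two implementation choices matter in practice. First, acceptance is
elitist: a candidate keeps its new position only when its fitness
improves, and the global best is tracked greedily, making the recorded
best fitness monotone. Second, the feature-selection wrapper
(positions in [0,1]^d thresholded at 0.5; fitness
0.99·error + 0.01·|S|/d; the empty mask is assigned a worst-case
fitness) finishes with a deterministic single-bit hill climb from the
best mask (≤ 3 sweeps, same cached fitness): the multiplicative position
updates essentially never propose clean single-feature additions or
removals, which is exactly the move that separates a tight subset from a
starved or bloated one. With this finish, the synthetic recovery
experiment (3 informative of 20 features) returns exactly the
informative subset on 5/5 seeds.

Hyperparameter tuning reuses the same optimizer over a continuous box
(validation RMSE as fitness); the untuned default configuration always
competes, so tuning can never return something worse than the default.

## Self-evolving deep-belief fuzzy network

**Pretraining.** A stack of RBMs (hidden widths 32, 16 by default) is
trained greedily with full-batch CD-1 (data statistics minus
reconstruction statistics, sampled hidden states on the negative phase;
learning rate 0.1). Weights initialize fan-in scaled,
N(0, 1/√n_visible): with a fixed small scale every hidden probability
collapses to logistic(0) = 0.5 and the rule layer downstream receives
indistinguishable vectors. The deterministic forward transform is the
composition of hidden-probability maps.

**Rule layer.** Rules store an exemplar (D1), a consequent quality value
in [0,1] (D2) and a sensitivity threshold R* (fresh rules start at 0.3).
Fuzzification computes p-norm distances to all exemplars normalized to
sum 1 (p = 2 default); activations are Y1 = 1 − e. During the online
pass a new rule is created from the current sample when (a) there are no
rules, (b) the best activation falls below the winner's sensitivity, or
(c) the prediction misses the target by more than 0.1 (one tenth of the
quality scale, half the spacing of the study's noise grid) — the
distance-plus-error pair of creation criteria standard in evolving
fuzzy systems. Otherwise the winner moves: exemplar toward the input
with rate κ1 = 0.1 (a geometric contraction, (1−κ1)^t), consequent by
κ2·Y_max·(target − prediction) with κ2 = 0.1, clamped to [0,1]. At each
epoch's end the most active rule's sensitivity evolves from its win
count relative to the mean (decrease by 1 − (μ−δ)/x for busy rules,
increase by 1 + μ/x for idle ones, x = 10, clamped to (0.01, 1]).
Evolution is deliberately restricted to the epoch winner: applying the
increase branch to every sub-threshold rule compounds multiplicatively
to the cap, after which every sample spawns a rule and predictions
collapse to a constant.

**Defuzzification.** The score is the activation-weighted average of
consequents over the *gated* rule set: each rule's weight is
Y1 · exp(−(d/d_min − 1)/γ), a soft cutoff on the distance ratio to the
nearest rule (γ = 0.2; exact exemplar hits take all the weight). The
gate is essential: because the distances are normalized to sum 1, every
activation approaches 1 as the rule count grows, and the ungated average
provably collapses toward the mean consequent — measured on this study,
predictions compressed into a ~0.1-wide band regardless of rule
placement. With one or two rules the gate is inactive in the natural
cases: a single rule returns its consequent, and an input equidistant
from two rules returns the midpoint of their consequents. Labels
threshold the score at 0.5.

## Pipeline

Stage order: data (simulate or load) → hybrid denoise → texture
features → deep features → fuse + normalize → feature selection →
(optional) hyperparameter tuning → train on the training partition →
predict on the test partition → report. The selection stage's wrapper
fitness is a cheap 2-fold, reduced-epoch cross-validation of the actual
predictor; because the search then picks the minimum over hundreds of
noisy estimates, the winning mask is optimistically biased, so the
leading distinct masks — together with three block-level ablation
baselines (texture block, deep block, full fused vector) — are re-ranked
by a 10-fold full-epoch cross-validation before committing. Every run
writes feature tables, the model, predictions, the report, and a
manifest (config hash, seed, stage timings); identical configurations
reproduce byte-identical artifacts.

Problem sizes were chosen to keep a full study desk-scale: 200 phantoms
at 64×64, population 10 and 40 iterations for the selection search, 20
training epochs. A complete run takes roughly 90 s on one CPU;
end-to-end recovery on this study measures SROCC ≈ 0.85–0.97 and MAE
≈ 0.04–0.11 on the held-out partition across seeds.

## Numerical and degenerate-input conventions

- Borders: symmetric (edge-duplicating) reflection in both filters.
- Local variance clamped at zero; Wiener with σ² = 0 short-circuits to
  the identity.
- Quantization boundaries go to the higher bin; level sets are 1-based.
- Fuzzy distances with a zero denominator (input equal to every
  exemplar) fall back to uniform 1/count.
- Prediction with zero total gated weight falls back to the mean
  consequent.
- Empty feature masks are never selected (assigned worst-case fitness).
- All randomness flows through `numpy.random.default_rng(seed)`; every
  public operation is a pure function of its arguments including the
  seed.

## Known limitations

- The default deep backend is a random-projection descriptor, not a
  trained network; its features are weaker than learned ones and, on
  this study, noticeably content-dominated — feature selection usually
  discards most of them in favor of the texture block.
- The rule layer predicts by local interpolation in the transformed
  feature space; extrapolation beyond the training distribution returns
  the nearest rules' consequents.
- Rank correlations on a 30-image test partition carry sampling noise of
  roughly ±0.05; single-seed comparisons near a threshold should be read
  accordingly.
- Real-data evaluation requires user-supplied ground-truth scores; the
  package defines none for clinical images.
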