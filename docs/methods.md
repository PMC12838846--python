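# Methods

## The model

`qfusion` implements a quantum-inspired fusion classifier for multi-class
medical image classification (the motivating task is five-way grading of
appendicitis from abdominal CT: normal, simple, localized complicated,
advanced complicated, rare variants). Two frozen backbone networks emit
feature vectors `z_A ∈ R^{d_A}` and `z_B ∈ R^{d_B}` per image; the fusion
head combines them as follows.

**Hadamard interaction.** Both vectors are truncated to their first
`d_H = min(d_A, d_B)` components and multiplied elementwise,
`z_H = ẑ_A ⊙ ẑ_B`. This token carries explicitly multiplicative
cross-backbone structure: signals that are invisible in either embedding's
marginal statistics but present in their joint sign/magnitude pattern
survive in `z_H`. Truncation keeps the leading components; no learned
projection is involved.

**Quantum feature map (QFM).** Each of the three vectors passes through its
own map (parameters are not shared across branches, since input dimensions
may differ):

    θ  = W z + b               phase projection, θ ∈ R^P
    c  = cos θ,  s = sin θ     trigonometric embedding
    h₁ = (cos θ) U             phase-domain interaction, h₁ ∈ R^r
    h₂ = sin(zᵀV)              input-domain interaction, h₂ ∈ R^r
    h  = h₁ ⊙ h₂               low-rank multiplicative interaction
    f̃  = [c; s; h]             extended representation, R^{2P+r}
    f  = W₀ f̃ + b₀             output projection, R^P
    ψ  = f / (‖f‖₂ + ε)        norm scaling

The scaling gives `‖ψ‖₂ = ‖f‖₂/(‖f‖₂+ε) ∈ [0, 1)`, strictly inside the
unit ball and approaching the sphere as `‖f‖₂/ε → ∞` — the classical
analogue of a unit-norm state vector, and a useful Lipschitz-style control
on token magnitude during training.

The parse of the interaction terms deserves a note: `h₁` applies the cosine
*before* the projection by `U` (θ is already defined, so `cos θ` is the
natural operand), while `h₂` applies the sine *after* projecting `z` by `V`
(honouring the parenthesization `sin(zᵀV)`). The alternative reading — the
trig function after projection in both terms — is available via
`QFMParams.alt_phase_interaction` / `FusionConfig(alt_phase_interaction=True)`
and is covered by the same oracle tests.

**Token sequence and attention.** The three `P`-dimensional tokens form
`T = [t_A; t_B; t_H] ∈ R^{3×P}`, processed by a single multi-head
self-attention layer: per head, `Attention(Q,K,V) = softmax(QKᵀ/√d_k) V`
with `d_k = P / n_heads`; heads are concatenated and projected by `W_O`.
There is deliberately no residual connection and no layer norm: the fusion
layer is a single attention block, not a transformer encoder.

**Classifier head.** Attended tokens are mean-pooled (configurable to
flattening), passed through one hidden layer with ReLU, dropout (inverted,
inactive at inference), and a softmax over the `K` classes.

## Training

Mean cross-entropy `L = −(1/N_b) Σ log p_{n,y_n}` with the true-class
probability clamped below at 1e−12; AdamW-style decoupled weight decay
(decay applied to matrices only, not biases); per-step cosine annealing
`lr(t) = lr₀ · ½(1 + cos(πt/T))` over all `epochs × steps_per_epoch` steps
with no warm restarts; early stopping and checkpoint selection on
validation **macro** F1 (patience 3 epochs by default), while model
*comparison* uses **weighted** F1. Backbones stay frozen throughout, so
gradients are only required for the fusion parameters; the backward pass is
hand-derived and verified against central finite differences in the test
suite.

Defaults mirror the study recipe: 10 epochs, batch 32, lr 1e−4,
weight decay 1e−2 (conventional for decoupled-decay optimizers; the source
recipe does not state a value), `P = 256`, `r = 32`, 4 heads, 768-d
backbone features, 224×224 inputs. At desk scale — a few hundred samples
and `P` in the tens, as used throughout the tests and the acceptance
script — 1e−4 over so few optimizer steps barely moves the parameters, so
those runs use lr 3e−3; this is a problem-size adaptation, everything else
in the recipe is unchanged. Unstated quantities fixed here: MLP hidden
width 256, dropout 0.3, `ε = 1e−6`, Glorot-uniform initialization with
zero biases under a fixed seed.

## Preprocessing and splits

Channel statistics use the population divisor `NHW` and are computed over
the **full** image set by default, matching the protocol this package
reproduces; note this leaks test statistics into normalization —
`stats_from: train` computes them on the training split only. A zero-variance
channel is guarded with `σ + 1e−8`. Images are bilinearly resized to the
target square size before statistics.

The partition is 80/20 train/test with 10% of the remaining training data
as validation. The test share is rounded **per class with a ceiling rule**
(every class, however rare, is represented in the test set); with plausible
class sizes summing to 3176 this realizes a 636-image test set, matching
the reported study split. The validation share is drawn globally from the
pooled, shuffled training remainder with round-half-up (N=100 therefore
gives 72/8/20). Whether the original protocol stratified its splits is not
stated; stratification is the default here because the rare class is small.

## Backbones

The registry treats a backbone as a named, frozen callable from a
normalized image batch to an `(n, feature_dim)` matrix. The shipped
extractors are small deterministic NumPy descriptors — blockwise channel
means/stds, gradient-magnitude statistics, or both — followed by a fixed
random projection (seeded from the backbone name) and tanh. They are not
CNNs and make no claim of representational power; they exist so that
selection, fusion, training and evaluation run end-to-end in seconds on one
CPU. Pretrained architectures can be registered through the same contract.

Candidate ranking fine-tunes a linear softmax probe per candidate with the
standard recipe and compares weighted F1 on the validation split (scoring
on the held-out test split would leak it into model selection).
`select_top_two` breaks F1 ties by higher accuracy, then lexicographic
name, and returns the winning scores best-first (the best becomes
Backbone A).

## Synthetic data

`generate_images` draws 5-class RGB images whose class signal has three
components, all scaled by `signal_strength ∈ [0, 1]`: blob count (1..K),
sinusoidal texture frequency, and a fixed per-class ±1 coarse brightness
layout on a 4×4 grid. At `signal_strength = 0` the class-conditional
distributions are exactly identical (verified by a seeded two-sample test).
Defaults: 40 images per class, 224×224, additive pixel noise sd 12 (8-bit
units) — a deliberately moderate noise level that leaves the classes
separable but not trivially so at default signal strength.

`generate_feature_fixture` draws class-conditional Gaussian clusters in two
views with centroid distance proportional to `separation`.
`generate_interaction_fixture` is the adversarial case for late fusion:
class `k` has a ±1 code `c_k`; each sample draws i.i.d. signs `ε` and
returns view A = `ε` + noise, view B = `ε ⊙ c_k` + noise. Each view is
marginally sign-symmetric regardless of class — *no* classifier on a single
view can beat chance — while `A ⊙ B ≈ c_k` decodes the class exactly. This
is the regime the Hadamard token is built for, and the end-to-end
acceptance check uses it: the fused model reaches ≈99% where single-view
linear baselines sit at ≈20%.

What the generators do **not** emulate: CT physics, Hounsfield units,
anatomy, inter-patient variability, class imbalance, annotation noise.
Passing tests demonstrate that the implementation is faithful and that the
architecture can exploit multiplicative cross-view structure; they say
nothing about clinical performance on real CT data.

## Numerical choices and degenerate inputs

- ψ at `f = 0` is exactly 0 (0/(0+ε)); the backward pass guards the norm
  with a 1e−300 floor.
- Softmax is computed with max-subtraction; cross-entropy clamps at 1e−12.
- Zero-division in per-class metrics (a class never predicted or absent)
  yields 0 with a `RuntimeWarning`.
- Support-weighted recall equals accuracy by construction; the metrics
  module asserts nothing silently but the identity is covered by tests
  against an independent reference implementation.
- Determinism: every stochastic component (generators, shuffling, dropout,
  init) draws from `numpy.random.SeedSequence`-spawned streams keyed by one
  integer seed; reruns are bit-identical.

## Known limitations

- The shipped backbones are descriptors, not learned networks; absolute
  accuracies on the synthetic data do not transfer to any real task.
- Training is single-threaded NumPy; fine for `P ≤ 256` and thousands of
  samples, not for ImageNet-scale work.
- The published per-class test counts the package's split rule reproduces
  (636 of 3176) rest on assumed class sizes; the source's own per-class
  figures are internally inconsistent by one image, which is documented,
  not resolved.
- One attention layer over exactly 3 tokens: attention here is a learned
  reweighting of three views, not sequence modelling.
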