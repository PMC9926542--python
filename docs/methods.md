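# Methods

## Architecture

The model is a U-shaped encoder–decoder over rank-5 feature volumes
`[batch, H, W, D, C]` (channels last). Input resolutions must be multiples
of 32: the encoder downsamples by 4, 2, 2, 2, and the attention window per
axis is `input_dim / 32`, so the deepest stage holds exactly one window per
axis and all merges divide evenly.

**Windowing.** Windows and the tokens inside them are enumerated in
row-major order over `(H/wh, W/ww, D/wd)` and `(wh, ww, wd)`; partitioning,
the shift mask and the inverse stitch share this order. The forward cyclic
shift rolls content toward the origin (voxel `(i,j,k)` moves to
`((i−s_h) mod H, …)`), matching the convention of the 2D/video shifted-window
transformers; the inverse rolls back. The shift mask is built by labelling
every voxel with its pre-shift window id, rolling the label volume, and
masking token pairs whose labels differ. Masked scores receive a finite
additive penalty of −10⁴ rather than −∞ so that softmax underflows to ~0
without any risk of NaN under reduced precision. With zero shift the mask is
identically zero and the shifted pass equals the plain one bitwise.

**Attention.** Per window, multi-head scaled dot-product attention with
separate learnable Q/K/V projections (bias enabled) and an output
projection. `head_dim` defaults to `C / heads`; with the default channel
schedule (below) this is 32 everywhere and all projections are square.
A learnable relative-position bias table per head (one entry per 3D offset
in a `(2·w_max−1)³` table, default `w_max = 4`) is added to the scores;
smaller windows index a sub-block of the same table, so one set of weights
serves inputs from 32³ to 128³. The bias can be disabled in the config — the
oracle tests run without it so the reference computation stays closed-form.

**Blocks.** The transformer block applies, in order: LN → W-MSA-3D,
LN → MLP, LN → SW-MSA-3D, LN → MLP — with the residual branch carrying
`LN(X)` rather than `X`. That residual-from-LN form is implemented literally
as the block is defined here; because it deviates from the conventional
pre-norm transformer and may be a transcription artifact in the source
design, `residual="identity"` switches to the standard `X + f(LN(X))` form.
Both satisfy every structural test; the literal form is the default.
The MLP is token-wise `C → 4C → C` with exact (erf-based) GELU.

The convolution block runs two rounds of depthwise-separable convolution
(per-channel `k³` depthwise + `1×1×1` pointwise) → LayerNorm → PReLU
(per-channel slope, init 0.25), then gates the block input multiplicatively:
`Y = branch ⊙ X`. The depthwise kernel defaults to `k = 1` — the literal
reading of the block's description — and is configurable (`k = 3` gives a
genuinely spatial local branch; implemented as a weighted sum of zero-filled
shifts, so no general convolution routine is needed).

**Stages.** Each encoder stage is (merge or embed) → transformer stack ∥
conv block → element-wise sum; both branches read the post-merge feature.
Decoder stages expand by 2, add the same-level encoder output (element-wise
skip; channel counts match by construction), and apply the same parallel
extraction. The first stage's "merge" is the ×4 patch embedding. A final
factor-4 expansion (96 → 96) precedes the linear class head. Per-axis, the
cyclic shift is disabled at stages where the token grid equals the window
(a single window per axis has no neighbor to exchange with; the masked
computation would reduce to the same restriction at extra cost).

## Channel schedule and the parameter budget

The printed head schedule (3, 6, 9, 12) cannot divide doubling channels
(96 → 768): 384/9 is not an integer, and Q/K/V could not be square as
specified. Two resolutions were considered:

* decouple `head_dim = 32` from the channel count and keep channel doubling —
  this makes the inner attention width `32·heads`, but the resulting model
  carries ≈ 56 M parameters, far above the reference budget of 33.7 M;
* set channels to `32 × heads` = (96, 192, 288, 384) with square projections —
  the literal reading of the attention equations — which lands at 33.82 M
  (full) and 32.99 M (pure variant).

The second is the default (the config exposes both `head_dim` and
`channel_multipliers`, so the decoupled variant remains constructible). The
residual gap to the reference counts — +0.4% on the full model, −1.8% on the
conv-free one — reflects unpublished internals of the reference
implementation (notably its conv-branch composition: the reference full/pure
difference of ~0.12 M is smaller than any branch containing a full C×C
pointwise map at these widths, ~0.83 M here). What is exactly reproducible
is kept exact: stage depths, head counts, the downsampling schedule, and the
identity `count(full) − count(pure) = conv-branch ledger`, which the test
suite asserts to the parameter.

## Losses, metrics, labels

Soft dice loss: `1 − mean_c (2·Σ p·t + ε) / (Σ p + Σ t + ε)` with
`ε = 10⁻⁵` in numerator and denominator, probabilities from per-channel
sigmoid (the three channels overlap by construction, so this is multi-label,
not softmax). The hard dice is `2TP/(2TP+FP+FN)`; when both prediction and
reference are empty the score is defined as 1.0 (a correct empty prediction
is not penalised). Labels {0, 1, 2, 4} map to channels by logical OR:
ET = {4}, TC = {1, 4}, WT = {1, 2, 4} (BraTS convention). The alternative
mapping ET = {2}, TC = {2, 4} appears in one description of the reference
protocol and is selectable (`mapping="paper"`), but it conflicts with the
label legend used everywhere else and with ET ⊆ TC nesting, so it is not the
default. The inverse conversion resolves by specificity (ET → 4, then
TC → 1, then WT → 2), which also gives non-nested predictions a defined
label.

## Training and inference protocol

AdamW (β = 0.9/0.999, weight decay 0.01 excluding norms, biases, PReLU
slopes and bias tables), learning rate 3e-4, physical batch 1 with gradient
accumulation (default effective batch 16), random crops with sides multiples
of 32, early stopping on mean validation dice with patience 10, per-epoch
CSV logging, seeded and bit-reproducible on one device; checkpoints carry
weights, the full model config and optimizer state. Inference tiles the
volume with stride `⌊roi·(1−overlap)⌋`, snaps the final tile flush to the
border, zero-pads volumes smaller than the ROI (cropping afterwards), and
averages sigmoid probabilities with uniform weights (Gaussian blending is
available behind a flag). A single-tile volume reproduces the direct forward
pass to float32 round-off.

## Desk-scale study conditions

The phantom study that the test suite and the acceptance script run uses:
40 training and 10 held-out phantoms at 32³, the width-reduced configuration
`embed_dim = 24` (channels 24/48/72/96; every other architectural choice
unchanged), accumulation 1 (each crop is an optimizer step — 40 steps per
epoch is what lets dice-loss training converge in ~30 epochs), 30 epochs
maximum. At 32³ the window policy gives windows of one token, so the
transformer branches act token-wise and the segmentation signal is carried
by the multiscale encoder–decoder and the conv gating; this is the intended
degenerate limit of the window policy, not a special case in the code.
Typical held-out results (seed 1): WT dice ≈ 0.86, mean dice ≈ 0.86 for the
full model, with the conv-free ablation ≈ 0.15 behind on mean dice — the
same ordering as the reference ablation, at desk scale.

## Synthetic phantoms

Each phantom is three strictly nested axis-aligned ellipsoids (necrotic
core = label 1 ⊂ enhancing rim = label 4 ⊂ edema envelope = label 2) on a
background, rendered into four contrast channels from a compartment × channel
mean-intensity table loosely shaped like T1 / post-contrast T1 / T2 / FLAIR
(rim brightest post-contrast, edema brightest FLAIR, core dark T1 / bright
T2), plus i.i.d. Gaussian noise (σ = 0.05). `PhantomSpec` validates that every
compartment differs from background by more than 2σ in at least one channel,
and that nesting is strict per axis. Dataset generation jitters centers
(±8% of the side) and radii (±15% per axis) deterministically per case seed;
the default templates leave margins so jitter cannot break nesting. The
32³ training template uses radii (2.5–3.5 / 4.5–5.5 / 7.5–9.5): shells
thinner than ~2 voxels fall below the 4-voxel patch granularity and are not
learnable at this resolution, so compartment shells are kept several voxels
thick.

Ellipsoids give closed-form volume oracles ((4/3)π·a·b·c, asserted within
10% of the voxel count). The phantoms deliberately do not emulate MRI
physics — no bias fields, partial-volume texture, anatomy, multi-site
variation or irregular tumor morphology. Passing the phantom study shows the
optimisation loop, loss, architecture wiring and inference are sound; it
does not predict dice on real BraTS data, which is out of this package's
test surface.

## Numerics

All tensors are float32; softmax subtracts the row max before
exponentiation; LayerNorm uses ε = 10⁻⁵ over the channel axis; GELU is
exact (erf). The autodiff engine is a reverse-mode tape over numpy with
broadcasting-aware accumulation; gradients of every operation are verified
against central differences in the test suite. Weight init is truncated
normal (σ = 0.02, clipped at 2σ) from a generator seeded by the model
config, so identical configs give identical models and training runs are
bit-reproducible.

## Limitations

No GPU path and no mixed precision — the full model trains far too slowly on
CPU for real data; the package's training claims are desk-scale by design.
No padding support for non-multiple-of-32 inputs (explicit rejection instead
of silent border semantics). Windows larger than the configured bias-table
maximum require rebuilding the model. Hausdorff distance, significance
testing and comparison baselines are out of scope; the per-case dice CSV is
the hand-off point for external statistics.
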