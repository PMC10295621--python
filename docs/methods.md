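# Methods

## Problem setting

Binary semantic segmentation of medical photographs and scans — skin-lesion
dermoscopy, breast ultrasound, gastrointestinal endoscopy — under a hard
budget on model size and compute, so that inference can run in real time on
modest hardware.  The model maps an RGB image `x ∈ [0,1]^{3×H×W}`
(H, W divisible by 32; the canonical working size is 256×256) to a
per-pixel foreground probability `p ∈ [0,1]^{1×H×W}`.  Training minimises

    L(p, y) = Dice(p, y) + 0.5 · BCE(p, y)

with soft Dice `1 − (2Σpy + ε)/(Σp + Σy + ε)`, ε = 1, and pixel-mean binary
cross-entropy on probabilities clipped to `[10⁻⁷, 1 − 10⁻⁷]`.  Evaluation
uses IoU, recall, precision and F1 from pixel confusion counts at threshold
0.5; the algebraic identity `F1 = 2·IoU/(1 + IoU)` holds exactly and is
property-tested.

## Architecture

A 16-stage encoder–decoder.  The encoder has five levels, channel schedule
3 → 16 → 32 → 128 → 160 → 256 (width capped at 256), each level halving
resolution; the decoder mirrors it with ×2 bilinear upsampling after every
stage.  The first three levels are convolutional LDA blocks (LDA-A at level
1, LDA-B with channel attention at levels 2–3); the two deepest levels are
axial tokenized-MLP (LMLP) blocks behind a 3×3 patch-embedding convolution
(stride 2 in the encoder, stride 1 in the decoder).  Same-resolution
encoder features are fused into the decoder by **elementwise addition**
after a 1×1 channel-matching convolution — never concatenation, which keeps
every stage's output width equal to its configured channel count.  The head
is a 1×1 convolution to one channel plus a sigmoid.

### LDA block (variant A)

For input X with `a` channels and output width `b`, all at the stage's
input resolution:

* Part I: `P₁ = ReLU(BN(Conv₁ₓ₁(X)))`; `P₂ = BN(DWConv₅ₓ₅(P₁))`;
  projection `S = BN(Conv₁ₓ₁(X))`; `P₃ = ReLU(P₂ + S)`.
* Part II: `Q₁ = ReLU(BN(Conv₁ₓ₁(P₃)))`; a depthwise asymmetric pair
  `Q₂ = BN(DWConv₅ₓ₁(BN(DWConv₁ₓ₅(Q₁))))`;
  shortcut `Q₃ = Q₂ + BN(DWConv₃ₓ₃(P₃))`; output `Y = ReLU(Q₃ + S)`.

When a stage downsamples (encoder), a 2×2 max-pool closes the block, so
the convolutions see the full-resolution map.  The final residual reuses
the Part-I projection `S` of the input: the raw input cannot be added
(channel mismatch), and sharing the projection keeps the block at exactly
two `a→b` convolutions.  Convolutions carry no bias where a BatchNorm
(ε = 10⁻⁵, momentum 0.1) follows.

### LDA block (variant B)

Identical, with squeeze-and-excitation applied to `P₃` (after the first
ADD): squeeze = per-channel global average; excitation =
`σ(W₂ ReLU(W₁ z))` with bottleneck `C → C/r → C` (biased linear maps);
the block input is rescaled per channel by the resulting weights in
[0, 1], so the SE output never exceeds its input in magnitude.

### LMLP block

Channel- and shape-preserving, at the stage's working resolution:
channels are split into five groups shifted by `s·(−2,−1,0,1,2)` pixels
along the **width** (zero-filling vacated pixels, default step s = 1), then
projected by a biased 1×1 tokenizer to give tokens `X_T`.  A per-token MLP
(`1×1 conv → GELU → 1×1 conv`, hidden width `ratio · C`) mixes channels,
a 3×3 depthwise convolution restores locality, and the first optional ADD
fuses `X_T` back in.  The same sequence repeats along the **height**
(shift, token MLP, depthwise conv) with a second optional ADD, followed by
a residual connection to the block input and layer normalisation over
channels (ε = 10⁻⁵).  The two ADD switches (`enable_add1`, `enable_add2`)
expose the feature-fusion ablation; disabling them changes values, never
shapes.

### Variants

`build_variant` provides: `lcmunet` (canonical); `all_lda_a` (every block
stage an LDA-A at the same channel schedule, downsampling via the block's
pool — no patch embeds); `lda_a_plus_b` (LDA-B everywhere except level 1,
i.e. stages 1 and 14, which stay LDA-A — SE over the 3-channel stage-14
output could not satisfy the divisibility constraint anyway);
`lda_a_plus_lmlp` (MLP levels kept, all LDA-B demoted to LDA-A); and
`unet_baseline`, the classic 5-level UNet (widths 64…1024, two 3×3
convolutions per level, transposed-convolution decoder, concatenating
skips, binary head) used as the complexity reference.

## Calibration of under-specified hyperparameters

The block description leaves several structural constants open: the
depthwise kernel (5×5), the asymmetric kernel length (5), the Part-II
shortcut kernel (3×3 depthwise), the sharing of the input projection in
the final residual, the SE reduction policy (r = 2 for C ≤ 128, r = 4 for
wider stages — the same order as the SE-width ablation range the design
explores), and the token-MLP hidden ratio (0.25).  These defaults were
fixed **jointly** by requiring that the assembled models land on the
reported complexity figures under the MAC = 1 convention:

| model            | reported     | this implementation |
|------------------|--------------|---------------------|
| full model       | 1.49 M       | 1.504867 M (+1.0%)  |
| full model       | 0.49 GFLOPs  | 0.4809 G (−1.9%)    |
| all-LDA-A        | 0.51 M       | 0.514059 M (+0.8%)  |
| LDA-A + LDA-B    | 0.62 M       | 0.608723 M (−1.8%)  |
| UNet baseline    | 31.04 M      | 31.037633 M         |

No single-knob reading reproduces all five figures at once; in particular,
computing the LDA convolutions at the stage's input resolution (pool at
stage end) is the only resampling placement compatible with both the
parameter and the FLOP totals.  Every count is also verified against an
independent closed-form formula written from the kernel shapes alone.

## Complexity conventions

FLOPs are multiply-accumulates (1 MAC = 1 FLOP) of convolutions and linear
maps only, `k²·(C_in/g)·C_out·H_out·W_out` per convolution, traced through
a real forward pass; normalisations, activations, pooling, bilinear
interpolation and elementwise additions are excluded, and transposed
convolutions are charged at output resolution — the convention of common
profilers, and the only one consistent with the reference UNet figure
(54.74 GFLOPs at 256×256; this accounting yields 54.60 G, the remainder
being exactly those excluded pointwise ops).  Parameters are enumerated
trainable scalars, including normalisation affines.

## Training recipe

Adam (β = 0.9/0.999, coupled L2 weight decay 5·10⁻⁴), initial learning
rate 10⁻³ decayed per iteration by the polynomial schedule
`lr₀·(1 − t/T)^0.9`, batch size 8, 100 epochs by default, online
augmentation (rotation ±30°, zoom 0.8–1.2, brightness/contrast ±0.2 on the
image only, random crop 0.8–1.0 of the side resized back; the identical
geometric transform is applied to image and mask, the mask re-binarised at
0.5 after nearest-neighbour warping).  Of the 80% train pool, 1/8 is held
out for validation; the checkpoint with the best validation IoU is kept.
Checkpoints embed an architecture fingerprint and loading refuses a
mismatch.  Weights use Kaiming-uniform fan-in initialisation; the head
bias starts at −2 (the logit of ≈12% foreground), the usual
background-prior initialisation for class-imbalanced dense prediction —
without it, short training runs spend their first tens of steps
un-learning the 50/50 prior.  All randomness (init, shuffling,
augmentation) derives from one integer seed; bit determinism is promised
per platform.

## Numerical backend

The network runs on a small reverse-mode autodiff engine over float32
numpy arrays: convolutions via im2col + BLAS matmul (depthwise kernels via
shift-and-accumulate, pointwise via channel matmul), exact-erf GELU,
overflow-safe sigmoid, dense separable matrices for ×2 bilinear
interpolation (half-pixel centres), and batch/layer normalisation with the
standard analytic backward.  Every operation's gradient is checked against
central differences on small inputs; max-pool, whose subgradient is not
numerically differentiable at ties, is checked against its scatter law
instead.

## Synthetic data

The generator emulates the coarse statistics that drive binary lesion
segmentation: a low-frequency textured skin-toned background, a union of
1–3 overlapping ellipses as foreground with a contrast offset of random
sign (bright or dark lesions) drawn from 0.25–0.45, Gaussian boundary blur
(σ = 1.5), additive Gaussian noise (σ = 0.03), and thin dark curvilinear
hair strokes.  The mask is the exact pre-blur ellipse union; lesion area
is constrained to 5–30% of the frame with bounded retries.  The dataset is
a pure function of its configuration.  It does **not** emulate speckle
physics of ultrasound, specular highlights of endoscopy, colour charts,
rulers, vignetting, or multi-lesion scenes; tests passing on it
demonstrate that the architecture, losses, metrics and training loop are
correct and that the model can fit segmentation structure — not that
clinical-grade accuracy transfers to real datasets, which requires the
original corpora and GPU-scale training and is out of scope here.

## Problem sizes used in the test suite

Accounting checks build full models (seconds).  The trainability check
overfits the full model on 8 synthetic 128×128 samples for 200 Adam steps
(batch 8, no augmentation, seed-pinned) and requires training IoU > 0.95;
it reaches ≈0.99.  Unit and property tests use 48–64 pixel images and
blocks of 4–32 channels.

## Known limitations

Single foreground class only; inputs must be divisible by 32; no
GPU path (pure numpy — training beyond desk scale is impractical);
wall-clock inference latency is hardware-bound and deliberately not
modelled; dataset-level accuracies on the public corpora are not
reproduced at desk scale.
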