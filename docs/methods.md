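# Methods

This note records the models, parameter choices and known limitations of
the package, in the order data flows through it.

## The speckle phantom

The phantom emulates an apical four-chamber echocardiographic view. A
tissue-class map is rasterised first: an annular sector (apex at top-centre,
default opening 80°, radii 6%–95% of the frame) containing four elliptical
blood pools — two ventricles above two atria — surrounded by a myocardial
wall obtained by Chebyshev dilation of the chamber set (default 3 px).
Geometry is specified in normalised coordinates and jittered per sample from
the seed; configurations whose chambers (plus wall) would leave the sector
raise an error naming the offending ellipse.

Ultrasound texture follows the classic point-scatterer model: scatterer
positions are uniform in the frame (default 0.5 scatterers/px²), each
carries a class-dependent amplitude (muscle 1.0, blood 0.06, faint far-field
0.25) multiplied by a unit-Rayleigh draw and a random phase; the complex
field is blurred with a Gaussian point-spread function (σ = 1.1 px),
envelope-detected, log-compressed over a 40 dB dynamic range, masked to the
sector and mapped to [−1, 1]. This is deliberately the minimal model with
the right first-order statistics — fully-developed speckle with
class-dependent brightness. It does not model beamforming, attenuation,
refraction, clutter, papillary muscles or cardiac motion, so passing tests
say nothing about those phenomena.

The sketch is a line drawing of the chamber outlines, the myocardial
contour and the sector boundary, with values −1/+1. The default stroke
width is 2 px: at 64 px working resolution a 1-px stroke is relatively far
thinner than the strokes in real teaching sketches, and — more importantly —
the 10-block U-Net below downsamples from its very first layer, so 1-px
targets sit at its localisation limit and every overlap metric saturates
near zero regardless of training. Stroke width is configurable.

Dataset-level variability: the experiment harness draws per-sample
anatomy and acoustics (geometry jitter, sector angle ±5–8°, scatterer
density ±40–60%, blood amplitude, PSF width, compression range) to emulate
inter-patient and inter-acquisition variation; invalid draws are rejected
and redrawn deterministically. Without this the phantom set is essentially
one heart and a handful of annotated pairs already covers the whole
distribution, which misrepresents the few-shot problem.

The auxiliary segmentation set for parent pretraining uses the same speckle
renderer over random primitives (ellipses, rectangles, annuli, wedges) of
three foreground classes, with an optional 2-px outline class analogous to
the void boundary band of public segmentation benchmarks; the harness
enables it so the parent learns boundary labelling.

## Networks

All tensors are float64 numpy arrays in (N, C, H, W) layout; images live in
[−1, 1]. The layer stack (convolution, transposed convolution, batch norm,
relu/tanh/sigmoid, Adam) implements explicit backward passes, each
gradient-checked against central finite differences.

* **G_S** — 10-block U-Net: five down blocks (conv k3 s2 p1 + BN + relu),
  five up blocks (deconv k4 s2 p1 + BN + relu), skip concatenation between
  symmetric blocks, tanh head (or an n-class logit head for segmentation
  pretraining). Channel widths double from `base_channels` (default 32;
  experiments use 8) capped at 256. Inputs must be divisible by 32 so the
  five halvings are exact.
* **S2U decoder** — 4 deconv blocks from a (64, 4, 4) latent grid to 64 px,
  tanh last; **encoder** — stride-2 conv blocks mapping a sketch onto the
  decoder's latent grid. Attaching the encoder to a pretrained decoder
  copies the decoder bits verbatim and tags their provenance "parent".
* **D_S, D_U** — 5 stride-2 conv blocks over the channel-concatenated
  (candidate, condition) pair, sigmoid patch score map (2×2 at 64 px),
  averaged inside the losses. The first block carries no batch norm: at
  batch size 1, first-block normalisation acts as instance norm and erases
  the global intensity level, and a discriminator blind to brightness
  cannot teach the unconditional decoder the dark-background intensity
  distribution (the pretraining test checks exactly this: the generated
  mean must move toward the data mean).

## Losses

The discriminator objective is −E log D(real) − E log(1 − D(fake)); the
generator uses the non-saturating −E log D(fake) (the minimax form stalls
early training). Scores are ε-clamped at 1e−7 for finite values.
Expectations are batch means; patch maps are averaged before the log, so
loss values are batch-size invariant. The sketch objective adds an
unweighted L1 term behind a toggle; the ultrasound objective adds
λ₁ = 6e−3 perceptual, λ₂ = 2e−8 total-variation and λ₃ = 1 L1 terms.
The perceptual distance uses a bundled fixed random-weight convolutional
stack (three stride-2 conv+relu stages, seeded, never trained; taps after
stages 2 and 3, mean-squared, averaged) — random convolutional features
preserve enough geometry for a feature-space metric while keeping the
package fully self-contained; an identity extractor reduces the loss to
pixel MSE for testing. Class-balanced cross-entropy uses per-batch weights
w_c = 1 − n_c/N and a weighted per-pixel mean.

## Training

Adam with betas (0.5, 0.999) throughout. Default learning rates are 2e−3
for generators and 5e−4 for discriminators: at the few-hundred-step budgets
this package targets, the conventional 2e−4 barely moves a tanh-headed
generator (the 1-shot overfit check in the acceptance suite quantifies the
convergence the defaults must deliver), and an equal-rate discriminator
overpowers the generators, swamping the unweighted L1 term. Batch size 1 (the few-shot regime); one optimisation
step processes one training pair round-robin, so equal step budgets mean
equal update counts for every k. Per step the order is: forward both
generators, update D_S, update D_U, then one joint generator step on
L_total = L_S + L_U with both updates applied together. Real/fake targets
are hard 1/0. A non-finite forward or loss aborts the run and returns the
last finite-step weights. The trainer snapshots (weights + Adam moments +
step counter) resume bit-exactly.

U-Net transfer copies every parent block except the segmentation head
(whose channel count differs); the head is freshly initialised. A
`finetune_lr_scale` knob can slow transferred parameters (discriminative
fine-tuning); its default is 1.0 because slowing the trunk measurably
traps the parent init at this scale.

## Evaluation

Sketch outputs are binarised at 0 (strict >, the midpoint of [−1, 1]) and
scored with DICE, IOU and VOE = 1 − IOU; both-empty masks count as perfect
agreement. A signed relative volume difference is provided under its own
name and is never substituted for VOE. Synthesized ultrasound is scored
with PSNR (dynamic range 2, identical images report ∞) and SSIM (11×11
Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03). Aggregates are unweighted
means over validation pairs, recomputed from the per-pair rows on demand.

## Problem sizes and observed behaviour

The package's study conditions are desk-scale by design: 64 px images,
8-channel networks in the experiment harness, a 55-pair annotated set split
10/45, 150 auxiliary segmentation images, 60 unannotated frames, parents
pretrained for 2000 (segmentation) and 300 (decoder GAN) steps, and
transfer budgets of 80–300 steps. A full pipeline runs in minutes on one
CPU.

Two qualitative claims are checked over 5 seeds in the acceptance suite.
The shots trend — final validation IOU of 10-shot transfer at or above
1-shot — reproduces robustly at these budgets. The transfer-benefit claim
— parent-initialised 5-shot training beating random initialisation at
equal budget — does **not** reproduce at this scale; the faithful check
remains in the suite and fails as measured. The likely reason is scale:
with 8-channel networks and a task learnable from five pairs in a few
hundred updates, generic pretrained features have no room to pay off
before from-scratch training converges, whereas the original setting
(deep networks, rich pretraining corpora, long fine-tuning) operates in
the opposite regime.

## Known limitations

No GPU path and float64 only — the layer stack is sized for 64–128 px
experiments, not production training. The phantom's realism limits are
listed above. Video I/O supports the containers the installed imageio
plugins decode without external binaries (GIF, multi-frame TIFF).
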