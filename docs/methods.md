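# Methods

## Problem and model

`medfuse` fuses a co-registered CT/MRI pair into one grayscale image that
keeps the CT's dense-structure content (bone, implants) and the MRI's
soft-tissue detail.  The pipeline is

1. **Siamese encoder.**  Both sources pass through the *same* weights:
   a 3×3 shallow conv, then four parallel branches of two 3×3 convs each.
   In the dense variant (`res2db`, default) the second conv of branch *i*
   consumes the concatenation `[f_1^2, …, f_{i−1}^2, f_i^1]`, so later
   branches see a growing receptive field and reuse earlier features; the
   plain variant (`res2b`) concatenates only `[f_{i−1}^2, f_i^1]`.  The four
   branch outputs are concatenated and merged by a 1×1 conv.  A mixed
   attention block then refines the stack: channel attention (global spatial
   max- and average-pooled descriptors through one shared
   reduce–ReLU–expand bottleneck, summed, sigmoid-gated per channel) and
   spatial attention (per-pixel channel max/avg maps through a 7×7 conv,
   sigmoid-gated per pixel) run in parallel and are merged by a 1×1 conv.
2. **Saliency fusion.**  The CT feature stack is collapsed to an activity
   map (channel-wise l1 norm), min–max normalised, quantised to `levels`
   (256) gray levels, and passed through the histogram saliency transform
   `f(v) = Σ_m count(m)·|v − m|` — a pixel is salient if its level is far
   from the bulk of the histogram, which on CT singles out the sparse,
   extreme-intensity dense structure.  The saliency map is min–max
   normalised again to give the weight map `w1 ∈ [0,1]`, and the fused
   stack is `γ·w1·F_CT + (1−γ)·w1·F_MRI + (1−w1)·F_MRI`.  Element-wise
   average/max/sum and per-pixel l1-softmax baselines are provided for
   comparison.
3. **Decoder.**  Five 3×3 convs narrowing 240→128→64→32→16→1 (default
   width), ReLU on the first four, none on the last; output clipped to
   [0,1] only at export.

All convolutions are stride 1 and zero-padded, so every stage preserves the
source resolution and the network is fully convolutional (any H×W ≥ 8).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.5 | CT share inside the dense-structure term; 1 → dense regions purely CT. The method itself does not pin this down; 0.5 treats modalities evenly. |
| `levels` | 256 | histogram resolution of the saliency transform (8-bit convention). |
| `mri_coefficient` | `convex` | reading of the dense-term MRI coefficient; `convex` = `(1−γ)·w1` keeps the three per-pixel coefficients summing to 1, `literal` = `(1−γ·w1)` is the alternative reading and makes the fused stack super-unit. Both ship because the choice is a genuine ambiguity. |
| `mu`, `phi` | 1, 1 | pixel vs gradient loss weight; no published values exist, equal weighting is the neutral choice. |
| `lr`, `batch_size` | 1e-4, 16 | published optimisation settings, kept as-is. |
| `reduction` | 16 | channel-attention bottleneck ratio (C → C/16 → C). |
| `dense_variant` | `res2db` | dense vs plain branch wiring, the extraction-block ablation switch. |

Encoder widths are not fully published; the default reading sets shallow
and per-branch channels to 60 so that four concatenated branches give the
240 channels the decoder's published schedule starts from.

## Numerical and design choices

* **Intensity domain.**  Images are floats in [0,1] internally; 0–255
  integer levels exist only where a histogram is defined.  Quantisation
  rounds half away from zero (0.5·255 = 127.5 → 128) — stated because it is
  a real boundary case.  RGB convenience input collapses via Rec. 601 luma.
* **Saliency re-normalisation.**  The saliency transform returns counts ×
  level distances (up to `(L−1)·P`); it is min–max renormalised before use
  as `w1`, otherwise `1 − w1` would be hugely negative and the fusion would
  not be a convex combination.  A constant activity map yields `w1 ≡ 0`
  ("no pixel is salient"), not NaN; min–max of a constant map is defined
  as all zeros throughout.
* **Gradient operator.**  ∇ in the loss is the 3×3 Sobel pair with
  whole-sample-symmetric (reflect) boundaries — the common choice in the
  fusion literature; a forward-difference variant sits behind
  `TrainConfig.grad_op`.
* **Autodiff.**  No deep-learning framework is used: the network runs on an
  in-package reverse-mode tape over numpy (`medfuse._autodiff`) providing
  exactly the needed ops (same-padded conv as one GEMM over an im2col
  matrix, ReLU, sigmoid, concat, global/channel pooling, broadcasting
  arithmetic).  Every gradient is finite-difference-checked in the test
  suite; runs are bit-reproducible on CPU for a fixed seed.
* **Weight init.**  Kaiming fan-in normal, biases zero, seeded.
* **Attention degeneracies.**  Per-channel and per-pixel gates are strictly
  inside (0,1) (sigmoid), so attention rescaling never flips feature signs;
  a spatially constant input makes max- and average-pooled descriptors
  coincide.
* **Metric conventions** (the metric family admits variants; these are
  fixed and config-exposed): MI in bits from 256-bin joint histograms; SF
  divides by the number of differences (M·(N−1) / (M−1)·N) and is reported
  on the [0,1] intensity scale; NCIE uses K = 3 variables and log base 256,
  with the pairwise nonlinear correlation coefficient computed on
  equal-frequency 256-bin marginals (`NCC = 2 − H_b(joint)`), which is
  exactly 1 for identical inputs and ≈ 0 for independent ones; PC uses a
  log-Gabor phase-congruency front end (4 scales, 6 orientations, minimum
  wavelength 3, multiplier 2.1, σ_onf 0.55) and multiplies the best
  source-vs-fused correlations of the congruency, maximum-moment and
  minimum-moment maps with unit exponents; Pearson r of a constant signal
  is 0, except that identical maps correlate at 1.

## The phantom generator

Real CT/MRI pairs are not shipped; a seeded generator emulates exactly the
complementarity the method exploits: the CT member is a bright ring
("skull", default level 0.95) over a flat interior (0.25), the MRI member a
dark ring over band-limited smooth texture (Gaussian-filtered seeded noise,
default correlation length 6 px) with optional bright lesions, plus
Gaussian pixel noise (σ = 0.01).  Both members share the same geometry
masks, so registration is exact by construction, and the ring mask is
recoverable by thresholding the noiseless CT midway between tissue and bone
level — which is how the tests verify that the saliency weight map is high
on dense structure.  Augmentation is crop plus right-angle rotation only
(no interpolation, registration trivially preserved).

What the phantoms do **not** model: CT/MRI physics, anatomy, partial-volume
effects, bias fields, or misregistration.  Passing tests therefore show the
pipeline's algebra, optimisation and directional behaviour — not clinical
fusion quality.

## Scale of the reference CPU study

`medfuse.profiles.CPU_STUDY` defines the experiment the test suite and
`scripts/acceptance.py` run: 100 phantom pairs at 64×64 (70 train / 15 val /
15 test), the narrow encoder profile (`NetConfig.small()`: 8 shallow/branch
channels, 32 encoder channels, decoder 32→16→8→8→4→1 — same topology as the
default), 50 epochs of Adam at lr 1e-4, batch 16, μ = φ = 1.  These sizes
were chosen so a single CPU core completes the study in minutes; the
full-scale settings (240-channel encoder, thousands of augmented pairs,
1000 epochs) are recorded in `FULL_STUDY` but not exercised.

## Known limitations

* At this study scale (≈450 Adam steps at the published lr of 1e-4) the
  reconstruction converges steadily but is still improving when training
  stops; held-out PSNR lands in the mid-20 dB range rather than the ≥30 dB
  a fully converged full-width model attains.  The loss history and PSNR
  are recomputed, not asserted away; see the acceptance output.
* On these phantoms the saliency strategy clearly beats element-wise
  averaging on mutual information, but not on spatial frequency: with
  γ = 0.5 the dense-structure term is at most an even CT/MRI mix (identical
  to averaging where `w1 = 1`), and the max-normalised weight map sits well
  below 1 over most of the ring, so averaging keeps the ring edges — the
  phantoms' dominant spatial-frequency content — at higher weight.  The SF
  advantage of saliency weighting relies on fine soft-tissue texture that
  the smooth-texture phantoms deliberately lack.
* Two source images only; single modality pair (CT/MRI-like contrast
  assumptions are baked into the fusion rule's direction).
* Metric values are not comparable across papers: the CC/MI/PC/NCIE/SCD
  family has unstandardised variants, and the conventions above are one
  defensible fixing.
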