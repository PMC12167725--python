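# Methods

## Problem and statistic

PSMA-targeted PET tracers accumulate physiologically in the renal cortex, so
the left/right split of renal tracer uptake tracks split renal function
(SRF) as measured by dedicated renography. `srfseg` automates that
measurement on co-registered PET/CT: a 3D U-Net labels every voxel as
background, left kidney or right kidney, and the left renal function
percentage is

    LRF% = 100 * sum(SUV over left-kidney voxels)
               / sum(SUV over left- plus right-kidney voxels).

LRF% is a ratio of SUV sums, which makes it robust to segmentation "style":
a reader (or model) that is consistently generous or tight changes both
sums nearly proportionally, so segmented volumes can differ by tens of
milliliters while LRF% moves by fractions of a percentage point. The
agreement module quantifies exactly this: per-kidney Dice and volume
differences, per-case LRF% differences, Spearman rank correlations and
Bland–Altman bias/limits of agreement across any set of sources.

All volumes live in a fixed anatomical convention (axis 0 increases toward
the patient's left), established at the NIfTI boundary, so "left kidney"
(label 1) is always anatomical left. The statistic is measured on the
native PET grid with labels mapped back by nearest neighbor, so no
interpolated SUV values enter the sums.

## Segmentation model

The network is an encoder–decoder U-Net over two input channels (CT in HU,
PET in SUV) resampled to a common 2.73 × 2.73 × 2.79 mm grid. Blocks are two
3×3×3 same-padding convolutions with instance normalization and ReLU;
channels double per level; downsampling is 2×2×2 max pooling and upsampling
a 2×2×2 transposed convolution with skip concatenation. Scores are raw; the
softmax lives in the loss and in argmax decoding (ties decode to
background). With deep supervision, a 1×1×1 score head is attached at every
decoder scale (the coarsest on the bottleneck) and each scale contributes a
class-weighted softmax cross-entropy against nearest-neighbor-downsampled
labels, with scale weights 1, 1/2, 1/4, … (normalized). The per-voxel loss
is combined as a weighted mean — kidney voxels weight 5, background 1,
divided by the total weight — so the loss magnitude is patch-size
invariant.

Input intensities are fed raw apart from a fixed affine rescale (HU/100,
SUV/10, on by default) that balances the two channels' dynamic ranges;
whether the original clinical model normalized PET intensities is unknown,
so the rescale is config-exposed.

The layers, backpropagation and the Nadam optimizer (adaptive moments with
a Nesterov lookahead, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) are implemented in
NumPy in channels-last layout; convolutions lower to shift-and-accumulate
BLAS products over cache-resident blocks. Every backward rule is pinned by
float64 dense oracles and finite-difference checks in the test suite.
Training is single-threaded and fully deterministic given the seed.

## Training recipe and profiles

Patches are cubes cut from the cohort with a 50% foreground bias (half the
patches are centered on a uniformly drawn kidney voxel; kidney-free cases
fall back to uniform sampling) — kidneys occupy ~1–2% of a torso volume, so
unbiased 160³ sampling would starve the foreground despite the 5× class
weight. Augmentation applies one affine (scale ∘ rotate ∘ shear ∘
translate) identically to CT, PET and labels (trilinear / trilinear /
nearest), plus HU-only intensity perturbations (shift ±50 HU, scale
0.9–1.1, smoothing σ ≤ 1.5 mm, noise ≤ 20 HU), each with probability 0.5.
PET intensity jitter exists behind a flag, default off, because perturbing
SUV would corrupt the quantity the model is trained to delineate.

The learning rate is constant within an epoch and decays geometrically,
lr(e) = lr0 · 0.985^e.

Two named profiles:

| parameter        | `full` profile | `desk` profile |
|------------------|-----------------|----------------|
| patch edge       | 160            | 32             |
| U-Net levels     | 4 (base 16)     | 2 (base 8)     |
| samples/epoch    | 10,000          | 200            |
| epochs           | 100             | 20             |
| batch size       | 2               | 8              |
| lr0              | 5e-5            | 2e-3           |

The desk profile is the package's scaled-down study condition: it sees
~250× fewer samples than the full profile, so its initial learning rate is
raised to 2e-3 to keep the optimizer's total traversal in a trainable
regime; the decay rule and everything else are shared. A full desk run
(simulate 24 cases, train on 16, evaluate on 8) takes roughly a quarter
hour on one CPU core.

Inference tiles a volume with 50%-overlapping patches and averages scores
in the overlaps, then keeps, per kidney class, only the largest
26-connected component (face, edge and corner adjacency). That cleanup
removes the known failure mode in which PSMA-avid lymph-node metastases are
mislabeled as a kidney; any kept component under 10 ml raises a non-fatal
warning in the result instead of changing it. Equal-size component ties
keep the component containing the smallest linear voxel index —
deterministic, and irrelevant in practice.

## Synthetic phantom

The phantom paints, on the scanner grid, an elliptical body in air, a bony
posterior midline rod (700 HU), liver/spleen-like moderate-uptake spheres
(SUV 3.5–4), two ellipsoidal kidneys (default semi-axes 20 × 16 × 32 mm)
with a bright cortex (SUV 25) and low-uptake pelvis core (SUV 5), a
high-uptake bladder (SUV 60), and optional para-aortic distractor lesions.
PET is blurred with a Gaussian point-spread function (default 4 mm FWHM),
then degraded with additive Gaussian noise and clamped at zero; CT gets its
own noise. The SUV palette is plausibility-driven — chosen to mimic the
qualitative contrast of [18F]PSMA-1007 images, where renal cortex and
bladder dominate — because no quantitative normal-kidney SUV reference was
available; every value is overridable.

Ground-truth labels and the true LRF% are computed from the painted field
*before* blur and noise, so they are exact and blur/noise effects on the
measured LRF% become quantifiable biases (at default settings, well under
2 ppt with the truth mask). Cohorts draw kidney size (±25%), uptake (±50%)
and position (±4 mm) per case and support the clinically motivated hard
variants: solitary kidney, hypoplastic (half-size) kidney, symmetric and
asymmetric low uptake. The body outline and spine are not decoration: a
32-voxel patch of a 64-voxel torso carries no absolute position, so
left/right assignment is learnable only from such global landmarks — as in
real torso images, where the body contour plays that role.

The surrogate reader perturbs the truth by a boundary shift of up to a
given number of 26-connected layers (fractional layers via random voxel
toggling). The shift is drawn once per reader and applied to both kidneys,
with a small independent per-kidney jitter: real readers differ mainly in
consistent generosity/tightness, which moves volumes a lot and LRF% very
little. Fully independent per-kidney shifts were rejected because, at
phantom scale, one full erosion strips ~40% of a kidney's bright cortex
shell and produces LRF% swings an order of magnitude beyond anything seen
between human readers.

What the phantom does *not* emulate: tomographic projection and
reconstruction (no sinograms, no regularized reconstruction artifacts),
attenuation, respiratory motion, anatomical texture, horseshoe or ectopic
kidneys, and pathological focal uptake beyond spherical distractors.
Passing the desk experiment therefore demonstrates that the pipeline's
machinery — recipe, losses, postprocessing, statistics — is correct and
learnable end-to-end, not that the desk-trained weights transfer to
clinical images.

## Numerical and design choices

- PET negatives are clamped to zero at load (SUV is nonnegative;
  reconstruction can produce small negatives).
- Resampling: trilinear for images, nearest neighbor for labels; the first
  voxel centers of input and output grids coincide, making same-spacing
  resampling an exact identity and label sets never grow.
- Out-of-field voxels from affine augmentation or patch padding are filled
  with ambient values: −100 HU, 0 SUV, label 0.
- Both-empty Dice is 1.0 (needed for the absent side of solitary-kidney
  cases); one-empty Dice is 0.0.
- Bland–Altman limits of agreement are bias ± 1.96 × SD with the n−1
  denominator.
- Differences are oriented first-minus-second source; reports collapse
  ordered duplicates onto the first-listed orientation.
- "Samples per epoch" counts patches, not optimizer steps.
- No validation-based early stopping or model selection: training runs a
  fixed number of epochs; per-epoch checkpoints can be kept.

## Limitations

The NumPy training core is CPU-bound and intended for desk-scale
experiments; full-size (160³, 100-epoch) training is expressed by the
`full` profile but is not practical without accelerator support. Clinical
performance numbers cannot be reproduced here because the underlying
patient data are not public; the package's evidence is the phantom's
analytically known ground truth plus the closed-form statistic checks. SRF
from PET is a relative measure only — it does not estimate absolute
function (GFR).
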