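# Methods

## Problem and model

Mastoid air cells vary enormously between people — in size, shape and
pneumatization — but are nearly mirror-symmetric between the two ears of
one person. Radiologists therefore read a mastoid AP view by comparing the
two sides: opacification ("haziness") of one mastoid relative to the other
is the tell-tale of mastoiditis, graded here as category 0 (normal, clear
air cells), 1 (mild, partial haziness) or 2 (severe, total haziness with
sclerosis). Category 3 (post-mastoidectomy) is inherently asymmetric and is
excluded from all symmetry computations; parsed label tables keep such rows
with an `excluded` flag so exclusion counts remain auditable.

The bilateral **symmetry grade** is `|category_right − category_left|` on
categories 0–2: grade 0 (concordant), 1 (one-stage difference), 2
(normal vs severe).

The model is a twin-stream CNN with a single shared parameter set:

* each 384×256 single-ear image passes through one shared stream of six
  pre-activation residual blocks with squeeze-and-excitation (SE) channel
  recalibration, ending in a 1×1 projection to 3 channels — a 12×8×3
  spatial **category evidence map** (one channel per category);
* each side's mastoiditis classifier applies per-channel Log-Sum-Exp (LSE)
  pooling, `lse_r(x) = (1/r) log mean exp(r x)`, followed by a softmax over
  the three categories;
* the **symmetry evaluation layer** takes the element-wise absolute
  difference of the two category maps; a learnable 1×1 channel map
  (category-difference channels → grade channels) followed by LSE pooling
  and a softmax yields the three-grade symmetry probability vector.

Training minimizes `CE_right + CE_left + 2·CE_symmetry`: the symmetry
cross-entropy is added to *each* side's loss and the two sums are added.
The factor 2 follows from that composition literally; a `symmetry_weight`
knob (default 1, applied per side) exists for sensitivity analyses. The
single-side baseline is one stream plus one mastoiditis classifier trained
with plain cross-entropy on individual ears.

Weight sharing plus the symmetric difference make side-swap equivariance
*exact*: exchanging the two input images swaps the two per-side outputs
bitwise and leaves the symmetry output unchanged. To preserve this at any
batch size, normalization is group normalization (statistics per sample,
never per batch) and inference has no stochastic layers.

## Architecture choices left open by the design contract

The fixed points are: six SE-residual blocks per stream, a 32× spatial
reduction to a 12×8×3 map, LSE pooling, shared weights, and the
absolute-difference symmetry layer. Everything else is this package's
choice:

* strides (1,2,2,2,2,2) and widths (16,32,64,128,256,256), with a final
  GroupNorm → ReLU → 1×1 convolution to 3 channels;
* pre-activation blocks (norm → ReLU → 3×3 conv → norm → ReLU → 3×3 conv →
  SE) with identity shortcuts, and 1×1 projection shortcuts (from the
  pre-activated input) where stride or width changes;
* SE reduction ratio 8 (floored at one hidden unit);
* LSE sharpness `r = 5.0`; the gradient of LSE pooling is the spatial
  softmax of `r·x`, so moderate `r` spreads training signal over the map
  while staying near-max pooling for localized evidence;
* the symmetry head's 1×1 channel map (default `linear`): the difference
  channels index *categories*, not grades, so a parameter-free head could
  not represent the grade semantics. A `direct` variant that pools the raw
  difference channels is available (`symmetry_head: direct`); with it, an
  exactly symmetric input necessarily yields uniform grade probabilities
  and zero grade CAMs.

## Implementation of the network

The layer stack (convolution via im2col, group normalization, SE blocks,
LSE pooling, dense layers) and its reverse-mode gradients are implemented
directly on numpy arrays in `mastsym.nn`, with explicit per-call caches so
one shared stream object can be applied to both sides of a batch and
accumulate gradients from both applications plus the symmetry path.
Gradients of every layer type are validated against central finite
differences in the test suite. Optimization is RMSprop
(`v ← 0.9 v + 0.1 g²`, `p ← p − lr·g/(√v + 1e-7)`), weights are
He-initialized, and cross-entropy uses a 1e-12 floor inside the logarithm.
Note that a normalization group must contain more than one element:
feature maps reduced to 1×1 with one channel per group are degenerate
(the normalized value is identically zero), which constrains minimum input
sizes for toy configurations (64×64 is the smallest used in tests).

## Preprocessing

Order of operations: read DICOM (rescale slope/intercept; MONOCHROME1
inverted so brighter = denser) → crop → resize → min-max normalize.
The right-ear crop is a 180 mm × 120 mm box (rows × columns, matching the
384×256 row×column resize) centred at (0.5·H, 0.25·W) pixels; fractional
centres are rounded half-up and boxes overhanging the frame by ≤10% of
their size are clamped inside (beyond that, a geometry error). The left
box is constructed as the exact column mirror of the right box rather than
by independently rounding the mirrored centre — this makes the
"reflect-and-recrop swaps the crops pixel-for-pixel" property exact for
every frame width. The left crop is flipped about its vertical axis,
both crops are resized bilinearly (no anti-aliasing, keeping flip/resize
commutation exact to floating point), and each half is min-max normalized
to [0,1] (robust to vendor-specific DICOM scaling; a zero-range crop
normalizes to zeros with a warning). The 768×256 vertical concatenation
(right on top) is the serialization of record; the network consumes the
two 384×256 halves.

## The phantom generator

The generator emulates exactly the statistics the method exploits, not
anatomy:

* per subject: a bone level (0.55 ± 0.05·`anatomy_variation`), a smooth
  mirrored background field, an air-cell region (feathered ellipse,
  semi-axes ≈ 50×35 mm jittered per subject), and a "blobby" cell texture
  (thresholded smoothed noise, cell scale 3.5–5.0 mm, coarse enough to
  survive the 4× downscaled network input);
* mirrored anatomical landmarks — a dense petrous-ridge band above the ear
  and a dark soft-tissue fade below the mastoid tip — anchor every crop's
  intensity range, so per-crop min–max windowing cannot cancel the disease
  signal (without them, the air cells themselves set the range and
  normalization divides the opacity contrast out);
* disease fills the cells toward opacity: air-cell intensity =
  bone − depth·cellness·(1 − opacity). Two subject-level nuisances are
  shared by both ears and therefore cancelled by contralateral comparison
  but confound unilateral reading: an opacity offset
  (sd `baseline_opacity_sd`) and a cell-depth factor
  (0.35·exp(0.35·`anatomy_variation`·z), the subject's pneumatization
  lucency) — judging haziness from one ear requires first estimating that
  subject's cell depth and density from texture. Per-category opacity means
  are `haziness_levels` (default 0.10/0.30/0.80); severe additionally
  brightens a sclerotic rim band (+0.15);
* the left half-frame is the mirror of the right, with the texture shifted
  by `asymmetry_jitter_mm` (default 0.4 mm) before thresholding; with zero
  jitter and zero noise a concordant subject is exactly mirror-symmetric;
* bilateral categories are drawn from a 3×3 `pair_distribution`
  (default mass 0.5 on concordant pairs, 0.35 on one-stage, 0.15 on
  two-stage differences), so the truth grade distribution is its
  pushforward under the absolute-difference map;
* additive Gaussian pixel noise (sd 0.02) is applied last, unmirrored.

What the phantom does **not** model: real air-cell morphology, projection
physics, scatter, positioning rotation/tilt asymmetry, age drift, and the
category-3 postoperative appearance. Tests passing on the phantom
demonstrate that the machinery implements the intended computation and that
the symmetry signal is exploitable when present; they say nothing about
clinical accuracy on real radiographs.

### Benchmark preset

`default_benchmark_params()` fixes the regime in which the symmetry design
has headroom: the normal→mild opacity step (0.18) is comparable to the
subject-level opacity spread (0.15), so mild disease is ambiguous from a
single ear but plain from the contralateral comparison, while severe
(step 0.70) is clear either way. A pixel-mean threshold oracle confirms
mild-vs-normal per-ear separability is well below severe-vs-normal.
Benchmark images are generated at 1.0 mm spacing (500×400 px frames,
180×120 px crops) and fed to the network at 96×64 (a 4× downscale of the
full-scale input) through a narrow stream (widths 4–24, SE reduction 4).

The benchmark experiment (`mastsym.benchmark`) trains both models on
600 subjects, selects checkpoints on 120 validation subjects (patience 3,
at most 10 epochs), and evaluates per-ear AUC on 200 test subjects, three
seeded replicates. It uses learning rate 1e-3 rather than the protocol default
1e-4: the benchmark budget is roughly thirty times fewer gradient steps
than a clinical-scale run, and at 1e-4 both models would remain far from
convergence at that budget, leaving the comparison uninformative. The
protocol defaults (RMSprop, lr 1e-4, batch 4, He initialization, 5:1
stratified split on symmetry grade) remain the package defaults.

## Statistics

* AUC is the Mann–Whitney statistic of the per-ear positive score
  `1 − p(normal)`; ears are treated as independent observations (two per
  subject), mirroring standard per-ear reporting; no within-subject
  clustering correction is applied by default.
* Dichotomization: an ear is called positive unless the normal category
  holds the strictly highest probability; an argmax tie involving normal
  resolves positive (screening favours sensitivity). The 3×3 confusion
  matrix uses the severity-preferring argmax for consistency.
* DeLong intervals/tests use placement (structural-component) variances
  with midrank tie handling; the paired one-sided test reports the
  upper-tail normal p-value for "AUC_A > AUC_B", returning 0.5 exactly
  when the paired difference is degenerate at zero.
* Clopper–Pearson intervals come from Beta quantiles (exact at k=0 and
  k=n); accuracy CIs use the same method for consistency.
* McNemar: exact binomial when the discordant total is below 25, else
  continuity-corrected chi-square (the degenerate b=c=0 case returns 1
  with a warning).
* Report percentages are rounded to one decimal.

## Class activation maps

A CAM is one channel of the pre-pooling evidence map (per-side category
maps, or the symmetry path's grade map), ReLU-rectified and bilinearly
upsampled to input resolution — no gradients. With the `linear` symmetry
head, grade CAMs are taken *after* the 1×1 grade mapping so channels
genuinely index grades. Panels render with a diverging blue–white–red map
whose midpoint is half the panel maximum (raw values are preserved in the
returned arrays; normalization is display-only).

## Numerical and degenerate-input conventions

* LSE pooling is computed with a max-shift; non-finite inputs raise.
* Probability-vector validation tolerance is 1e-6 on the sum.
* The stratified split rounds each stratum's validation count half-up and
  warns when a stratum has fewer subjects than the ratio total.
* Training aborts with a diagnostic on non-finite loss; histories record
  the per-epoch loss decomposition, and the identity
  `total = ce_right + ce_left + 2·ce_symmetry` holds at every step.
* Checkpoint selection and early stopping monitor the validation per-ear
  AUC of the dichotomized score by default (`monitor='val_auc'`) — the
  reported endpoint, applied identically to both architectures. Selecting
  on validation loss (`monitor='val_loss'`) is supported but mismatched
  for the bilateral model, whose validation objective is dominated by the
  doubly-weighted auxiliary symmetry term; the two rules can pick
  different checkpoints.
* Checkpoints are single `.npz` files carrying weights plus a JSON
  architecture summary; loading rebuilds the exact architecture.

## Known limitations

* The numpy training loop is CPU-bound; full-scale (384×256, widths to
  256) training is practical only for short runs. The benchmark scale is
  chosen so the full experiment runs on one CPU in minutes.
* The phantom's difficulty dial is one-dimensional (opacity); real
  mild mastoiditis differs texturally, not only in mean density.
* Per-ear AUC treats ears as independent; subject-level correlation would
  widen intervals slightly.
* A true postoperative ear at inference has no category-3 output; the
  closest category is surfaced and should be treated as low-confidence —
  an extension beyond the modelled label space.
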