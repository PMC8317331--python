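# Methods

## Scope and design

The package implements a two-branch ensemble classifier for
microcalcification clusters (MCs) in digital breast tomosynthesis (DBT)
together with everything needed to exercise it without clinical data: a
synthetic phantom generator, the preprocessing chain, the focus-slice
statistic, both network branches and ensembling strategies, the training
protocol, and the evaluation stack. Clinical DBT cohorts of biopsy-proven
MCs are not publicly available, so every empirical claim the test suite
makes is about *synthetic* cohorts whose generating process is part of the
package; nothing here should be read as a clinical performance claim.

The deep-learning layers (`dbtmc.nn`) are a compact numpy framework with
hand-derived backward passes (im2col convolutions on BLAS matmuls, batch
normalization, max/global pooling, dropout, Adam). It exists so the whole
pipeline runs and trains on a single CPU with no GPU stack; gradients are
verified against finite differences in the test suite.

## Phantom model

Each lesion view is rendered as

    volume(x, y, k) = background(x, y) + blur(spots, σ_k)(x, y) + ε,
    σ_k = blur_slope · |k − focus|,  ε ~ N(0, noise_sd²),

clipped to the 10-bit detector range [0, 1023].

* **Spots.** Antialiased disks, max-composited, drawn once per lesion
  (count, radius, peak intensity, cluster geometry) and re-rendered per
  view with a small positional jitter (default 2 px), so CC and MLO are
  correlated but not identical — this is what makes lesion-level score
  averaging meaningful. Benign clusters: 3–8 spots, radius 4–6 px, compact
  (cluster radius 13% of the in-plane extent). Malignant clusters: 10–25
  spots, radius 2–6 px (finer and more variable), more scattered (23%),
  optionally elongated up to 2:1. This echoes the clinical coarse-benign /
  fine-pleomorphic-malignant contrast qualitatively only; the defaults
  also put the total spot area near the 99.5th intensity percentile so the
  default auto-segmentation is a meaningful (imperfect) detector.
* **Focus slice.** Drawn uniformly from interior slices. The Gaussian blur
  grows linearly with slice distance at 0.9 px/slice, emulating the
  sharpness falloff of reconstructed MCs.
* **Background.** A smooth 2D texture (Gaussian-filtered noise, 12 px
  correlation length, mean 250 ± 50) broadcast over all slices. Over a
  ~1 cm stack tissue texture varies far more slowly than MC sharpness, and
  a z-constant background makes the focus statistic exact in the
  noise-free limit — a deliberate idealization.
* **Splits.** Per class: train = round(0.8 n), val = floor(0.1 n), test =
  remainder, which reproduces the reference cohort bookkeeping
  (173 → 138/17/18, 322 → 258/32/32, test total 50). Lesions map 1:1 to
  patients, so lesion-level splitting is also patient-level.

What the phantoms deliberately do **not** model: tomosynthesis
reconstruction physics (limited-angle artifacts, scatter, out-of-plane
ghosting), realistic parenchymal texture, intensity distributions of real
MCs, co-registration error between views beyond jitter. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
the method recovers structure *it assumes*, not that it classifies real
lesions.

## Focus-slice selection

G(k) is the mean intensity over segmented microcalcification pixels of
slice k; the focus is argmax G(k), ties broken toward the lowest index,
slices with no components excluded. The statistic presupposes a
segmentation; the built-in detector thresholds each slice at its q-th
intensity percentile (default 99.5), takes 8-connected components and
discards those under 2 px. Oracle-mask mode (phantom ground truth)
isolates the statistic from segmentation error. G is computed on
normalized intensities; the argmax is scale-invariant, so this is
inconsequential.

## Preprocessing

Min–max normalization maps the whole source volume linearly to [0, 1]
(P_out = (P_in − P_min)/(P_max − P_min)); for generated ROI phantoms "the
whole image" and the ROI coincide. The N-slice slab spans
[focus − N/2, focus + N/2 − 1] — one extra slice below the focus, keeping
it nearest the center of an even window — shifted minimally when it
overruns the volume. Resizing is bilinear. Augmentation is geometric and
strictly in-plane (translation ≤ 20 px, horizontal flip, rotation ≤ 20°),
identical parameters applied to every slice of a slab, borders
edge-replicated.

## Architectures

The 2D branch is the canonical 34-layer residual network with a
single-channel stem and a 2-logit head; the pooled 512-vector is exposed
for the feature ensemble. The anisotropic 3D branch mirrors it with every
convolution factorized (K1 = k×k×1 then K2 = 1×1×k, each followed by batch
normalization and ReLU, residual additions before the final ReLU; each
module holds two K1/K2 pairs = four convolutions). Choices the published
description leaves open, resolved here:

* **No through-plane striding** anywhere (with 8–12 slices the axis would
  collapse); "feature map halved" at block junctions is in-plane, via
  stride-2 K1 and a 1×1×1 stride-(2,2,1) projection shortcut.
* **Stem stride (2,2,1)** plus 3×3×1 max pooling, mirroring the 2D design.
* **C_temp = C_out** in the factorization (the common choice; keeps block
  channel bookkeeping simple).
* **Batch normalization after every convolution** — required for
  trainability at small batch sizes.
* The 2D branch trains **from random initialization** (no pretraining
  switch is exercised by default).
* Decision-level weights apply to **softmax probabilities**, not logits.

## Training protocol

Adam with default moments; initial learning rates 1e-4 (2D) and 1e-5 (3D);
dropout p = 0.5 before the final linear layer; cross-entropy loss. The
learning rate decays by 0.8 whenever the training loss has gone
`plateau_patience` (default 3) consecutive epochs without a new minimum —
the patience smooths single-epoch noise out of a bare "did not decrease"
rule. Checkpoint selection is by best validation AUC (the reporting
metric). Per-class augmentation factors expand each epoch to exactly
n_b·f_b + n_m·f_m samples; the factor defaults (37, 23) reproduce the
reference cohort's 5106 + 5934 = 11,040 augmented training samples from
138 + 258 originals. The feature-level ensemble head (one linear layer on
the concatenated 1024-vector) is fitted with both branches frozen;
training it jointly end-to-end is possible in principle but mixes branch
and head capacity, and frozen-branch fitting matches how the two
strategies are compared (same branch weights under both ensembles).

## Desk-scale problem sizes

Default experiment configuration (`RunConfig`): 100-lesion easy phantom
cohort (50/50) at 64×64×12 voxels, low noise (sd 4), slab N = 8, 2D input
56×56, reduced-width branches (modules (1,1,1,1), channels (8,16,32,64)),
batch size 8, augmentation factors (4,4), 10 epochs per branch — about two
minutes on one CPU core. These sizes are the package's own desk-scale
choice: small enough to iterate on, large enough that both branches must
actually learn the morphology signal. The full-width architectures
((3,4,6,3) × (64,…,512), 300×300 inputs) are constructed and traced
forward at full size in the tests and acceptance script; training them is
a GPU-scale undertaking outside this package's defaults.

## Numerical notes

* Arithmetic is float32 in the network stack, float64 elsewhere.
* AUC is the tie-aware rank statistic (average ranks), identical to the
  trapezoidal empirical-ROC area; the suite checks exact rational
  agreement with an exhaustive pairwise oracle on small instances.
* Thresholded confusion counts call a score exactly at threshold (default
  0.5) positive; AUC itself is threshold-free.
* Percent rounding for table recovery is half-up at two decimals, matching
  how the reference tables print 25/32 as 78.13; recovery reports
  ambiguity rather than guessing when printed precision does not pin the
  integer counts down.
* Degenerate inputs error loudly: constant volumes cannot be normalized,
  empty segmentations cannot select a focus, zero-denominator metrics are
  NaN ("undefined"), never silent zeros.

## Known limitations

* Phantom realism, as above: results on phantoms bound nothing clinically.
* The isotropic 3D baseline appears as closed-form parameter accounting
  (the 4/9 factorization ratio), not as a trained comparison model.
* The numpy framework targets clarity and determinism over speed; it is
  single-threaded BLAS-bound and unsuitable for full-width training.
* Focus-slice auto-segmentation is a deliberately simple percentile
  detector, not a clinical-grade MC finder; its Dice against phantom
  ground truth (~0.6–0.9 by class) is a property of the phantom contrast
  settings.
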