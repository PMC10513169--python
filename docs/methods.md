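# Methods

## Problem setting

A balloon wedge catheter with a gadolinium-filled tip balloon appears on
T1-weighted real-time cardiac MR images as a compact hyper-intense blob a
few pixels across.  A real-time acquisition produces, at each time point
("dynamic"), three contiguous parallel slices; the goal is to emit at most
one tip coordinate per dynamic — the input a prospective slice-tracking
system needs — with no user-tunable parameters at inference time.

## Balloon signal model

The balloon is modelled as a unit-peak 2D anisotropic Gaussian with
covariance `R(θ) diag(σx², σy²) R(θ)ᵀ`, rotated counter-clockwise in
(row, col) space about a centre placed inside a blood-pool structure.
Parameters per balloon:

| parameter | values | meaning |
|---|---|---|
| σx, σy | each uniform on {1.5, 2.5} px, independent | balloon size/shape |
| θ | uniform integer in [0°, 359°] | in-plane orientation |
| amplitude | uniform on {200, 300, 400} % | peak added signal, relative to the background intensity at the centre pixel |
| mask radius | fixed 1.5 SD | ground-truth extent |

The signal is *added* to the background (`I + A·G`) rather than replacing
it.  The amplitude convention fixes only the peak increment, not the
composition rule; additive composition preserves the background texture
under the balloon, matching the partial-saturation appearance of these
acquisitions, and makes the ground truth exactly recoverable
(`I' − I = A·G` to machine precision, a property the tests assert).

"Within 1.5 standard deviations" of an anisotropic rotated Gaussian is read
as Mahalanobis distance ≤ 1.5, i.e. the rotated ellipse with semi-axes
1.5 σx and 1.5 σy.  The mask builder is checked against a brute-force
per-pixel scan using the explicit inverse covariance for every
(σx, σy) ∈ {1.5, 2.5}² and θ on a 30° grid; the isotropic σ = 1.5 case
contains exactly 21 pixels.

## Phantom backgrounds

Real cardiac MR backgrounds are not distributed with the package, so the
generator synthesises them procedurally: a low-intensity smoothly textured
background (≈ 0.08 a.u.), two to three mid-intensity (0.35–0.55 a.u.)
elliptical chamber-like structures and one tubular vessel-like capsule, one
hyper-intense (0.9–1.2 a.u.) wavy fat-like band a few pixels from a border,
light smoothing, and additive Gaussian noise (σ = 0.01), clipped at zero.
Each training frame gets its own background (emulating the many distinct
source slices of a multi-slice stack per subject); subject identity seeds
the draw, so train/validation splits never share a background.  Balloons
are placed uniformly inside the eroded chamber/vessel interiors at least
`3·max(σ) = 8` px from the image border.  Contiguous slices of one dynamic
re-draw the same structural layout with per-slice positional jitter
(2 px per slice step) and independent noise.

What the phantoms deliberately exercise: hyper-intense confounders (fat
bands) that a naive intensity threshold would fire on, variable balloon
contrast (by placing on structures of different intensity), and multi-slice
ambiguity.  What they do not model: MR physics (bSSFP banding, saturation
contrast, coil profiles, undersampling artifacts), anatomy realism, motion,
or through-plane partial volume.  Passing the end-to-end tests therefore
shows the pipeline's machinery works under the stated signal model, not
clinical-grade performance on patient images.

## Segmentation network and training

Normalisation: each grayscale frame is rescaled to [0, 1] over its own
range, replicated to three channels, then shifted/scaled by the standard
ImageNet per-channel statistics (means 0.485/0.456/0.406, SDs
0.229/0.224/0.225, stored as overridable constants).  A constant image maps
to all zeros with a warning.

The network is an encoder–decoder with skip connections: a residual
encoder (conv–BN–ReLU stem, then residual stages that halve resolution and
raise channel count), a decoder that nearest-neighbour-upsamples,
concatenates the encoder skip and refines with conv units, and a 1×1 head
producing one logit per pixel.  Presets:

- `tiny` (8/16/32 channels, one residual block per downsampled stage, a
  bottleneck decoder: 1×1 channel fusion then one 3×3 refinement) — the
  CPU-trainable configuration used by the tests and the demo;
- `resnet34` (64/64/128/256/512 channels with the 3/4/6/3 residual stage
  pattern of a 34-layer residual encoder, classic two-conv decoder) — the
  full-scale reference configuration.

Everything (convolution via channels-last im2col + BLAS matrix products,
batch normalisation with running statistics, Adam) is implemented in NumPy
with hand-derived backward passes; the test suite checks every layer path
against central finite differences to ~1e-7 relative error.  Pretrained
encoder weights are supported only as a user-supplied checkpoint file
(`use_pretrained_encoder` + `pretrained_weights`); no download is
performed, and random (He) initialisation is the default.

Training minimises the per-image Dice loss averaged over the batch, with
smoothing ε = 1.0 in numerator and denominator so the loss is defined (and
zero) for the catheter-free frames that make up 10 % of the training set.
The reference recipe fixes learning rate 1e-5, batch 64, 200 epochs; the
weights kept are those of the epoch with the global minimum validation
loss (earliest epoch on ties).  Inputs whose size is not a multiple of the
encoder's downsampling factor are reflect-padded and the prediction cropped
back.  The decision threshold is fixed at 0.5, inclusive (an activation of
exactly 0.5 is balloon).

A single seed controls weight initialisation and batch order; training is
bit-reproducible on a given platform, and cross-platform differences are
bounded only by BLAS summation order, so tests assert with margins.

## Scaled-down study conditions

The CPU-sized conditions used by the end-to-end tests, the demo and the
acceptance script: 64×64 frames; 8 training subjects × 38 frames = 304
training frames (10 % catheter-free) and 48 validation frames from 4 other
subjects; the `tiny` preset trained 30 epochs from random initialisation
with learning rate 3e-3 and batch 16 (a small network trained without
pretraining needs a larger step size than the full-scale recipe, and a
smaller batch gives more updates on a small set); evaluation on 55 held-out
dynamics (25 % catheter-free) grouped into four evaluation subjects.  Under
these conditions the pipeline reaches per-dynamic sensitivity and
specificity at or near 100 % with sub-pixel mean tip error (≈ 0.1–0.3 px);
the internal acceptance bar is ≥ 90 % for both, averaged over three seeds,
and a worst-case tip error of 1.5·max(σ) = 3.75 px on correct detections.

## Tracking (disambiguation)

Predicted masks are decomposed into connected components under
8-connectivity (balloon blobs are compact; diagonal splits are artifacts).
All regions across the three slices of a dynamic are pooled and scored by
the **mean** underlying image intensity over the region's pixels — "highest
signal intensity" could also mean peak or sum; the mean is robust to region
size, and peak scoring is available as an option.  The winner's centroid
(unweighted mean pixel coordinate) is the tip; the tip point within the
balloon is otherwise unspecified, and the centroid is the natural unique
choice.  Ties break deterministically: lowest slice index, then largest
region, then smallest (row, col) centroid — inference is entirely seed-free.
Dynamics are processed independently; no temporal smoothing or motion
prior is applied (the "parameter-free" property).

## Evaluation rules

Per evaluated unit: TP requires *exactly one* predicted region whose centre
of mass, rounded to the nearest pixel, lies on a ground-truth foreground
pixel; TN is no region and empty ground truth; FN is a present catheter
with no predicted region at all; everything else — spurious regions on a
catheter-free unit, multiple regions, or a single region in the wrong
place — is FP.  The FP-vs-FN boundary for "catheter present but only wrong
regions predicted" is genuinely ambiguous; FP is the default and the
convention is switchable (`missed_gt_label`).

Two granularities mirror the two analyses: per-image (network alone,
against the per-slice ground truth) and per-dynamic (full pipeline, against
a multi-slice ground truth built by keeping only the per-slice ground-truth
region with the highest mean intensity; a per-dynamic TP additionally
requires the predicted slice to match).

Metrics use the standard formulas in percent; zero-denominator ratios
(e.g. specificity for a patient with no catheter-free dynamics) propagate
as NaN with a warning and are excluded from aggregation rather than forced
to 0 or 100.  Cross-patient aggregation is the unweighted mean, with the
population standard deviation (n in the denominator) as the spread: on the
published seven-patient table this convention reproduces the printed
specificity and sensitivity spreads (0.2, 5.5) exactly, while the accuracy
spread computes to 1.9 under the population convention and 2.1 under the
sample convention — consistent with the printed 2.0 only if unrounded
per-patient inputs were used — so the means, not the spreads, are treated
as the reproducible surface.

Operator agreement between two segmentations: each mask's centre of mass
(unweighted; intensity weighting is not used anywhere) must fall inside the
other mask.  Two empty masks agree; exactly one empty disagrees.

## Known limitations

- Phantom backgrounds are stylised; absolute performance numbers on them do
  not transfer to patient images.
- The full-scale `resnet34` preset is structurally faithful but impractical
  to train in NumPy on a CPU; it is exercised for correctness (shapes,
  gradients, checkpointing) rather than trained in the test suite.
- Batch-normalisation statistics make training-mode predictions
  batch-dependent; all inference uses running statistics (evaluation mode).
- The tracker assumes at most one catheter is present, by design of the
  procedure it supports.
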