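# Methods

## Registration model

The registration network maps a stack of input channels — fixed image,
moving image, then the fixed and moving per-class segmentation channels in
ascending class-code order — to a dense displacement field `u` with two
channels: channel 0 the x-direction (column) displacement, channel 1 the
y-direction (row) displacement, both in pixel units. With all six
anatomical classes the input has 2 + 2·6 = 14 channels; with no
segmentation inputs, 2. The architecture is a U-Net: stride-2
conv → batch-norm → ReLU blocks in the encoder (default widths 16, 32, 32,
32), nearest-neighbour ×2 upsampling with skip concatenation in the decoder
(default widths 32, 32, 32, 16, 16), and a linear 3×3 output convolution
initialised near zero so an untrained network predicts a near-identity
field. Image sizes must be divisible by 2^levels.

Warping uses the backward convention `output(p) = moving(p + u(p))` with
bilinear interpolation; sample coordinates are clamped to the image border
(no zero-fill, which would fabricate dark borders that the MSE term would
chase). Label maps are warped by one-hot encoding every class including
background, warping each channel bilinearly and taking the per-pixel
argmax, ties to the lowest class code. No smoothness or invertibility
constraint is imposed on `u` beyond the loss penalty: contact and
separation of articulators require discontinuous fields, and the phantom's
ground-truth fields are themselves discontinuous at structure boundaries.

## Loss

`L = MSE + λ‖∇u‖² − γ·DSC`, with λ, γ ≥ 0.

- MSE: mean squared intensity difference between the fixed and warped
  moving image.
- Smoothness: forward differences with edge replication; each squared
  partial is averaged over all pixels and both displacement channels and
  the two partials are averaged. Translation-invariant and quadratic.
- DSC: soft Dice with squared denominator and smoothing ε = 1e-5,
  `(2Σpq + ε)/(Σp² + Σq² + ε)`, computed per foreground class on the
  *ground-truth* one-hots (the moving one warped bilinearly, without
  argmax, to keep gradients flowing) and averaged over the six foreground
  classes. Averaging per class rather than pooling all classes keeps the
  small classes (soft palate, tooth space) from being swamped by the head;
  a class empty in both inputs scores 1. γ = 0 recovers the image-only
  objective exactly.

During training the registration inputs are the estimated, post-processed
segmentations (or the oracle stand-in, below); the ground-truth one-hots
appear only inside the Dice term and in evaluation.

## Segmentation

The segmenter is a pluggable pre-trained component: any object with
`predict_soft(frames) -> (T, C+1, H, W)`. Provided implementations are a
softmax U-Net (`build_segmentation_network`, trainable with a soft-Dice
loss via `train_segmenter`) and an `OracleSegmenter` that replays stored
ground-truth labels as one-hots, so registration experiments can be run
independently of segmentation quality. Post-processing keeps, for each
foreground class, only the largest connected component (8-connectivity;
ties go to the first-scanned component) and reassigns the rest to
background — idempotent, and it never adds foreground pixels.

## Closure metric

A frame shows velopharyngeal closure when at least `min_contact_pixels`
(default 3) soft-palate pixels inside the posterior portion of the soft
palate's bounding box have a head-class neighbour (8-connectivity by
default). "Posterior" is operationalised as the posterior third of the
bounding box along the anterior–posterior (column) axis, with the image
orientation configurable; this restriction keeps the anatomical attachment
of the soft palate to the hard palate (also head class) from registering
as contact. Closures are maximal runs of consecutive closed frames; a true
closure is captured when any predicted run overlaps it by ≥ 1 frame, and a
single predicted run overlapping two truth runs captures both. DSC of two
empty masks is defined as 1; ASD is symmetric (pooled mean over both
boundary point sets, boundaries being mask pixels with a 4-neighbour
outside the mask) and is undefined — recorded as missing — when a mask is
empty.

## Training and evaluation protocol

Per epoch, every training frame serves once as the fixed image, paired
with a uniformly drawn other frame of the same subject; mini-batches of 4
pairs; Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-8; 200 epochs at full scale.
Augmentation multiplies the epoch's pairs by 4: each extra copy applies one
sampled affine transform (translation ±10 px, rotation ±10°, crop-and-zoom
retaining ≥ 85%, rescale 0.9–1.1 — config-overridable defaults) to both
frames of the pair, images bilinearly, labels by nearest neighbour. At
evaluation, every test frame is the fixed image and the series' reference
frame the moving image; the reference frame is the first frame with lips
apart, tongue free and no posterior palate–wall contact, found
automatically by class-adjacency tests.

Hyperparameters (learning rate, λ, γ) are selected per main
leave-one-subject-out fold by nested leave-one-subject-out folds: the
combination capturing the most true closures, summed over the nested
left-out subjects, wins; ties break by grid order (the selection rule does
not define a tie-break, so the deterministic choice is documented here).
Group DSC/ASD comparisons use a two-tailed Wilcoxon signed-rank test when
|sample skewness| of the paired differences is < 1 (the symmetry screen's
operationalisation) and a two-tailed sign test otherwise; closure counts
use an exact (binomial) McNemar test; Holm–Bonferroni controls the
family-wise error at 5%.

## Phantom

The generator emulates a dynamic midsagittal series at study-like scale
(default 64×64, 40 frames — two frames per counted number at 10 fps — with
3 closures): a static head comprising a top band (hard palate/skull) and a
4-pixel posterior wall; a soft-palate flap hanging from the hard palate
that translates posteriorly to a plateau during each scheduled closure
interval (3 frames, with half-amplitude ramp frames, resting 4 px clear of
the wall so zero amplitude produces no closures); a tongue ellipse and jaw
band oscillating sinusoidally (period 10 frames; jaw at half the tongue
amplitude); airway filled by the vocal-tract class; a 3×3 tooth-space box
riding on the jaw. Intensities are per-class constants (head 0.8, jaw 0.7,
palate 0.6, tongue 0.5, tooth space 0.3, airway 0.05) plus Gaussian noise
(σ = 0.02 by default), min–max normalised per series to [0, 1].

Because every moving structure translates rigidly inside its own disjoint
support band, the exact backward field of each frame relative to the
reference is piecewise constant: `−d_t` inside a structure's band, zero
elsewhere. The generator verifies itself: the closure detector applied to
the generated labels must reproduce the scheduled runs exactly, the
reference-selection criteria must pick a motion-free frame, and geometry
that cannot realise the request (too-small frames, palate amplitude below
the 4 px resting gap when closures are requested, too few frames per
closure) raises an error rather than degrading silently.

What the phantom does *not* emulate: MRI physics and artefacts, soft-tissue
deformation (motions are rigid translations), anatomically realistic
shapes, inter-subject anatomical variability, or out-of-plane motion.
Passing phantom tests therefore demonstrates that the pipeline's mechanics
— losses, warping, metrics, selection, statistics — behave correctly and
that segmentation inputs help capture contact events in a controlled
setting; it does not certify accuracy on clinical data.

## Scaled-down experiment sizes

The bundled experiment (`closure_capture_experiment`) and the test suite
run a deliberately small protocol chosen to keep full repeats tractable on
a single CPU while preserving the contrast of interest: 3 subjects, 64×64
frames, 20 frames and 3 closures per subject, 20 epochs, no augmentation,
a narrow three-level network (encoder 8, 16, 16; decoder 16, 16, 8, 8),
and lr = 3e-3, λ = 0.01, γ = 1 — the combination that captured the most
closures in a coarse phantom search, i.e. selected by the same
closure-capture criterion that drives the full protocol's nested
cross-validation. At this scale the segmentation-informed configuration
typically captures most or all of the nine true closures and the
image-only configuration captures none, a small-scale analogue of the
headline contrast; training remains stochastic, so individual repeats
vary.

When a repeat fails to capture closures it fails in a characteristic way:
the warped soft palate itself can be pixel-perfect while the predicted
field bleeds the palate's displacement a few pixels into the static wall,
so the backward warp erodes the head class exactly where contact should
appear and the detector correctly reports no closure. Capturing contact
therefore requires the field to be discontinuous at the palate–wall
interface; whether 20 epochs suffice to sharpen that discontinuity is
marginal at this scale, which is the source of the repeat-to-repeat
variance (overlap metrics barely register the difference — another
illustration of why the closure metric is the more sensitive instrument).

## Numerical choices and limitations

- Argmax ties (hard labels, warped labels) resolve to the lowest class
  code; equal-sized connected components resolve to the first scanned.
- Batch norm uses per-batch statistics in training and running averages
  (momentum 0.1) in inference, so inference is deterministic; training
  reproducibility is exact for a fixed seed on a given platform but not
  guaranteed across BLAS implementations.
- The engine stores float32 parameters; losses are accumulated in the
  input dtype. Finite-difference gradient checks run in float64.
- Checkpoints are NumPy `.npz` archives keyed by parameter order; loading
  requires rebuilding the same architecture.
- Series are handled uncompressed in memory; the implementation targets
  2D series of a few hundred frames, not 3D volumes.
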