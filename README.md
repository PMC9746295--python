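# vtreg

Segmentation-informed deformable registration of dynamic 2D vocal-tract
image series, with a velopharyngeal-closure evaluation metric and a
synthetic phantom generator.

## The problem

Dynamic midsagittal imaging of speech shows articulators — tongue, jaw and
soft palate — moving, touching and separating. Quantifying that motion
means estimating a dense displacement field **u** between frames
(deformable registration). The clinically decisive event, *velopharyngeal
closure* (the soft palate sealing against the posterior pharyngeal wall),
is exactly the kind of contact-and-separation motion that smooth
registration models fail to capture, and that standard overlap metrics
barely notice.

This package is for researchers and clinical scientists who want to

- register frames of a dynamic 2D vocal-tract series with a CNN that takes
  **segmentations as well as images** as input and is trained with a
  Dice-supervised objective, and
- evaluate fields not only with the Dice similarity coefficient (DSC) and
  average surface distance (ASD) but with a **closure-capture metric**: how
  many true velopharyngeal closures survive in the warped label maps.

## The method

Given a fixed and a moving frame with six-class segmentations (head, soft
palate, jaw, tongue, vocal tract, tooth space), a U-Net-style registration
CNN — 14 input channels (2 images + 2 × 6 segmentation channels), 2 output
channels (x- and y-displacement), conv → batch-norm → ReLU blocks — predicts
**u**. A differentiable spatial transformer warps the moving image and
moving ground-truth one-hot segmentations backward through **u**
(output(p) = moving(p + u(p)), bilinear). Training minimises

    L = MSE(f, m ∘ u) + λ‖∇u‖² − γ·DSC(Sf, Sm ∘ u)

with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Setting γ = 0 and dropping the
segmentation input channels gives the image-only baseline configuration
(L = MSE + λ‖∇u‖²). A frame shows closure when ≥ 3 posterior soft-palate
pixels touch head pixels; a true closure (a run of consecutive closed
frames) is *captured* when the warped moving labels reproduce a run that
overlaps it. Hyperparameters are selected by leave-one-subject-out nested
cross-validation, maximising captured closures. All networks run on a
small NumPy autodiff engine bundled in `vtreg.nn` — no GPU or deep-learning
framework required.

Because real subject series of this kind are not publicly available, the
`phantom` module generates synthetic series with full ground truth: label
maps, closure schedules and the exact (piecewise-constant, discontinuous)
displacement fields relating every frame to the reference frame.

## A worked example

`examples/03_train_registration.py` trains the segmentation-informed
configuration on three phantom subjects (64 × 64, 20 frames, 3 closures
each) for 20 epochs and evaluates every frame against each subject's
reference frame:

```
input channels: 14 (2 images + 2x6 segmentations)
loss: first epoch -0.730, last epoch -0.981
s0: mean DSC 0.997; captured closures 3/3
s1: mean DSC 0.997; captured closures 3/3
s2: mean DSC 0.997; captured closures 3/3
```

The loss (dominated by the negative Dice term) approaches −1 as alignment
becomes exact; all nine true closures are captured. The other examples
cover phantom generation, warping and metrics, nested cross-validation and
the statistical tests. The `vtreg` command exposes `simulate`, `segment`,
`register`, `evaluate` and `train` for shell use.

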