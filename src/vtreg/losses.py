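"""Training objective: similarity + field smoothness - segmentation overlap.

The full loss is

    L = MSE(fixed, warped moving) + lambda * ||grad u||^2 - gamma * DSC

where the DSC term is a soft (differentiable) Dice coefficient between the
fixed ground-truth one-hot segmentations and the bilinearly warped moving
ground-truth one-hots, averaged over the foreground classes.  Setting
``gamma = 0`` removes the segmentation term and leaves the image-only
objective ``MSE + lambda * ||grad u||^2``.

Every term accepts either NumPy arrays (returning a float) or autodiff
``Tensor``s (returning a scalar ``Tensor``, for use during training).
Array layouts: images (H, W) or batched (N, C, H, W) tensors; displacement
fields (H, W, 2) arrays or (N, 2, H, W) tensors; one-hot stacks (H, W, C)
arrays or (N, C, H, W) tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossWeights", "mse_term", "grad_l2_term", "soft_dice_term", "sivxm_loss"]

DICE_EPS = 1e-5


@dataclass(frozen=True)
class LossWeights:
    """Weights of the smoothness (lambda) and Dice (gamma) loss terms."""

    lambda_grad: float = 0.01
    gamma_dice: float = 1.0

    def __post_init__(self):
        for name in ("lambda_grad", "gamma_dice"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def mse_term(fixed, warped):
    """Mean over pixels of the squared intensity difference."""
    if _is_tensor(fixed, warped):
        f = fixed if isinstance(fixed, Tensor) else Tensor(np.asarray(fixed))
        w = warped if isinstance(warped, Tensor) else Tensor(np.asarray(warped))
        if f.shape != w.shape:
            raise ValueError("image shapes differ")
        return ((f - w) ** 2).mean()
    f, w = np.asarray(fixed), np.asarray(warped)
    if f.shape != w.shape:
        raise ValueError("image shapes differ")
    return float(np.mean((f - w) ** 2))


def grad_l2_term(u):
    """L2 penalty on the spatial gradients of the displacement field.

    Forward differences with edge replication (the difference at the last
    row/column is zero); each squared partial is averaged over all pixels
    and both displacement channels, and the two partials are averaged.
    Translation-invariant: adding a constant to the field changes nothing.
    """
    if isinstance(u, Tensor):
        if u.ndim != 4 or u.shape[1] != 2:
            raise ValueError("tensor field must have shape (N, 2, H, W)")
        if not np.all(np.isfinite(u.data)):
            raise ValueError("displacement field contains non-finite values")
        n, _, h, w = u.shape
        dx = u[:, :, :, 1:] - u[:, :, :, :-1]
        dy = u[:, :, 1:, :] - u[:, :, :-1, :]
        denom = float(n * 2 * h * w)
        return ((dx ** 2).sum() * (1.0 / denom) + (dy ** 2).sum() * (1.0 / denom)) * 0.5
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ValueError("array field must have shape (H, W, 2)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    h, w = u.shape[:2]
    dx = np.diff(u, axis=1)
    dy = np.diff(u, axis=0)
    denom = 2.0 * h * w
    return float(0.5 * ((dx ** 2).sum() / denom + (dy ** 2).sum() / denom))


def _soft_dice_tensor(f: Tensor, w: Tensor, foreground_only: bool) -> Tensor:
    if f.shape != w.shape:
        raise ValueError("class-count or shape mismatch between one-hot stacks")
    c0 = 1 if (foreground_only and f.shape[1] > 1) else 0
    per_class = []
    for c in range(c0, f.shape[1]):
        fc, wc = f[:, c], w[:, c]
        inter = (fc * wc).sum()
        denom = (fc ** 2).sum() + (wc ** 2).sum() + DICE_EPS
        per_class.append((2.0 * inter + DICE_EPS) / denom)
    total = per_class[0]
    for t in per_class[1:]:
        total = total + t
    return total * (1.0 / len(per_class))


def soft_dice_term(fixed_onehot, warped_onehot, foreground_only: bool = True):
    """Soft Dice coefficient averaged over (foreground) classes.

    Per class: ``(2 * sum(p*q) + eps) / (sum(p^2) + sum(q^2) + eps)``, the
    smoothed squared-denominator form (a class empty in both inputs scores
    1).  Channel 0 is treated as background and skipped when
    ``foreground_only`` and more than one channel is present.  Equals 1 for
    identical hard one-hots.
    """
    if _is_tensor(fixed_onehot, warped_onehot):
        f = fixed_onehot if isinstance(fixed_onehot, Tensor) else Tensor(np.asarray(fixed_onehot))
        w = warped_onehot if isinstance(warped_onehot, Tensor) else Tensor(np.asarray(warped_onehot))
        return _soft_dice_tensor(f, w, foreground_only)
    f = np.asarray(fixed_onehot, dtype=np.float64)
    w = np.asarray(warped_onehot, dtype=np.float64)
    if f.shape != w.shape:
        raise ValueError("class-count or shape mismatch between one-hot stacks")
    if f.ndim == 2:
        f, w = f[..., None], w[..., None]
    c0 = 1 if (foreground_only and f.shape[-1] > 1) else 0
    vals = []
    for c in range(c0, f.shape[-1]):
        inter = float((f[..., c] * w[..., c]).sum())
        denom = float((f[..., c] ** 2).sum() + (w[..., c] ** 2).sum()) + DICE_EPS
        vals.append((2.0 * inter + DICE_EPS) / denom)
    return float(np.mean(vals))


def sivxm_loss(fixed, warped_img, fixed_gt_onehot, warped_gt_onehot, u, w: LossWeights):
    """Full objective: MSE + lambda * grad - gamma * Dice.

    The name abbreviates "segmentation-informed VoxelMorph", the family of
    unsupervised registration objectives this loss belongs to.  With
    ``gamma_dice = 0`` this is exactly the image-only (plain VoxelMorph)
    objective; the Dice term is then neither computed nor needed.
    """
    total = mse_term(fixed, warped_img)
    if w.lambda_grad != 0:
        total = total + w.lambda_grad * grad_l2_term(u)
    if w.gamma_dice != 0:
        total = total - w.gamma_dice * soft_dice_term(fixed_gt_onehot, warped_gt_onehot)
    return total
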