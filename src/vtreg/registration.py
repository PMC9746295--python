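"""Displacement-field estimation and spatial-transformer warping.

A displacement field ``u`` is an (H, W, 2) array in pixel units: channel 0
holds x-direction (column) displacements and channel 1 y-direction (row)
displacements.  Warping follows the backward convention

    output(p) = moving(p + u(p))

with bilinear interpolation and border-clamped sampling.  No invertibility
or smoothness constraint is imposed on the field itself: discontinuous
fields are exactly what contact/separation of articulators requires.

The registration network is a U-Net-style CNN (conv -> batch norm -> ReLU
blocks, linear 2-channel output head) whose input stacks the fixed and
moving images with their per-class segmentation channels: with all six
anatomical classes it has 2 + 2*6 = 14 input channels; with no segmentation
inputs it reduces to the 2-channel image-only configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Tensor, UNet2d, warp_bilinear
from .segmentation import one_hot

__all__ = [
    "RegNetConfig",
    "RegistrationNetwork",
    "build_registration_network",
    "estimate_field",
    "warp_image",
    "warp_labels",
    "identity_field",
]

DEFAULT_ENCODER_WIDTHS = (16, 32, 32, 32)
DEFAULT_DECODER_WIDTHS = (32, 32, 32, 16, 16)


@dataclass(frozen=True)
class RegNetConfig:
    """Configuration of the registration CNN.

    ``seg_classes_in`` lists the foreground class codes whose segmentation
    channels are stacked into the input (possibly empty for the image-only
    configuration).  Input channel count is ``2 + 2 * len(seg_classes_in)``.
    """

    seg_classes_in: tuple = (1, 2, 3, 4, 5, 6)
    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    decoder_widths: tuple = DEFAULT_DECODER_WIDTHS
    batch_norm: bool = True

    def __post_init__(self):
        codes = tuple(sorted(int(c) for c in self.seg_classes_in))
        if len(set(codes)) != len(codes) or any(c < 1 for c in codes):
            raise ValueError("seg_classes_in must be distinct foreground class codes")
        object.__setattr__(self, "seg_classes_in", codes)
        object.__setattr__(self, "encoder_widths", tuple(self.encoder_widths))
        object.__setattr__(self, "decoder_widths", tuple(self.decoder_widths))

    @property
    def in_channels(self) -> int:
        return 2 + 2 * len(self.seg_classes_in)

    @property
    def out_channels(self) -> int:
        return 2


class RegistrationNetwork(Module):
    def __init__(self, cfg: RegNetConfig, seed: int | None = None):
        super().__init__()
        self.cfg = cfg
        self.unet = UNet2d(
            cfg.in_channels, cfg.out_channels,
            encoder_widths=cfg.encoder_widths,
            decoder_widths=cfg.decoder_widths,
            batch_norm=cfg.batch_norm,
            final_init_scale=1e-5,
            seed=seed,
        )

    @property
    def in_channels(self) -> int:
        return self.cfg.in_channels

    @property
    def out_channels(self) -> int:
        return self.cfg.out_channels

    def __call__(self, x: Tensor) -> Tensor:
        """(N, in_channels, H, W) -> (N, 2, H, W) displacement field."""
        return self.unet(x)


def build_registration_network(cfg: RegNetConfig, seed: int | None = None) -> RegistrationNetwork:
    return RegistrationNetwork(cfg, seed=seed)


def _stack_inputs(fixed, moving, fixed_seg, moving_seg, n_seg: int) -> np.ndarray:
    """Stack [fixed image, moving image, fixed seg block, moving seg block]."""
    fixed = np.asarray(fixed, dtype=np.float32)
    moving = np.asarray(moving, dtype=np.float32)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError("fixed and moving must be 2D images of equal shape")
    chans = [fixed, moving]
    for name, seg in (("fixed", fixed_seg), ("moving", moving_seg)):
        if n_seg == 0:
            if seg is not None and np.size(seg):
                raise ValueError("network takes no segmentation inputs")
            continue
        seg = np.asarray(seg, dtype=np.float32)
        if seg.shape != fixed.shape + (n_seg,):
            raise ValueError(
                f"{name} segmentation must have shape {fixed.shape + (n_seg,)}, got {seg.shape}"
            )
        chans.extend(np.moveaxis(seg, -1, 0))
    return np.stack(chans, axis=0)


def estimate_field(fixed, moving, fixed_seg, moving_seg, network: RegistrationNetwork) -> np.ndarray:
    """Estimate the displacement field aligning ``moving`` to ``fixed``.

    Segmentation inputs are (H, W, k) channel stacks in ascending class-code
    order restricted to the network's ``seg_classes_in`` (``None`` or empty
    for an image-only network).  Runs the network in inference mode; returns
    an (H, W, 2) field (channel 0 = x/column, channel 1 = y/row).
    """
    k = len(network.cfg.seg_classes_in)
    x = _stack_inputs(fixed, moving, fixed_seg, moving_seg, k)
    network.eval()
    u = network(Tensor(x[None]))
    return np.moveaxis(u.data[0], 0, -1).astype(np.float64)


def identity_field(height: int, width: int) -> np.ndarray:
    return np.zeros((height, width, 2), dtype=np.float64)


def _check_field(image: np.ndarray, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if u.shape != image.shape[:2] + (2,):
        raise ValueError(f"field shape {u.shape} does not match image shape {image.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    return u


def warp_image(moving: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Backward-warp an image: output(p) = moving(p + u(p)), bilinear, clamped."""
    moving = np.asarray(moving, dtype=np.float64)
    u = _check_field(moving, u)
    ut = np.moveaxis(u, -1, 0)[None]
    out = warp_bilinear(Tensor(moving[None, None]), Tensor(ut))
    return out.data[0, 0]


def warp_labels(labels: np.ndarray, u: np.ndarray, n_channels: int | None = None) -> np.ndarray:
    """Warp an integer label map through one-hot bilinear warping and argmax.

    Every class (including background) is one-hot encoded, each channel is
    warped bilinearly, and the per-pixel argmax is taken; ties go to the
    lowest class code.  The output contains no codes absent from the input.
    """
    labels = np.asarray(labels)
    u = _check_field(labels, u)
    if n_channels is None:
        n_channels = int(labels.max(initial=0)) + 1
    oh = np.moveaxis(one_hot(labels, n_channels), -1, 0)[None].astype(np.float64)
    ut = np.moveaxis(u, -1, 0)[None]
    warped = warp_bilinear(Tensor(oh), Tensor(ut)).data[0]
    return np.argmax(warped, axis=0).astype(labels.dtype)
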