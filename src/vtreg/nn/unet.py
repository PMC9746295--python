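"""U-Net-style encoder-decoder used by both networks.

The encoder downsamples with stride-2 convolutions, one per encoder width.
The decoder upsamples (nearest-neighbour, x2) back to full resolution,
concatenating the skip feature (or the network input at full resolution)
before each decoder convolution; any decoder widths beyond the upsampling
path run at full resolution.  Every convolution is a conv -> batch norm ->
ReLU block except the final output convolution, which is linear.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ConvBlock, Module
from .tensor import Tensor, concat, upsample_nearest2x

__all__ = ["UNet2d"]


class UNet2d(Module):
    def __init__(self, in_ch: int, out_ch: int,
                 encoder_widths=(16, 32, 32, 32),
                 decoder_widths=(32, 32, 32, 16, 16),
                 batch_norm: bool = True,
                 final_init_scale: float = 1e-5,
                 seed: int | None = None):
        super().__init__()
        if len(decoder_widths) < len(encoder_widths):
            raise ValueError("need at least one decoder width per encoder level")
        rng = np.random.default_rng(seed)
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.n_levels = len(encoder_widths)

        self.enc = []
        prev = in_ch
        for w in encoder_widths:
            self.enc.append(ConvBlock(prev, w, stride=2, batch_norm=batch_norm, rng=rng))
            prev = w

        # skip channels seen by successive decoder stages (deepest first),
        # ending with the raw input at full resolution
        skips = list(encoder_widths[:-1][::-1]) + [in_ch]
        self.dec = []
        for i, w in enumerate(decoder_widths):
            if i < self.n_levels:
                self.dec.append(ConvBlock(prev + skips[i], w, batch_norm=batch_norm, rng=rng))
            else:
                self.dec.append(ConvBlock(prev, w, batch_norm=batch_norm, rng=rng))
            prev = w

        self.final = Conv2d(prev, out_ch, rng=rng, init_scale=final_init_scale)

    @property
    def downsampling_factor(self) -> int:
        return 2 ** self.n_levels

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        f = self.downsampling_factor
        if h % f or w % f:
            raise ValueError(f"image size {h}x{w} not divisible by the downsampling factor {f}")
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        skips = [x]
        for block in self.enc:
            x = block(x)
            skips.append(x)
        skips = skips[:-1][::-1]  # deepest skip first, raw input last
        for i, block in enumerate(self.dec):
            if i < self.n_levels:
                x = upsample_nearest2x(x)
                x = concat([x, skips[i]], axis=1)
            x = block(x)
        return self.final(x)
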