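"""Multi-class segmentation of vocal-tract frames and label post-processing.

The anatomical class scheme follows the six-feature convention for
midsagittal vocal-tract imaging: head (including hard palate and pharyngeal
wall), soft palate, jaw, tongue, vocal tract (airway) and tooth space, with
integer codes 1-6 over a background code 0.

The segmentation network is a pluggable component: any object exposing
``predict_soft(frames) -> (T, C+1, H, W)`` can stand in.  Two implementations
are provided: an encoder-decoder CNN (:class:`SegmentationNetwork`) and an
:class:`OracleSegmenter` that replays stored ground-truth label maps, so the
registration stages can be exercised independently of segmentation quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .nn import Module, Tensor, UNet2d, softmax

__all__ = [
    "ClassScheme",
    "VOCAL_TRACT_SCHEME",
    "SegmentationNetwork",
    "OracleSegmenter",
    "build_segmentation_network",
    "segment_series",
    "postprocess_labels",
    "one_hot",
]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered (code, name) pairs; code 0 is background."""

    labels: tuple = (
        (0, "background"),
        (1, "head"),
        (2, "soft palate"),
        (3, "jaw"),
        (4, "tongue"),
        (5, "vocal tract"),
        (6, "tooth space"),
    )

    def __post_init__(self):
        codes = [c for c, _ in self.labels]
        if codes != list(range(len(codes))):
            raise ValueError("class codes must be unique and contiguous from 0")

    @property
    def codes(self) -> tuple:
        return tuple(c for c, _ in self.labels)

    @property
    def foreground_codes(self) -> tuple:
        return tuple(c for c, _ in self.labels if c != 0)

    @property
    def n_classes(self) -> int:
        """Number of foreground classes."""
        return len(self.labels) - 1

    def name_of(self, code: int) -> str:
        return dict(self.labels)[code]


VOCAL_TRACT_SCHEME = ClassScheme()

HEAD = 1
SOFT_PALATE = 2
JAW = 3
TONGUE = 4
VOCAL_TRACT = 5
TOOTH_SPACE = 6


def one_hot(labels: np.ndarray, n_channels: int) -> np.ndarray:
    """One-hot encode an integer label map; output shape labels.shape + (C,)."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (n_channels,), dtype=np.float32)
    np.put_along_axis(out, labels[..., None].astype(np.intp), 1.0, axis=-1)
    return out


class SegmentationNetwork(Module):
    """Encoder-decoder that maps one frame to per-class probability maps."""

    def __init__(self, n_classes: int, encoder_widths, decoder_widths, batch_norm=True, seed=None):
        super().__init__()
        self.n_classes = n_classes
        self.unet = UNet2d(
            1, n_classes + 1,
            encoder_widths=encoder_widths,
            decoder_widths=decoder_widths,
            batch_norm=batch_norm,
            final_init_scale=0.01,
            seed=seed,
        )

    def __call__(self, x: Tensor) -> Tensor:
        return softmax(self.unet(x), axis=1)

    def predict_soft(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Soft segmentations of a stack of frames; (T, H, W) -> (T, C+1, H, W)."""
        frames = np.asarray(frames, dtype=np.float32)
        self.eval()
        chunks = []
        for i in range(0, len(frames), batch_size):
            x = Tensor(frames[i : i + batch_size, None])
            chunks.append(self(x).data)
        return np.concatenate(chunks, axis=0)


class OracleSegmenter:
    """Replays stored ground-truth labels as one-hot soft segmentations.

    Queries are matched to the stored series by frame index, so the frames
    passed to :func:`segment_series` must align with the labels this oracle
    was built from.
    """

    def __init__(self, labels: np.ndarray, n_classes: int = 6):
        self.labels = np.asarray(labels)
        self.n_classes = n_classes

    def predict_soft(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames)
        if frames.shape[0] != self.labels.shape[0]:
            raise ValueError("frame count does not match the stored label series")
        if frames.shape[1:] != self.labels.shape[1:]:
            raise ValueError("frame shape does not match the stored label series")
        oh = one_hot(self.labels, self.n_classes + 1)  # (T, H, W, C)
        return np.moveaxis(oh, -1, 1)


def build_segmentation_network(n_classes: int, widths=(16, 32, 32), *,
                               decoder_widths=None, batch_norm=True, seed=None) -> SegmentationNetwork:
    """Build an encoder-decoder segmentation CNN.

    ``widths`` are the encoder feature widths (one stride-2 level each); the
    decoder mirrors them unless ``decoder_widths`` is given.  The output has
    ``n_classes + 1`` softmax channels (foreground classes plus background).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    widths = tuple(widths)
    if decoder_widths is None:
        decoder_widths = tuple(reversed(widths)) + (widths[0],)
    return SegmentationNetwork(n_classes, widths, decoder_widths, batch_norm=batch_norm, seed=seed)


def train_segmenter(images: np.ndarray, labels: np.ndarray, network: SegmentationNetwork,
                    *, epochs: int = 5, learning_rate: float = 1e-3, batch_size: int = 4,
                    seed: int = 0) -> list[float]:
    """Fit the segmentation CNN to (frame, label-map) pairs with a soft-Dice loss.

    Returns the per-epoch mean loss.  Small-scale convenience trainer; the
    framework otherwise treats the segmenter as a pre-trained component.
    """
    from .losses import soft_dice_term
    from .nn import Adam

    images = np.asarray(images, dtype=np.float32)
    targets = np.moveaxis(one_hot(np.asarray(labels), network.n_classes + 1), -1, 1)
    opt = Adam(network.parameters(), lr=learning_rate)
    rng = np.random.default_rng(seed)
    history = []
    network.train()
    for _ in range(epochs):
        order = rng.permutation(len(images))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            pred = network(Tensor(images[idx][:, None]))
            loss = 1.0 - soft_dice_term(Tensor(targets[idx]), pred, foreground_only=False)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def segment_series(images: np.ndarray, network) -> tuple[np.ndarray, np.ndarray]:
    """Segment every frame of a series.

    Returns ``(hard_labels, soft)`` where ``hard_labels`` is (T, H, W) int
    (per-pixel argmax over the soft channels, ties to the lowest class code)
    and ``soft`` is (T, C+1, H, W).
    """
    images = np.asarray(images)
    soft = network.predict_soft(images)
    hard = np.argmax(soft, axis=1).astype(np.int16)
    return hard, soft


def postprocess_labels(labels: np.ndarray, scheme: ClassScheme = VOCAL_TRACT_SCHEME) -> np.ndarray:
    """Keep only the largest 8-connected component of each foreground class.

    Pixels of smaller components are reassigned to background.  Idempotent;
    ties between equal-sized components are broken in favour of the
    first-scanned component.
    """
    labels = np.asarray(labels)
    if labels.max(initial=0) > max(scheme.codes) or labels.min(initial=0) < 0:
        raise ValueError("label map contains codes outside the class scheme")
    out = labels.copy()
    for code in scheme.foreground_codes:
        mask = labels == code
        if not mask.any():
            continue
        comps, n = cc_label(mask, connectivity=2, return_num=True)
        if n <= 1:
            continue
        sizes = np.bincount(comps.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1  # first max -> first-scanned component
        out[mask & (comps != keep)] = 0
    return out
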