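"""Synthetic dynamic vocal-tract phantom with ground-truth everything.

The study data this package targets (dynamic midsagittal image series of
speakers, with six-class label maps and per-frame closure labels) are not
publicly deposited, so this module generates a geometric stand-in that
exercises every downstream stage: a static head containing a posterior
pharyngeal wall band, a soft-palate flap that periodically advances until it
contacts the wall (velopharyngeal closures), a smoothly oscillating tongue
and jaw, an airway filled by the vocal-tract class, piecewise-constant
class intensities plus Gaussian noise min-max normalised to [0, 1], and --
crucially -- a known dense displacement field per frame mapping the
reference frame to that frame.

Moving structures translate rigidly inside disjoint rectangular support
bands, so the true backward field is piecewise constant: ``-d_t`` inside a
structure's band at frame ``t`` and zero elsewhere.  The resulting fields
are discontinuous across band edges, which is precisely the kind of motion
(contact and separation) that smooth registration models cannot represent.

All geometry is deterministic given the spec; the only randomness is the
intensity noise, driven by ``spec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, polygon

from .metrics import ClosureDetectorConfig, ClosureSeries, closure_series, detect_closure
from .segmentation import HEAD, JAW, SOFT_PALATE, TONGUE, TOOTH_SPACE, VOCAL_TRACT

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "select_reference_frame"]

# piecewise-constant class intensities before noise (air dark, tissue bright)
CLASS_INTENSITY = {
    0: 0.0,
    HEAD: 0.8,
    SOFT_PALATE: 0.6,
    JAW: 0.7,
    TONGUE: 0.5,
    VOCAL_TRACT: 0.05,
    TOOTH_SPACE: 0.3,
}

_MIN_CONTACT_GAP = 4.0  # rest gap (px) between palate tip and wall when static
_CLOSURE_PLATEAU = 3    # frames per closure interval
_TONGUE_PERIOD = 10.0   # frames per tongue/jaw oscillation (1 s at 10 fps)


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    n_frames: int = 40
    n_closures: int = 3
    palate_amplitude: float = 6.0
    tongue_amplitude: float = 4.0
    noise_sd: float = 0.02
    orientation: str = "posterior-right"
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("height and width must be >= 32")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_closures < 0:
            raise ValueError("n_closures must be >= 0")
        if self.palate_amplitude < 0 or self.tongue_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.orientation not in ("posterior-right", "posterior-left"):
            raise ValueError("orientation must be 'posterior-right' or 'posterior-left'")


@dataclass
class PhantomOutput:
    images: np.ndarray            # (T, H, W) float in [0, 1]
    labels: np.ndarray            # (T, H, W) int16 class codes
    closure_truth: ClosureSeries  # per-frame binary closure labels
    fields_to_reference: np.ndarray  # (T, H, W, 2): warp reference labels to frame t
    reference_index: int
    detector_config: ClosureDetectorConfig = field(default_factory=ClosureDetectorConfig)


class _Geometry:
    """Resolved pixel geometry for a posterior-right phantom."""

    def __init__(self, spec: PhantomSpec):
        h, w = spec.height, spec.width
        amp = spec.palate_amplitude
        t_amp = spec.tongue_amplitude
        j_amp = 0.5 * t_amp

        self.top_band_rows = (2, max(4, h // 8))            # inclusive rows of hard palate/skull
        self.wall_cols = (w - 5, w - 2)                     # 4-px posterior pharyngeal wall
        self.cavity = (self.top_band_rows[1] + 1, h - 1, 3, w - 6)  # r0, r1, c0, c1 airway

        wall_left = self.wall_cols[0]
        self.flap_len = max(8, h // 5)
        self.flap_run = max(8, w // 6)
        self.flap_halfwidth = 1.8
        self.tip_rest_x = wall_left - 0.6 - max(amp, _MIN_CONTACT_GAP)
        self.flap_top_row = self.top_band_rows[1] + 1
        self.flap_tip_row = self.flap_top_row + self.flap_len - 1
        self.flap_anchor_x = self.tip_rest_x - self.flap_run
        band_r1 = min(h - 1, self.flap_tip_row + 3)
        self.palate_band = (
            self.flap_top_row, band_r1,
            int(math.floor(self.flap_anchor_x - amp - 3)), wall_left - 1,
        )

        self.tongue_center = (0.60 * h, 0.42 * w)
        self.tongue_radii = (0.10 * h, 0.14 * w)
        cy, cx = self.tongue_center
        ry, rx = self.tongue_radii
        self.tongue_band = (
            int(math.floor(cy - ry - t_amp - 2)), int(math.ceil(cy + ry + t_amp + 2)),
            int(math.floor(cx - rx - 2)), int(math.ceil(cx + rx + 2)),
        )

        self.jaw_top_row = h - max(5, h // 8)
        self.jaw_cols = (3, w - 8)
        self.jaw_band = (
            int(math.floor(self.jaw_top_row - j_amp - 2)), h - 1,
            self.jaw_cols[0], self.jaw_cols[1],
        )
        self.tooth = (self.jaw_top_row + 1, 6)  # top-left corner of 3x3 tooth-space box

        self._validate(spec)

    def _validate(self, spec: PhantomSpec):
        h, w = spec.height, spec.width
        amp = spec.palate_amplitude
        if spec.n_closures > 0 and amp < _MIN_CONTACT_GAP:
            raise ValueError(
                f"palate_amplitude={amp} cannot produce closures; the palate rests "
                f"{_MIN_CONTACT_GAP} px from the wall, so an amplitude >= {_MIN_CONTACT_GAP} is needed"
            )
        pr0, pr1, pc0, pc1 = self.palate_band
        if pc0 - amp < self.cavity[2]:
            raise ValueError("frame too narrow for the soft-palate flap and its motion")
        if self.flap_anchor_x - amp - 3 <= self.cavity[2]:
            raise ValueError("frame too narrow for the soft-palate flap and its motion")
        tr0, tr1, tc0, tc1 = self.tongue_band
        if tr0 <= pr1:
            raise ValueError("frame too small: tongue band overlaps the soft-palate band")
        jr0 = self.jaw_band[0]
        if tr1 >= jr0:
            raise ValueError("frame too small: tongue band overlaps the jaw band")
        cy, cx = self.tongue_center
        ry, rx = self.tongue_radii
        if cy + ry + spec.tongue_amplitude >= jr0 - 1:
            raise ValueError("frame too small: tongue motion reaches the jaw")
        if self.jaw_top_row + 5 > h - 1:
            raise ValueError("frame too short for the jaw")
        if self.tooth[1] + 2 >= self.jaw_cols[1]:
            raise ValueError("frame too narrow for the tooth space")


def _closure_drive(n_frames: int, n_closures: int) -> np.ndarray:
    """Per-frame palate drive in [0, 1]: plateaus of 1 during closures, 0.5 ramps."""
    drive = np.zeros(n_frames)
    if n_closures == 0:
        return drive
    seg = n_frames // n_closures
    if seg < _CLOSURE_PLATEAU + 3:
        raise ValueError(
            f"n_frames={n_frames} too small for {n_closures} closures "
            f"(need >= {n_closures * (_CLOSURE_PLATEAU + 3)})"
        )
    for k in range(n_closures):
        start = k * seg + (seg - _CLOSURE_PLATEAU) // 2
        start = max(start, k * seg + 2)  # keep frame 0 (and segment starts) open
        drive[start : start + _CLOSURE_PLATEAU] = 1.0
        if start - 1 >= 0:
            drive[start - 1] = 0.5
        if start + _CLOSURE_PLATEAU < n_frames:
            drive[start + _CLOSURE_PLATEAU] = 0.5
    return drive


def _paint_frame(spec: PhantomSpec, geo: _Geometry, e: float, dy_t: float, dy_j: float) -> np.ndarray:
    h, w = spec.height, spec.width
    lab = np.zeros((h, w), dtype=np.int16)

    r0, r1, c0, c1 = geo.cavity
    lab[r0 : r1 + 1, c0 : c1 + 1] = VOCAL_TRACT
    lab[geo.top_band_rows[0] : geo.top_band_rows[1] + 1, 3 : w - 2] = HEAD
    lab[2:, geo.wall_cols[0] : geo.wall_cols[1] + 1] = HEAD

    # jaw (with tooth space), translated vertically by dy_j
    jt = geo.jaw_top_row + dy_j
    jt_px = int(round(jt))
    lab[max(0, jt_px) :, geo.jaw_cols[0] : geo.jaw_cols[1] + 1] = JAW
    tr, tc = geo.tooth
    tr_px = int(round(tr + dy_j))
    lab[tr_px : tr_px + 3, tc : tc + 3] = TOOTH_SPACE

    # tongue ellipse, translated vertically by dy_t
    cy, cx = geo.tongue_center
    ry, rx = geo.tongue_radii
    yy, xx = np.ogrid[:h, :w]
    tongue = ((yy - (cy + dy_t)) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    lab[tongue] = TONGUE

    # soft-palate flap: thick slanted bar + blunt tip, translated by e in x
    top_r = geo.flap_top_row - 0.5
    tip_r = geo.flap_tip_row
    ax = geo.flap_anchor_x + e
    tx = geo.tip_rest_x + e
    dr, dc = tip_r - top_r, tx - ax
    norm = math.hypot(dr, dc)
    pr, pc_ = -dc / norm * geo.flap_halfwidth, dr / norm * geo.flap_halfwidth
    rr, cc = polygon(
        [top_r + pr, tip_r + pr, tip_r - pr, top_r - pr],
        [ax + pc_, tx + pc_, tx - pc_, ax - pc_],
        shape=(h, w),
    )
    flap = np.zeros((h, w), dtype=bool)
    flap[rr, cc] = True
    rr, cc = disk((tip_r, tx - 0.5), 2.3, shape=(h, w))
    flap[rr, cc] = True
    # clip to the cavity side: never overwrite the head band or wall
    flap[: geo.flap_top_row, :] = False
    flap[:, geo.wall_cols[0] :] = False
    lab[flap] = SOFT_PALATE
    return lab


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate a synthetic series; see the module docstring for the model."""
    geo = _Geometry(spec)
    drive = _closure_drive(spec.n_frames, spec.n_closures)
    t = np.arange(spec.n_frames)
    e_sched = spec.palate_amplitude * drive
    dy_tongue = spec.tongue_amplitude * np.sin(2 * np.pi * t / _TONGUE_PERIOD)
    dy_jaw = 0.5 * spec.tongue_amplitude * np.sin(2 * np.pi * t / _TONGUE_PERIOD)

    h, w = spec.height, spec.width
    labels = np.empty((spec.n_frames, h, w), dtype=np.int16)
    fields = np.zeros((spec.n_frames, h, w, 2), dtype=np.float64)
    for i in range(spec.n_frames):
        labels[i] = _paint_frame(spec, geo, e_sched[i], dy_tongue[i], dy_jaw[i])
        r0, r1, c0, c1 = geo.palate_band
        fields[i, r0 : r1 + 1, c0 : c1 + 1, 0] = -e_sched[i]
        r0, r1, c0, c1 = geo.tongue_band
        fields[i, r0 : r1 + 1, c0 : c1 + 1, 1] = -dy_tongue[i]
        r0, r1, c0, c1 = geo.jaw_band
        fields[i, r0 : r1 + 1, c0 : c1 + 1, 1] = -dy_jaw[i]

    # intensity model: per-class constants + noise, then series-wide min-max
    intensity = np.zeros(max(CLASS_INTENSITY) + 1)
    for code, v in CLASS_INTENSITY.items():
        intensity[code] = v
    images = intensity[labels]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        images = images + rng.normal(0.0, spec.noise_sd, images.shape)
    lo, hi = images.min(), images.max()
    images = (images - lo) / (hi - lo)

    cfg = ClosureDetectorConfig(orientation=spec.orientation)
    if spec.orientation == "posterior-left":
        images = images[:, :, ::-1].copy()
        labels = labels[:, :, ::-1].copy()
        fields = fields[:, :, ::-1, :].copy()
        fields[..., 0] *= -1.0

    closure_truth = closure_series(labels, cfg)
    intended = tuple(int(d == 1.0) for d in drive)
    if closure_truth.values != intended:
        raise RuntimeError(
            "phantom self-check failed: detected closures do not match the closure "
            "schedule; the requested geometry cannot realise the schedule"
        )
    if closure_truth.n_closures != spec.n_closures:
        raise RuntimeError("phantom self-check failed: wrong number of closure runs")

    reference_index = select_reference_frame(labels, cfg)
    if np.any(fields[reference_index] != 0):
        raise RuntimeError("phantom self-check failed: reference frame field is not identity")

    return PhantomOutput(
        images=images,
        labels=labels,
        closure_truth=closure_truth,
        fields_to_reference=fields,
        reference_index=reference_index,
        detector_config=cfg,
    )


def _classes_adjacent(labels: np.ndarray, code_a: int, code_b: int) -> bool:
    from scipy.ndimage import binary_dilation

    a = labels == code_a
    b = labels == code_b
    if not a.any() or not b.any():
        return False
    return bool((binary_dilation(a, structure=np.ones((3, 3), dtype=bool)) & b).any())


def select_reference_frame(labels: np.ndarray,
                           cfg: ClosureDetectorConfig = ClosureDetectorConfig()) -> int:
    """First frame suitable as the reference (moving) image of a series.

    Criteria, evaluated as class adjacency on the label map:

    1. upper and lower lips apart: no head-jaw contact;
    2. tongue not touching the roof of the mouth or soft palate: no
       tongue-head and no tongue-soft-palate contact;
    3. soft palate not in contact with the pharyngeal wall: the posterior
       closure detector reports no closure (the anterior attachment of the
       soft palate to the hard palate does not count as contact).

    Raises ``ValueError`` if no frame qualifies, in which case a reference
    index must be supplied manually.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3 or labels.shape[0] == 0:
        raise ValueError("expected a non-empty (T, H, W) label series")
    for i, frame in enumerate(labels):
        if _classes_adjacent(frame, HEAD, JAW):
            continue
        if _classes_adjacent(frame, TONGUE, HEAD) or _classes_adjacent(frame, TONGUE, SOFT_PALATE):
            continue
        if detect_closure(frame, cfg):
            continue
        return i
    raise ValueError(
        "no frame satisfies the reference criteria (lips apart, tongue free, "
        "soft palate off the pharyngeal wall); supply a reference index explicitly"
    )
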