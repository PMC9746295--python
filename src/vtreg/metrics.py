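"""Evaluation of displacement fields: overlap, surface distance and closures.

Registration accuracy is measured by warping the moving frame's ground-truth
label map with the estimated field and comparing it with the fixed frame's
ground truth using three metrics: the Dice similarity coefficient (DSC) and
average surface distance (ASD) per class, and a clinically motivated metric
counting how many true velopharyngeal closures the fields capture.

A frame shows velopharyngeal closure when at least ``min_contact_pixels``
(default three) posterior soft-palate pixels are adjacent to head pixels
(the pharyngeal wall belongs to the head class).  A closure is a maximal run
of consecutive closed frames; a true closure counts as captured when its run
overlaps any run in the predicted series by at least one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import cKDTree

from .segmentation import HEAD, SOFT_PALATE, VOCAL_TRACT_SCHEME, ClassScheme

__all__ = [
    "ClosureSeries",
    "ClosureDetectorConfig",
    "MetricsReport",
    "dice",
    "average_surface_distance",
    "detect_closure",
    "closure_series",
    "count_captured_closures",
    "evaluate_registration",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE = np.ones((3, 3), dtype=bool)


def _runs_of_ones(values: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(values):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return runs


@dataclass(frozen=True)
class ClosureSeries:
    """Per-frame binary closure labels and their maximal runs of ones."""

    values: tuple

    def __post_init__(self):
        vals = tuple(int(v) for v in self.values)
        if any(v not in (0, 1) for v in vals):
            raise ValueError("closure values must be binary")
        object.__setattr__(self, "values", vals)

    @property
    def runs(self) -> list[tuple[int, int]]:
        return _runs_of_ones(self.values)

    @property
    def n_closures(self) -> int:
        return len(self.runs)

    def __len__(self):
        return len(self.values)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.int8)


@dataclass(frozen=True)
class ClosureDetectorConfig:
    min_contact_pixels: int = 3
    posterior_fraction: float = 1.0 / 3.0
    orientation: str = "posterior-right"
    connectivity: int = 8

    def __post_init__(self):
        if self.min_contact_pixels < 1:
            raise ValueError("min_contact_pixels must be >= 1")
        if not (0 < self.posterior_fraction <= 1):
            raise ValueError("posterior_fraction must be in (0, 1]")
        if self.orientation not in ("posterior-right", "posterior-left"):
            raise ValueError("orientation must be 'posterior-right' or 'posterior-left'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); both empty -> 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask.

    Pixels on the image border count as boundary (out-of-image is outside).
    """
    return mask & ~binary_erosion(mask, structure=_CROSS, border_value=0)


def average_surface_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric average surface distance between two masks, in pixels.

    Mean over the pooled boundary pixels of A and B of the Euclidean distance
    to the nearest boundary pixel of the other mask.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("average surface distance is undefined for an empty mask")
    pa = np.argwhere(_boundary(a))
    pb = np.argwhere(_boundary(b))
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


def detect_closure(labels: np.ndarray, cfg: ClosureDetectorConfig = ClosureDetectorConfig(),
                   *, head_code: int = HEAD, palate_code: int = SOFT_PALATE) -> bool:
    """Does one label map show velopharyngeal closure?

    True iff at least ``cfg.min_contact_pixels`` soft-palate pixels within
    the posterior portion of the soft palate's bounding box (the posterior
    ``posterior_fraction`` of its columns, given the image orientation) have
    at least one head-class neighbour under ``cfg.connectivity``.
    """
    labels = np.asarray(labels)
    palate = labels == palate_code
    head = labels == head_code
    if not palate.any() or not head.any():
        return False
    cols = np.nonzero(palate.any(axis=0))[0]
    c0, c1 = cols[0], cols[-1]
    width = c1 - c0 + 1
    n_post = max(1, int(np.ceil(cfg.posterior_fraction * width)))
    posterior = np.zeros_like(palate)
    if cfg.orientation == "posterior-right":
        posterior[:, c1 - n_post + 1 : c1 + 1] = True
    else:
        posterior[:, c0 : c0 + n_post] = True
    struct = _SQUARE if cfg.connectivity == 8 else _CROSS
    contact = palate & posterior & binary_dilation(head, structure=struct)
    return int(contact.sum()) >= cfg.min_contact_pixels


def closure_series(labels: np.ndarray, cfg: ClosureDetectorConfig = ClosureDetectorConfig(),
                   **kwargs) -> ClosureSeries:
    """Apply the closure detector to every frame of a label-map series."""
    return ClosureSeries(tuple(int(detect_closure(frame, cfg, **kwargs)) for frame in labels))


def count_captured_closures(truth: ClosureSeries, predicted: ClosureSeries) -> int:
    """Number of true closure runs sharing at least one frame with a predicted run.

    A single predicted run overlapping two truth runs captures both.
    """
    if len(truth) != len(predicted):
        raise ValueError("closure series lengths differ")
    captured = 0
    for ts, te in truth.runs:
        if any(ps <= te and pe >= ts for ps, pe in predicted.runs):
            captured += 1
    return captured


@dataclass
class MetricsReport:
    """Per-frame, per-class DSC/ASD table plus closure-capture summary."""

    frame_table: pd.DataFrame
    truth_closures: ClosureSeries
    predicted_closures: ClosureSeries
    captured_closures: int

    @property
    def n_truth_closures(self) -> int:
        return self.truth_closures.n_closures

    def summary(self) -> dict:
        per_class = (
            self.frame_table.groupby("class_name")[["dsc", "asd"]].median().to_dict("index")
        )
        return {
            "per_class_median": per_class,
            "mean_dsc": float(self.frame_table["dsc"].mean()),
            "truth_closures": self.n_truth_closures,
            "captured_closures": self.captured_closures,
        }

    def write(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame_table.to_csv(out / "metrics.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=2, default=float))


def evaluate_registration(fixed_gt: np.ndarray, warped_moving_gt: np.ndarray,
                          cfg: ClosureDetectorConfig = ClosureDetectorConfig(),
                          scheme: ClassScheme = VOCAL_TRACT_SCHEME) -> MetricsReport:
    """Compare warped moving ground-truth labels with fixed ground-truth labels.

    One DSC and one ASD value per frame and foreground class (ASD is NaN when
    either mask is empty, recorded as missing), plus the captured-closure
    count between the closure series of the two inputs.
    """
    fixed_gt = np.asarray(fixed_gt)
    warped_moving_gt = np.asarray(warped_moving_gt)
    if fixed_gt.shape != warped_moving_gt.shape:
        raise ValueError("series shapes differ")
    rows = []
    for t, (f, w) in enumerate(zip(fixed_gt, warped_moving_gt)):
        for code in scheme.foreground_codes:
            fm, wm = f == code, w == code
            try:
                asd = average_surface_distance(fm, wm)
            except ValueError:
                asd = np.nan
            rows.append({
                "frame": t,
                "class_code": code,
                "class_name": scheme.name_of(code),
                "dsc": dice(fm, wm),
                "asd": asd,
            })
    truth = closure_series(fixed_gt, cfg)
    predicted = closure_series(warped_moving_gt, cfg)
    return MetricsReport(
        frame_table=pd.DataFrame(rows),
        truth_closures=truth,
        predicted_closures=predicted,
        captured_closures=count_captured_closures(truth, predicted),
    )
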