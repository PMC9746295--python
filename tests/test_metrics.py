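"""Overlap, surface-distance and closure metrics against brute-force oracles."""

import numpy as np
import pytest

from vtreg.metrics import (ClosureDetectorConfig, ClosureSeries, average_surface_distance,
                           closure_series, count_captured_closures, detect_closure, dice,
                           evaluate_registration)
from vtreg.segmentation import HEAD, SOFT_PALATE


# -- brute-force oracles -----------------------------------------------------

def bf_dice(a, b):
    inter = sum(1 for p in zip(a.ravel(), b.ravel()) if p[0] and p[1])
    return 1.0 if (a.sum() + b.sum()) == 0 else 2 * inter / (int(a.sum()) + int(b.sum()))


def bf_boundary(mask):
    pts = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            nbrs = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            if any(not (0 <= y < h and 0 <= x < w) or not mask[y, x] for y, x in nbrs):
                pts.append((i, j))
    return pts


def bf_asd(a, b):
    pa, pb = bf_boundary(a), bf_boundary(b)
    d = lambda p, q: np.hypot(p[0] - q[0], p[1] - q[1])
    s = sum(min(d(p, q) for q in pb) for p in pa) + sum(min(d(q, p) for p in pa) for q in pb)
    return s / (len(pa) + len(pb))


def bf_runs(values):
    runs, start = [], None
    for i, v in enumerate(list(values) + [0]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def bf_captured(truth, pred):
    count = 0
    for ts, te in bf_runs(truth):
        if any(any(t in range(ps, pe + 1) for t in range(ts, te + 1)) for ps, pe in bf_runs(pred)):
            count += 1
    return count


def random_blob(rng, shape=(12, 12), p=0.3):
    m = rng.random(shape) < p
    m[0, 0] = True  # never empty
    return m


# -- dice / asd --------------------------------------------------------------

class TestDice:
    def test_identical_masks(self, rng):
        m = random_blob(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_and_both_empty(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0
        assert dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_worked_example(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0] = True
        b[0, 2:] = True
        b[1, :2] = True
        assert dice(a, b) == 0.5

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            a, b = random_blob(rng), random_blob(rng)
            assert dice(a, b) == pytest.approx(bf_dice(a, b))


class TestASD:
    def test_identical_masks_zero(self, rng):
        m = random_blob(rng)
        assert average_surface_distance(m, m) == 0.0

    def test_single_pixels_three_apart(self):
        a = np.zeros((5, 8), bool)
        b = np.zeros((5, 8), bool)
        a[2, 2] = True
        b[2, 5] = True
        assert average_surface_distance(a, b) == pytest.approx(3.0)

    def test_symmetric_and_matches_brute_force(self, rng):
        for _ in range(30):
            a, b = random_blob(rng), random_blob(rng)
            v = average_surface_distance(a, b)
            assert v == pytest.approx(average_surface_distance(b, a))
            assert v == pytest.approx(bf_asd(a, b))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            average_surface_distance(np.zeros((4, 4), bool), np.ones((4, 4), bool))


# -- closure detection -------------------------------------------------------

def _contact_frame(n_contact, gap=0):
    """Palate bar whose posterior end has ``n_contact`` pixels adjacent to a
    head wall (or ``gap`` columns away from it)."""
    lab = np.zeros((16, 16), np.int16)
    lab[:, 13:15] = HEAD
    lab[5:11, 2:12 - gap] = 0
    lab[6:10, 2:12] = SOFT_PALATE           # 4-row bar, cols 2..11
    lab[6:10, 12 - gap:] = np.where(lab[6:10, 12 - gap:] == HEAD, HEAD, 0)
    lab[6:6 + n_contact, 12] = SOFT_PALATE if gap == 0 else 0
    return lab


class TestDetector:
    def test_three_contacting_pixels_is_closure(self):
        assert detect_closure(_contact_frame(3)) is True

    def test_two_contacting_pixels_is_not(self):
        assert detect_closure(_contact_frame(2)) is False

    def test_no_palate_or_no_head_is_false(self):
        lab = np.zeros((8, 8), np.int16)
        assert detect_closure(lab) is False
        lab[:, 6] = HEAD
        assert detect_closure(lab) is False

    def test_anterior_contact_does_not_count(self):
        # 3+ palate pixels touch head far from the posterior end of the palate
        lab = np.zeros((16, 20), np.int16)
        lab[4, 2:18] = 0
        lab[5, 2:17] = SOFT_PALATE
        lab[4, 2:6] = HEAD  # anterior attachment above the palate bar
        assert detect_closure(lab) is False

    def test_threshold_monotonicity(self, rng):
        for n in range(1, 6):
            frame = _contact_frame(n)
            fired = [detect_closure(frame, ClosureDetectorConfig(min_contact_pixels=k))
                     for k in (1, 2, 3, 4, 5)]
            # once the detector stops firing it never fires at higher thresholds
            assert fired == sorted(fired, reverse=True)


class TestRunsAndCapture:
    def test_run_extraction_worked_example(self):
        s = ClosureSeries((0, 1, 1, 0, 1, 0))
        assert s.runs == [(1, 2), (4, 4)]

    def test_all_zeros_and_all_ones(self):
        assert ClosureSeries((0,) * 5).runs == []
        assert ClosureSeries((1,) * 5).runs == [(0, 4)]

    def test_capture_worked_example(self):
        truth = ClosureSeries((0, 1, 1, 0, 1, 1, 0))
        pred = ClosureSeries((0, 0, 1, 0, 0, 1, 1))
        assert count_captured_closures(truth, pred) == 2

    def test_nothing_captured_and_self_capture(self):
        truth = ClosureSeries((0, 1, 1, 0, 1, 1, 0))
        assert count_captured_closures(truth, ClosureSeries((0,) * 7)) == 0
        assert count_captured_closures(truth, truth) == truth.n_closures

    def test_single_predicted_run_captures_two_truth_runs(self):
        truth = ClosureSeries((1, 1, 0, 1, 1))
        pred = ClosureSeries((0, 1, 1, 1, 0))
        assert count_captured_closures(truth, pred) == 2

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(100):
            t = (rng.random(12) < 0.4).astype(int)
            p = (rng.random(12) < 0.4).astype(int)
            st, sp = ClosureSeries(tuple(t)), ClosureSeries(tuple(p))
            assert st.runs == bf_runs(t)
            assert count_captured_closures(st, sp) == bf_captured(t, p)

    def test_capture_monotone_in_predicted_ones(self, rng):
        for _ in range(25):
            t = tuple((rng.random(10) < 0.4).astype(int))
            p = (rng.random(10) < 0.3).astype(int)
            base = count_captured_closures(ClosureSeries(t), ClosureSeries(tuple(p)))
            i = rng.integers(0, 10)
            p2 = p.copy()
            p2[i] = 1
            more = count_captured_closures(ClosureSeries(t), ClosureSeries(tuple(p2)))
            assert more >= base

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_captured_closures(ClosureSeries((0, 1)), ClosureSeries((0, 1, 0)))


class TestEvaluateRegistration:
    def test_perfect_registration(self, phantom):
        rep = evaluate_registration(phantom.labels, phantom.labels)
        assert (rep.frame_table.dsc == 1.0).all()
        assert (rep.frame_table.asd == 0.0).all()
        assert rep.captured_closures == rep.n_truth_closures == 3

    def test_erased_palate_degenerate_case(self, phantom):
        broken = phantom.labels.copy()
        broken[broken == SOFT_PALATE] = 0
        rep = evaluate_registration(phantom.labels, broken)
        sp = rep.frame_table[rep.frame_table.class_code == SOFT_PALATE]
        assert (sp.dsc == 0.0).all()
        assert sp.asd.isna().all()
        assert rep.captured_closures == 0

    def test_identity_field_reproduces_direct_metric_calls(self, phantom):
        ref = phantom.reference_index
        warped = np.stack([phantom.labels[ref]] * len(phantom.labels))
        rep = evaluate_registration(phantom.labels, warped)
        t = 5
        row = rep.frame_table[(rep.frame_table.frame == t)
                              & (rep.frame_table.class_code == SOFT_PALATE)].iloc[0]
        a = phantom.labels[t] == SOFT_PALATE
        b = phantom.labels[ref] == SOFT_PALATE
        assert row.dsc == pytest.approx(dice(a, b))
        assert row.asd == pytest.approx(average_surface_distance(a, b))

    def test_report_row_count(self, phantom):
        rep = evaluate_registration(phantom.labels, phantom.labels)
        assert len(rep.frame_table) == len(phantom.labels) * 6
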