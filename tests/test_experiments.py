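"""Training protocol, cross-validation bookkeeping and statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vtreg.experiments import (AugmentationRanges, ExperimentConfig, SubjectData,
                               augment_dataset, evaluate_on_subject, holm_bonferroni,
                               make_fold_plan, make_training_pairs, mcnemar_closures,
                               nested_cv_search, paired_group_test, train_framework)
from vtreg.losses import LossWeights
from vtreg.phantom import PhantomSpec, generate_phantom


def small_cfg(**kw):
    base = dict(epochs=1, augmentation_factor=1, batch_pairs=4,
                encoder_widths=(4, 8), decoder_widths=(8, 4, 4),
                learning_rate=1e-3, seed=0)
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def tiny_subject():
    out = generate_phantom(PhantomSpec(n_frames=8, n_closures=1, seed=11))
    return SubjectData("s0", out.images, out.labels, out.reference_index), out


class TestTrainingPairs:
    def test_every_frame_fixed_once_none_self_paired(self):
        pairs = make_training_pairs({"a": 7, "b": 4}, 0)
        assert len(pairs) == 11
        fixed = [(s, f) for s, f, _ in pairs]
        assert len(set(fixed)) == 11
        assert all(f != m for _, f, m in pairs)

    def test_deterministic_given_seed_and_varies_across_seeds(self):
        p1 = make_training_pairs({"a": 20}, 3)
        p2 = make_training_pairs({"a": 20}, 3)
        p3 = make_training_pairs({"a": 20}, 4)
        assert p1 == p2
        assert p1 != p3

    def test_single_frame_subject_rejected(self):
        with pytest.raises(ValueError):
            make_training_pairs({"a": 1}, 0)

    def test_partner_distribution_is_uniform(self):
        """Chi-square test over many epochs should not reject uniformity of
        the partner choice at the 1% level."""
        n, reps = 6, 3000
        counts = np.zeros((n, n))
        rng = np.random.default_rng(0)
        for _ in range(reps):
            for _, f, m in make_training_pairs({"a": n}, rng):
                counts[f, m] += 1
        for f in range(n):
            observed = np.delete(counts[f], f)
            p = stats.chisquare(observed).pvalue
            assert p > 0.01


class TestAugmentation:
    def test_factor_multiplies_dataset_size(self, tiny_subject):
        sd, _ = tiny_subject
        pairs = make_training_pairs({"s0": sd.n_frames}, 0)
        cfg = small_cfg(augmentation_factor=4)
        samples = augment_dataset(pairs, {"s0": sd}, cfg, 0)
        assert len(samples) == 4 * len(pairs)

    def test_zero_ranges_give_copies_of_originals(self, tiny_subject):
        sd, _ = tiny_subject
        pairs = make_training_pairs({"s0": sd.n_frames}, 0)
        cfg = small_cfg(augmentation_factor=3, augmentation=AugmentationRanges(
            translation=0.0, rotation=0.0, crop_fraction=1.0, rescale_low=1.0, rescale_high=1.0))
        samples = augment_dataset(pairs, {"s0": sd}, cfg, 0)
        n = len(pairs)
        for k in range(n):
            assert np.allclose(samples[k].fixed_img, samples[k + n].fixed_img, atol=1e-6)
            assert np.array_equal(samples[k].fixed_labels, samples[k + n].fixed_labels)

    def test_augmented_labels_contain_only_original_codes(self, tiny_subject):
        sd, _ = tiny_subject
        pairs = make_training_pairs({"s0": sd.n_frames}, 0)
        samples = augment_dataset(pairs, {"s0": sd}, small_cfg(augmentation_factor=2), 0)
        codes = set(np.unique(sd.labels))
        for s in samples:
            assert set(np.unique(s.fixed_labels)) <= codes


class TestTrainFramework:
    def test_one_epoch_bookkeeping(self, tiny_subject):
        sd, _ = tiny_subject
        net, hist = train_framework({"s0": sd}, small_cfg())
        assert len(hist) == int(np.ceil(sd.n_frames / 4))
        assert {"epoch", "step", "mse", "grad", "dice", "total"} <= set(hist.columns)
        assert np.isfinite(hist.total).all()

    def test_image_only_configuration_has_two_input_channels(self, tiny_subject):
        sd, _ = tiny_subject
        cfg = small_cfg(seg_classes_in=(), loss_weights=LossWeights(0.01, 0.0))
        net, hist = train_framework({"s0": sd}, cfg)
        assert net.in_channels == 2
        assert hist.dice.isna().all()  # no Dice term in the image-only objective

    def test_loss_decreases_over_short_training(self):
        # a two-frame subject makes every epoch train on the same fixed pair
        out = generate_phantom(PhantomSpec(n_frames=2, n_closures=0, seed=21))
        sd = SubjectData("s0", out.images, out.labels, 0)
        net, hist = train_framework({"s0": sd}, small_cfg(epochs=10, learning_rate=3e-3))
        first = hist[hist.epoch < 2].total.mean()
        last = hist[hist.epoch >= hist.epoch.max() - 1].total.mean()
        assert last < first

    def test_evaluation_report_schema(self, tiny_subject):
        sd, _ = tiny_subject
        net, _ = train_framework({"s0": sd}, small_cfg())
        rep = evaluate_on_subject(net, sd)
        assert len(rep.frame_table) == sd.n_frames * 6
        assert rep.captured_closures <= rep.n_truth_closures


class TestFoldBookkeeping:
    def test_every_subject_left_out_once(self):
        plan = make_fold_plan(["a", "b", "c", "d"], [(1e-3, 0.01, 1.0)])
        tested = [t for t, _ in plan.main_folds]
        assert sorted(tested) == ["a", "b", "c", "d"]
        for main, train in plan.main_folds:
            assert main not in train
            nested_val = [v for v, _ in plan.nested_folds(main)]
            assert sorted(nested_val) == sorted(train)
            for v, tr in plan.nested_folds(main):
                assert v not in tr and main not in tr

    def test_too_few_subjects_or_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b"], [(1, 1, 1)])
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b", "c"], [])


class TestNestedCVSelection:
    @staticmethod
    def _subjects(n=3):
        # metadata-only stand-ins; the injected scorer never touches the data
        return {f"s{i}": SubjectData(f"s{i}", np.zeros((2, 8, 8)), np.zeros((2, 8, 8), np.int16), 0)
                for i in range(n)}

    def test_single_combo_grid_is_forced(self):
        grid = [(1e-3, 0.01, 1.0)]
        res = nested_cv_search(self._subjects(), grid, small_cfg(),
                               train_and_score=lambda *a: 0)
        assert all(v["combo"] == grid[0] for v in res.values())

    def test_strictly_best_combo_selected(self):
        grid = [(1e-3, 0.01, 1.0), (1e-4, 0.1, 1.0), (1e-3, 0.01, 0.1)]

        def scorer(train, val, combo, cfg, segmenter):
            return {grid[0]: 1, grid[1]: 5, grid[2]: 2}[combo]

        res = nested_cv_search(self._subjects(), grid, small_cfg(), train_and_score=scorer)
        assert all(v["combo"] == grid[1] for v in res.values())

    def test_ties_break_by_grid_order(self):
        grid = [(1e-3, 0.01, 1.0), (1e-4, 0.1, 1.0)]
        res = nested_cv_search(self._subjects(), grid, small_cfg(),
                               train_and_score=lambda *a: 3)
        assert all(v["combo"] == grid[0] for v in res.values())

    def test_selection_reproducible_given_seeds(self):
        grid = [(1e-3, 0.01, 1.0), (1e-3, 0.1, 1.0)]

        def scorer(train, val, combo, cfg, segmenter):
            rng = np.random.default_rng(abs(hash((val.name, combo))) % 2**31)
            return int(rng.integers(0, 5))

        r1 = nested_cv_search(self._subjects(), grid, small_cfg(), train_and_score=scorer)
        r2 = nested_cv_search(self._subjects(), grid, small_cfg(), train_and_score=scorer)
        assert r1 == r2


class TestAblation:
    def test_channel_count_adapts_and_reports_have_schema(self, tiny_subject):
        from vtreg.experiments import run_ablation

        sd, _ = tiny_subject
        reports = run_ablation([(2, 5), (1, 2, 5)], {"s0": sd}, small_cfg())
        assert set(reports) == {(2, 5), (1, 2, 5)}
        for subset, per_subject in reports.items():
            rep = per_subject["s0"]
            assert len(rep.frame_table) == sd.n_frames * 6


class TestPairedGroupTest:
    def test_identical_samples_give_p_one(self):
        r = paired_group_test(np.arange(8.0), np.arange(8.0))
        assert r.p_value == 1.0
        assert "zero" in r.note

    def test_symmetric_differences_choose_wilcoxon(self):
        rng = np.random.default_rng(0)
        chosen = []
        for _ in range(50):
            a = rng.normal(0, 1, 30)
            b = a + rng.normal(0.2, 1, 30)  # symmetric differences
            chosen.append(paired_group_test(a, b).test)
        assert np.mean([c == "wilcoxon signed-rank" for c in chosen]) >= 0.9

    def test_heavily_skewed_differences_choose_sign_test(self):
        rng = np.random.default_rng(1)
        chosen = []
        for _ in range(50):
            a = rng.normal(0, 0.05, 40)
            b = a - rng.lognormal(0, 1.5, 40)  # heavy right skew in a - b
            chosen.append(paired_group_test(a, b).test)
        assert np.mean([c == "sign test" for c in chosen]) >= 0.9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_group_test([1.0, 2.0], [2.0, 1.0])


class TestMcNemar:
    def test_identical_captures_give_p_one(self):
        assert mcnemar_closures([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_five_discordant_one_direction(self):
        a = [1, 1, 1, 1, 1, 1, 0]
        b = [0, 0, 0, 0, 0, 1, 0]
        assert mcnemar_closures(a, b) == pytest.approx(2 * 0.5 ** 5)

    def test_symmetric_in_arguments(self, rng):
        a = rng.integers(0, 2, 20)
        b = rng.integers(0, 2, 20)
        assert mcnemar_closures(a, b) == pytest.approx(mcnemar_closures(b, a))


class TestHolmBonferroni:
    def test_single_p_below_alpha_rejected(self):
        assert holm_bonferroni([0.04]).tolist() == [True]

    def test_hand_worked_step_down(self):
        # 0.01 < 0.05/2 -> reject; then 0.04 < 0.05/1 -> reject
        assert holm_bonferroni([0.01, 0.04]).tolist() == [True, True]
        # 0.03 < 0.025 fails at the first step -> nothing rejected
        assert holm_bonferroni([0.03, 0.04]).tolist() == [False, False]

    def test_all_ones_reject_none(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([1.2])
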