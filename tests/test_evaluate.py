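"""Metrics, split plans, cross-validation, and pipeline modes 1/2."""

import numpy as np
import pandas as pd
import pytest

from prostacad import (
    EmulatedSegmenter,
    SplitPlan,
    auc_roc,
    cross_validate,
    run_mode1,
    run_mode2,
    sens_spec,
)
from prostacad.classify import ModelSpec
from prostacad.evaluate import PipelineConfig, baseline_labels, bundle_from_report, cohort_checksum
from tests.conftest import tiny_spec
from prostacad import generate_cohort


def pairwise_auc_oracle(scores, labels):
    """Brute force over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc_roc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs(self):
        assert auc_roc([0.9, 0.3, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert auc_roc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = rng.random(n)
        if rng.random() < 0.5:
            scores = np.round(scores, 1)   # provoke ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert auc_roc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc_roc([0.1, 0.9], [1, 1])


class TestSensSpec:
    def test_arithmetic(self):
        pred = [1, 1, 1, 0, 0, 0, 0, 0]
        true = [1, 1, 1, 1, 0, 0, 0, 0]
        assert sens_spec(pred, true) == (0.75, 1.0)

    def test_perfect_and_inverted(self):
        assert sens_spec([1, 0], [1, 0]) == (1.0, 1.0)
        assert sens_spec([0, 1], [1, 0]) == (0.0, 0.0)

    def test_undefined_sensitivity_is_nan_not_zero(self):
        sens, spec = sens_spec([0, 0], [0, 0])
        assert np.isnan(sens)
        assert spec == 1.0


class TestSplitPlan:
    def test_partition_property(self):
        labels = np.array([0] * 40 + [1] * 26)
        assign = SplitPlan(seed=3).assign(labels)
        train, test, folds = assign["train"], assign["test"], assign["folds"]
        assert set(train) & set(test) == set()
        assert len(train) + len(test) == len(labels)
        counts_tr = {i: 0 for i in train}
        counts_va = {i: 0 for i in train}
        for tr, va in folds:
            assert set(tr) & set(va) == set()
            assert set(tr) | set(va) == set(train)
            for i in tr:
                counts_tr[i] += 1
            for i in va:
                counts_va[i] += 1
        assert all(c == 4 for c in counts_tr.values())
        assert all(c == 1 for c in counts_va.values())

    def test_stratification_and_determinism(self):
        labels = np.array([0] * 40 + [1] * 26)
        a = SplitPlan(seed=5).assign(labels)
        b = SplitPlan(seed=5).assign(labels)
        np.testing.assert_array_equal(a["test"], b["test"])
        # test fraction of positives close to cohort fraction
        frac = labels[a["test"]].mean()
        assert abs(frac - labels.mean()) < 0.1


@pytest.fixture(scope="module")
def lesion_cohort():
    spec = tiny_spec(grid=(64, 64, 16), gland_radius_mm=18.0,
                     class_ratio=(1, 1), lesion_count_range=(1, 2))
    cases, _ = generate_cohort(spec, 16, seed=9)
    return cases


def lesion_cfg(seed=0):
    return PipelineConfig(region_kind="lesion", selection_kind="none",
                          model_spec=ModelSpec(family="gbt", seed=seed))


class TestCrossValidate:
    def test_deterministic_given_seed(self, lesion_cohort):
        plan = SplitPlan(seed=2)
        a = cross_validate(lesion_cohort, lesion_cfg(), plan)
        b = cross_validate(lesion_cohort, lesion_cfg(), plan)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        assert a.test_metrics == b.test_metrics

    def test_report_structure_and_ranges(self, lesion_cohort):
        rep = cross_validate(lesion_cohort, lesion_cfg(), SplitPlan(seed=2))
        assert len(rep.fold_metrics) == 5
        for m in ("auc", "sensitivity", "specificity"):
            vals = rep.fold_metrics[m].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        assert rep.mode == "standalone"
        assert "auc" in rep.test_metrics

    def test_evaluation_data_untouched_by_training(self, lesion_cohort):
        before = cohort_checksum(lesion_cohort)
        cross_validate(lesion_cohort, lesion_cfg(), SplitPlan(seed=2))
        assert cohort_checksum(lesion_cohort) == before


class TestEmulatedSegmenter:
    def test_zero_corruption_returns_ground_truth(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=0.0, fn_rate=0.0, seed=1)
        for i, case in enumerate(lesion_cohort):
            props = seg.propose(case, i)
            assert len(props) == len(case.lesion_masks)
            for (pm, pl), (tm, tl) in zip(props, case.lesion_masks):
                assert pl == tl
                np.testing.assert_array_equal(pm, tm)

    def test_deterministic_per_case(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=2.0, fn_rate=0.2, seed=4)
        a = seg.propose(lesion_cohort[0], 0)
        b = seg.propose(lesion_cohort[0], 0)
        assert len(a) == len(b)
        for (ma, la), (mb, lb) in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_overproposing_adds_false_positives(self, lesion_cohort):
        seg0 = EmulatedSegmenter(fp_rate=0.0, seed=1)
        seg5 = EmulatedSegmenter(fp_rate=5.0, seed=1)
        extra = sum(len(seg5.propose(c, i)) - len(seg0.propose(c, i))
                    for i, c in enumerate(lesion_cohort))
        assert extra > 0


class TestMode1:
    def test_always_pass_equals_baseline(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=1.5, fn_rate=0.1, seed=7)
        rep = run_mode1(lesion_cohort, "always_pass", seg)
        truth = np.array([c.case_label for c in lesion_cohort])
        base = baseline_labels(lesion_cohort, seg)
        sens, spec = sens_spec(base, truth)
        assert rep.test_metrics["sensitivity"] == pytest.approx(sens, nan_ok=True)
        assert rep.test_metrics["specificity"] == pytest.approx(spec, nan_ok=True)
        assert rep.extras["skipped"] == 0

    def test_always_block_sens0_spec1(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=1.5, seed=7)
        rep = run_mode1(lesion_cohort, "always_block", seg)
        assert rep.test_metrics["sensitivity"] == 0.0
        assert rep.test_metrics["specificity"] == 1.0
        assert rep.extras["skipped"] == len(lesion_cohort)

    def test_oracle_filter_raises_specificity_preserves_sensitivity(self, lesion_cohort):
        """The false-positive-reduction goal: an oracle upstream filter on an
        over-proposing segmenter improves specificity at identical sensitivity."""
        seg = EmulatedSegmenter(fp_rate=3.0, fn_rate=0.2, seed=11)
        truth = np.array([c.case_label for c in lesion_cohort])
        base_sens, base_spec = sens_spec(baseline_labels(lesion_cohort, seg), truth)
        rep = run_mode1(lesion_cohort, "oracle", seg)
        assert rep.test_metrics["sensitivity"] == pytest.approx(base_sens)
        assert rep.test_metrics["specificity"] > base_spec


class TestMode2:
    def test_zero_corruption_oracle_perfect(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=0.0, fn_rate=0.0, seed=1)
        rep = run_mode2(lesion_cohort, "oracle", seg)
        assert rep.test_metrics["sensitivity"] == 1.0
        assert rep.test_metrics["specificity"] == 1.0

    def test_always_malignant_equals_baseline(self, lesion_cohort):
        seg = EmulatedSegmenter(fp_rate=2.0, fn_rate=0.1, seed=3)
        rep = run_mode2(lesion_cohort, "always_malignant", seg)
        truth = np.array([c.case_label for c in lesion_cohort])
        sens, spec = sens_spec(baseline_labels(lesion_cohort, seg), truth)
        assert rep.test_metrics["sensitivity"] == pytest.approx(sens, nan_ok=True)
        assert rep.test_metrics["specificity"] == pytest.approx(spec, nan_ok=True)

    def test_trained_lesion_bundle_beats_always_malignant_specificity(self, lesion_cohort):
        """A phantom-trained lesion classifier rejects benign false proposals."""
        rep = cross_validate(lesion_cohort, lesion_cfg(), SplitPlan(seed=2))
        bundle = bundle_from_report(rep, lesion_cfg())
        seg = EmulatedSegmenter(fp_rate=2.0, fn_rate=0.0, seed=5)
        truth = np.array([c.case_label for c in lesion_cohort])
        base_spec = sens_spec(baseline_labels(lesion_cohort, seg), truth)[1]
        m2 = run_mode2(lesion_cohort, bundle, seg)
        assert m2.test_metrics["specificity"] >= base_spec
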