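import numpy as np
import pytest

from aarspred.errors import ComputationError, InputError
from aarspred.evaluation import (
    ConfusionCounts,
    CVSplit,
    DEFAULT_THRESHOLDS,
    EvaluationReport,
    confusion,
    cross_validate,
    make_folds,
    metrics,
    report_to_tsv,
    roc,
    sweep_scores,
)
from aarspred.pipeline import SVMPipeline, build_pipeline
from aarspred.sequence_io import LabeledDataset, ProteinSequence


def _toy_dataset(n_pos, n_neg):
    recs = [
        (ProteinSequence(f"p{i}", "ACDEFGHIKL"), 1) for i in range(n_pos)
    ] + [(ProteinSequence(f"n{i}", "ACDEFGHIKL"), 0) for i in range(n_neg)]
    return LabeledDataset(recs)


class TestMakeFolds:
    def test_stratification_on_balanced_117(self):
        ds = _toy_dataset(117, 117)
        split = make_folds(ds, 5, seed=7)
        for fold in range(1, 6):
            ids = set(split.ids_in_fold(fold))
            pos = sum(1 for s, l in ds.records if l == 1 and s.id in ids)
            neg = sum(1 for s, l in ds.records if l == 0 and s.id in ids)
            assert pos in (23, 24) and neg in (23, 24)

    def test_tiny_balanced_case_exact(self):
        ds = _toy_dataset(5, 5)
        split = make_folds(ds, 5, seed=0)
        for fold in range(1, 6):
            ids = set(split.ids_in_fold(fold))
            assert len(ids) == 2
            assert sum(1 for s, l in ds.records if l == 1 and s.id in ids) == 1

    def test_partition_property(self):
        ds = _toy_dataset(20, 30)
        split = make_folds(ds, 5, seed=1)
        all_ids = [i for f in range(1, 6) for i in split.ids_in_fold(f)]
        assert sorted(all_ids) == sorted(s.id for s in ds.sequences)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(InputError):
            make_folds(_toy_dataset(3, 10), 5, 0)

    def test_deterministic_per_seed(self):
        ds = _toy_dataset(20, 20)
        assert make_folds(ds, 5, 9).assignment == make_folds(ds, 5, 9).assignment
        assert make_folds(ds, 5, 9).assignment != make_folds(ds, 5, 10).assignment


class TestConfusion:
    def test_hand_tally(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.fp, c.fn) == (0, 0)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            confusion([1, 0], [1])

    def test_agrees_with_recount_oracle(self, rng):
        y = rng.integers(0, 2, 1000)
        p = rng.integers(0, 2, 1000)
        c = confusion(list(y), list(p))
        assert c.tp == int(((y == 1) & (p == 1)).sum())
        assert c.tn == int(((y == 0) & (p == 0)).sum())
        assert c.fp == int(((y == 0) & (p == 1)).sum())
        assert c.fn == int(((y == 1) & (p == 0)).sum())
        assert c.total == 1000


# Threshold-table rows from an independent evaluation of 44 positives vs
# 450 negatives; confusion counts back-solved from printed sensitivity and
# specificity. Columns: sensitivity, specificity, accuracy, MCC.
TABLE_ROWS = [
    (100.00, 43.11, 48.18, 0.25),
    (97.73, 63.56, 66.60, 0.35),
    (81.82, 82.44, 82.39, 0.43),
    (72.73, 92.22, 90.49, 0.54),
    (63.64, 97.11, 94.13, 0.63),
    (54.55, 99.56, 95.55, 0.69),
    (52.27, 100.00, 95.75, 0.71),
    (47.73, 100.00, 95.34, 0.67),
    (43.18, 100.00, 94.94, 0.64),
    (36.36, 100.00, 94.33, 0.59),
    (22.73, 100.00, 93.12, 0.46),
    (18.18, 100.00, 92.71, 0.41),
    (11.36, 100.00, 92.11, 0.32),
]


class TestMetrics:
    @pytest.mark.parametrize("sens,spec,acc,mcc", TABLE_ROWS)
    def test_reproduces_published_rows_from_backsolved_counts(
        self, sens, spec, acc, mcc
    ):
        tp = round(sens / 100 * 44)
        tn = round(spec / 100 * 450)
        rep = metrics(ConfusionCounts(tp, tn, 450 - tn, 44 - tp)).rounded()
        assert rep["sensitivity"] == pytest.approx(sens)
        assert rep["specificity"] == pytest.approx(spec)
        assert rep["accuracy"] == pytest.approx(acc)
        assert rep["mcc"] == pytest.approx(mcc)

    def test_perfect_prediction(self):
        rep = metrics(ConfusionCounts(10, 10, 0, 0))
        assert rep.mcc == 1.0 and rep.accuracy == 100.0

    def test_undefined_metrics_are_none_not_zero(self):
        rep = metrics(ConfusionCounts(0, 5, 0, 0))  # no positives evaluated
        assert rep.sensitivity is None
        assert rep.specificity == 100.0
        assert rep.mcc == 0.0  # zero denominator convention

    def test_mcc_bounds(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            assert -1.0 <= metrics(ConfusionCounts(tp, tn, fp, fn)).mcc <= 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(InputError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestCrossValidate:
    def test_separable_data_gives_100(self, stage1_data):
        ds, ann, _ = stage1_data
        small = ds.subset([s.id for s in ds.sequences[::4]])
        split = make_folds(small, 5, 0)
        rep = cross_validate(
            small, split, lambda: SVMPipeline(build_pipeline("hybrid2", 1), ann)
        )
        assert rep.accuracy >= 90.0
        assert rep.pooled.counts.total == len(small.records)

    def test_label_shuffled_data_is_chance_level(self, null_data):
        ds, ann, _ = null_data
        split = make_folds(ds, 5, 3)
        rep = cross_validate(
            ds, split, lambda: SVMPipeline(build_pipeline("hybrid2", 1), ann)
        )
        assert abs(rep.mcc) <= 0.15

    def test_deterministic(self, null_data):
        ds, ann, _ = null_data
        split = make_folds(ds, 5, 4)
        factory = lambda: SVMPipeline(build_pipeline("aac", 1), ann)
        r1 = cross_validate(ds, split, factory)
        r2 = cross_validate(ds, split, factory)
        assert r1.mcc == r2.mcc and r1.accuracy == r2.accuracy


class TestThresholdSweep:
    def _scores_labels(self, rng):
        y = np.array([1] * 50 + [0] * 50)
        scores = np.where(y == 1, rng.normal(0.5, 0.5, 100), rng.normal(-0.5, 0.5, 100))
        return scores, y

    def test_default_grid_has_21_rows_ascending(self, rng):
        scores, y = self._scores_labels(rng)
        rep = sweep_scores(scores, y, DEFAULT_THRESHOLDS)
        assert len(rep.threshold_rows) == 21
        ts = [t for t, _ in rep.threshold_rows]
        assert ts == sorted(ts)

    def test_sensitivity_monotone_down_specificity_up(self, rng):
        scores, y = self._scores_labels(rng)
        rep = sweep_scores(scores, y, DEFAULT_THRESHOLDS)
        sens = [r.sensitivity for _, r in rep.threshold_rows]
        spec = [r.specificity for _, r in rep.threshold_rows]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_threshold_below_minimum_gives_full_sensitivity(self, rng):
        scores, y = self._scores_labels(rng)
        rep = sweep_scores(scores, y, [scores.min() - 1.0])
        assert rep.threshold_rows[0][1].sensitivity == 100.0

    def test_empty_threshold_list_rejected(self, rng):
        scores, y = self._scores_labels(rng)
        with pytest.raises(InputError):
            sweep_scores(scores, y, [])

    def test_tsv_table_layout(self, rng):
        scores, y = self._scores_labels(rng)
        text = report_to_tsv(sweep_scores(scores, y, DEFAULT_THRESHOLDS))
        lines = text.strip().split("\n")
        assert lines[0] == "Threshold\tSensitivity\tSpecificity\tAccuracy\tMCC"
        assert len(lines) == 22


class TestRoc:
    def test_perfect_separation_area_one(self):
        _, area = roc([1.0, 2.0, 3.0, -1.0, -2.0], [1, 1, 1, 0, 0])
        assert area == pytest.approx(1.0)

    def test_random_scores_area_half(self, rng):
        y = rng.integers(0, 2, 2000)
        scores = rng.normal(size=2000)
        _, area = roc(scores, y)
        assert area == pytest.approx(0.5, abs=0.05)

    def test_label_reversal_mirrors_area(self, rng):
        y = rng.integers(0, 2, 300)
        scores = rng.normal(size=300) + y
        _, a = roc(scores, y)
        _, a_rev = roc(scores, 1 - y)
        assert a_rev == pytest.approx(1.0 - a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc([1.0, 2.0], [1, 1])

    def test_curve_endpoints_and_tie_grouping(self):
        points, _ = roc([0.5, 0.5, 0.1], [1, 0, 0])
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        assert (0.5, 1.0) in points  # tied pair enters as one step

    def test_area_equals_normalized_mannwhitney(self, rng):
        # pairwise-comparison oracle on a small sample with ties
        y = rng.integers(0, 2, 150)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, 150)
        scores = np.round(rng.normal(size=150) + 0.8 * y, 1)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        u_area = wins / (len(pos) * len(neg))
        _, area = roc(scores, y)
        assert area == pytest.approx(u_area, abs=1e-12)
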