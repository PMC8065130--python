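"""1-s confusion scoring, metric arithmetic, CIs and experiment grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nonwear.evaluation import (
    ConfusionCounts,
    aggregate_participants,
    cnn_model_grid,
    compare_algorithms,
    compute_metrics,
    confusion_1s,
    hyperparameter_combinations,
    hyperparameter_grid,
)
from nonwear.signal_io import Interval, LabeledInterval


def truth(*spans):
    out = []
    for a, b, label in spans:
        out.append(LabeledInterval(Interval(a, b), label))
    return out


class TestConfusion1s:
    def test_perfect_prediction(self):
        t = truth((0, 40, "wear"), (40, 70, "nonwear"), (70, 100, "wear"))
        c = confusion_1s([Interval(40, 70)], t, 100)
        assert (c.tp, c.fp, c.fn, c.tn) == (30, 0, 0, 70)

    def test_all_positive_on_all_wear(self):
        c = confusion_1s([Interval(0, 100)], truth((0, 100, "wear")), 100)
        assert c.fp == 100 and c.tp == c.fn == 0

    def test_matches_naive_per_second_loop(self, rng):
        for _ in range(10):
            dur = 200
            pred = []
            t = 0
            while t < dur - 10:
                a = t + int(rng.integers(0, 10))
                b = a + int(rng.integers(1, 30))
                if b > dur:
                    break
                pred.append(Interval(a, b))
                t = b + int(rng.integers(1, 10))
            cut = int(rng.integers(50, 150))
            tr = truth((0, cut, "wear"), (cut, dur, "nonwear"))
            c = confusion_1s(pred, tr, dur)
            tp = fp = fn = tn = 0
            for s in range(dur):
                p = any(iv.start_s <= s and s + 1 <= iv.stop_s for iv in pred)
                g = cut <= s
                tp += p and g
                fp += p and not g
                fn += (not p) and g
                tn += (not p) and (not g)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_swapping_pred_and_truth_swaps_fp_fn(self):
        t = truth((0, 60, "wear"), (60, 100, "nonwear"))
        pred = [Interval(50, 80)]
        c = confusion_1s(pred, t, 100)
        swapped = confusion_1s(
            [Interval(60, 100)], truth((0, 50, "wear"), (50, 80, "nonwear"), (80, 100, "wear")), 100
        )
        assert (c.tp, c.tn) == (swapped.tp, swapped.tn)
        assert (c.fp, c.fn) == (swapped.fn, swapped.fp)


class TestComputeMetrics:
    def test_printed_formulas(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=0, tn=6))
        assert m.accuracy == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(2 * 0.75 / 1.75)

    def test_no_positives_anywhere_convention(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=100))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
        assert m.accuracy == 1.0

    def test_one_sided_degeneracy(self):
        # truth has positives, prediction stays silent
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=10, tn=90))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        # prediction fires, truth has no positives
        m = compute_metrics(ConfusionCounts(tp=0, fp=10, fn=0, tn=90))
        assert m.recall == 0.0 and m.precision == 0.0 and m.f1 == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50),
            st.integers(0, 50), st.integers(0, 50),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_f1_bounded_by_precision_and_recall(self, counts):
        m = compute_metrics(ConfusionCounts(*counts))
        lo, hi = sorted((m.precision, m.recall))
        assert lo - 1e-12 <= m.f1 <= hi + 1e-12
        tp, _, fn, _ = counts
        if tp == 0 and fn > 0:
            assert m.f1 == 0.0


class TestAggregate:
    def _summary(self, value):
        return compute_metrics(
            ConfusionCounts(tp=int(value * 100), fp=0, fn=100 - int(value * 100), tn=100)
        )

    def test_identical_values_zero_halfwidth(self):
        agg = aggregate_participants([self._summary(0.9)] * 4)
        assert agg.ci_halfwidth["recall"] == 0.0
        assert agg.n_participants == 4

    def test_two_participant_closed_form(self):
        agg = aggregate_participants([self._summary(0.9), self._summary(1.0)])
        assert agg.recall == pytest.approx(0.95)
        expected = 1.96 * np.std([0.9, 1.0], ddof=1) / np.sqrt(2)
        assert agg.ci_halfwidth["recall"] == pytest.approx(expected, abs=1e-6)
        assert agg.ci_halfwidth["recall"] == pytest.approx(0.098, abs=1e-3)

    def test_single_participant(self):
        agg = aggregate_participants([self._summary(0.8)])
        assert agg.recall == pytest.approx(0.8)
        assert agg.ci_halfwidth["recall"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_participants([])


class TestGrids:
    def test_twenty_hyperparameter_combinations(self):
        combos = hyperparameter_combinations()
        assert len(combos) == 20
        assert len(set(combos)) == 20

    def test_thirtysix_cnn_configurations(self):
        grid = cnn_model_grid()
        assert len(grid) == 36
        assert {w for w, _ in grid} == set(range(2, 11))
        assert {a for _, a in grid} == {"V1", "V2", "V3", "V4"}

    @pytest.fixture()
    def tiny_cohort(self):
        from tests.test_pipeline import EnergyStub, add_jerk

        rng = np.random.default_rng(77)
        cohort = []
        for p in range(2):
            n = 18000  # 30 min at 10 Hz
            samples = rng.normal(0, 0.05, size=(n, 3))
            samples[:, 2] += 1.0
            a, b = 600, 900
            samples[a * 10 : b * 10] = rng.normal(0, 0.002, size=(3000, 3))
            samples[a * 10 : b * 10, 1] += 1.0
            add_jerk(samples, 10.0, a - 2, a)
            add_jerk(samples, 10.0, b, b + 2)
            from tests.conftest import make_recording

            rec = make_recording(samples, 10.0, participant_id=f"p{p}")
            tr = truth((0, a, "wear"), (a, b, "nonwear"), (b, 1800, "wear"))
            cohort.append((rec, tr))
        return cohort, EnergyStub()

    def test_grid_rows_sorted_and_reproducible(self, tiny_cohort):
        cohort, model = tiny_cohort
        table = hyperparameter_grid(cohort, model)
        assert len(table) == 20
        assert list(table["f1"]) == sorted(table["f1"], reverse=True)

    def test_grid_row_matches_independent_run(self, tiny_cohort):
        from nonwear.pipeline import PipelineConfig, infer_nonwear

        cohort, model = tiny_cohort
        table = hyperparameter_grid(cohort, model)
        row = table[
            (table.merge_min == 3)
            & (table.operator == "AND")
            & (table.edge_default == "nonwear")
        ].iloc[0]
        cfg = PipelineConfig(merge_min=3, operator="AND", edge_default="nonwear")
        summaries = []
        for rec, tr in cohort:
            pred = infer_nonwear(rec, model, cfg)
            summaries.append(
                compute_metrics(confusion_1s(pred, tr, int(rec.duration_s)))
            )
        agg = aggregate_participants(summaries)
        assert row["f1"] == pytest.approx(agg.f1)
        assert row["precision"] == pytest.approx(agg.precision)

    def test_grid_split_mode_scores_both_halves(self, tiny_cohort):
        cohort, model = tiny_cohort
        table = hyperparameter_grid(cohort, model, split_seed=1)
        assert len(table) == 40
        assert set(table["split"]) == {"train", "test"}

    def test_compare_algorithms_one_row_each(self, tiny_cohort):
        from nonwear.baselines import xyz_nonwear
        from nonwear.pipeline import infer_nonwear

        cohort, model = tiny_cohort
        table = compare_algorithms(
            cohort,
            {
                "XYZ_90": lambda rec: xyz_nonwear(rec, 0.004, 90),
                "CNN": lambda rec: infer_nonwear(rec, model),
            },
        )
        assert list(table["algorithm"]) == ["XYZ_90", "CNN"]
        # the 5-min episode cohort is invisible to a 90-min interval detector
        assert table.iloc[0]["recall"] == 0.0
        assert table.iloc[1]["recall"] == 1.0
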