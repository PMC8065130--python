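"""1-s-resolution scoring of inferred non-wear time against ground truth.

Predicted and true non-wear intervals are rasterized to per-second labels
over the scored duration; seconds are accumulated into TP/FP/FN/TN counts
and summarised as accuracy, precision, recall and F1 (harmonic mean of
precision and recall).  Cohort-level numbers are means over participants
with a 95% normal-approximation confidence interval.

Also hosts the experiment grids: the 20-combination hyperparameter grid
over (merge minutes x logical operator x edge default) and the
36-configuration CNN training grid (9 window sizes x 4 architectures).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signal_io import Interval, LabeledInterval, NONWEAR, intervals_to_seconds

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-second confusion counts; TP+FP+FN+TN equals the scored duration."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSummary:
    accuracy: float
    precision: float
    recall: float
    f1: float
    ci_halfwidth: dict = field(default_factory=dict)
    n_participants: int = 1


def confusion_1s(
    pred: Sequence[Interval],
    truth: Sequence[LabeledInterval],
    duration_s: int,
) -> ConfusionCounts:
    """Compare predicted non-wear intervals with labelled truth per second.

    ``truth`` intervals labelled non-wear define the positive class; all other
    seconds are wear.  Scored duration is ``duration_s`` whole seconds.
    """
    pred_vec = intervals_to_seconds(list(pred), duration_s)
    truth_vec = intervals_to_seconds(
        [li.interval for li in truth if li.label == NONWEAR], duration_s
    )
    tp = int(np.sum((pred_vec == 1) & (truth_vec == 1)))
    fp = int(np.sum((pred_vec == 1) & (truth_vec == 0)))
    fn = int(np.sum((pred_vec == 0) & (truth_vec == 1)))
    tn = int(np.sum((pred_vec == 0) & (truth_vec == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(c: ConfusionCounts) -> MetricSummary:
    """Accuracy, precision, recall and F1 from confusion counts.

    Degenerate conventions: with no predicted and no true positives anywhere
    (TP+FP = 0 and TP+FN = 0) every positive-class metric is 1.0 — the
    classifier was right to stay silent.  If exactly one denominator is empty
    with TP = 0, the undefined metric is 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    no_pred_pos = (c.tp + c.fp) == 0
    no_true_pos = (c.tp + c.fn) == 0
    if no_pred_pos and no_true_pos:
        precision = recall = f1 = 1.0
    else:
        precision = 1.0 if no_pred_pos else c.tp / (c.tp + c.fp)
        recall = 1.0 if no_true_pos else c.tp / (c.tp + c.fn)
        if no_pred_pos or no_true_pos:
            # one side empty with TP = 0: the undefined metric is 0
            if no_pred_pos:
                precision = 0.0
            else:
                recall = 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
    return MetricSummary(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def aggregate_participants(per_participant: Sequence[MetricSummary]) -> MetricSummary:
    """Mean of each metric across participants with a 95% CI half-width.

    CI half-width is 1.96 * sample SD / sqrt(n); zero for a single participant.
    """
    if len(per_participant) == 0:
        raise ValueError("cannot aggregate an empty list of summaries")
    n = len(per_participant)
    means, halfwidths = {}, {}
    for m in METRICS:
        vals = np.array([getattr(s, m) for s in per_participant], dtype=float)
        means[m] = float(vals.mean())
        halfwidths[m] = (
            0.0 if n == 1 else float(1.96 * vals.std(ddof=1) / np.sqrt(n))
        )
    return MetricSummary(
        accuracy=means["accuracy"],
        precision=means["precision"],
        recall=means["recall"],
        f1=means["f1"],
        ci_halfwidth=halfwidths,
        n_participants=n,
    )


def hyperparameter_combinations(
    merge_values: Sequence[int] = (1, 2, 3, 4, 5),
    operators: Sequence[str] = ("AND", "OR"),
    edge_defaults: Sequence[str] = ("wear", "nonwear"),
) -> list[tuple[int, str, str]]:
    """The pipeline hyperparameter grid: 5 merge values x 2 operators x 2 defaults."""
    return list(itertools.product(merge_values, operators, edge_defaults))


def cnn_model_grid(
    window_sizes: Sequence[int] = tuple(range(2, 11)),
    architectures: Sequence[str] = ("V1", "V2", "V3", "V4"),
) -> list[tuple[int, str]]:
    """The CNN training grid: 9 window sizes (2-10 s) x 4 architectures."""
    return list(itertools.product(window_sizes, architectures))


def _score_cohort(
    cohort: Sequence[tuple],
    infer: Callable,
) -> MetricSummary:
    """Run an inference callable over (recording, truth) pairs and aggregate."""
    summaries = []
    for rec, truth in cohort:
        pred = infer(rec)
        counts = confusion_1s(pred, truth, int(rec.duration_s))
        summaries.append(compute_metrics(counts))
    return aggregate_participants(summaries)


def hyperparameter_grid(
    cohort: Sequence[tuple],
    model,
    merge_values: Sequence[int] = (1, 2, 3, 4, 5),
    operators: Sequence[str] = ("AND", "OR"),
    edge_defaults: Sequence[str] = ("wear", "nonwear"),
    base_config=None,
    split_seed: int | None = None,
) -> pd.DataFrame:
    """Score the full pipeline at every hyperparameter combination.

    ``cohort`` is a sequence of ``(AccelRecording, list[LabeledInterval])``
    pairs.  Returns one row per combination sorted by F1 descending.  When
    ``split_seed`` is given, participants are split 50/50 and each combination
    is scored on both halves (column ``split`` in {train, test}).
    """
    from .pipeline import PipelineConfig, infer_nonwear

    base = base_config or PipelineConfig()
    if split_seed is not None:
        rng = np.random.default_rng(split_seed)
        order = rng.permutation(len(cohort))
        half = len(cohort) // 2
        groups = {
            "train": [cohort[i] for i in order[:half]],
            "test": [cohort[i] for i in order[half:]],
        }
    else:
        groups = {"all": list(cohort)}

    rows = []
    for merge_min, operator, edge_default in hyperparameter_combinations(
        merge_values, operators, edge_defaults
    ):
        cfg = base.with_overrides(
            merge_min=merge_min, operator=operator, edge_default=edge_default
        )
        for split_name, group in groups.items():
            summary = _score_cohort(
                group, lambda rec: infer_nonwear(rec, model, cfg)
            )
            row = {
                "merge_min": merge_min,
                "operator": operator,
                "edge_default": edge_default,
            }
            if split_seed is not None:
                row["split"] = split_name
            for m in METRICS:
                row[m] = getattr(summary, m)
                row[f"{m}_ci"] = summary.ci_halfwidth[m]
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("f1", ascending=False, ignore_index=True)


def compare_algorithms(
    cohort: Sequence[tuple],
    algorithms: dict[str, Callable],
) -> pd.DataFrame:
    """Score named non-wear detectors over one cohort, one row per algorithm.

    Each value of ``algorithms`` maps an :class:`AccelRecording` to a list of
    predicted non-wear :class:`Interval` objects.
    """
    rows = []
    for name, infer in algorithms.items():
        summary = _score_cohort(cohort, infer)
        row = {"algorithm": name}
        for m in METRICS:
            row[m] = getattr(summary, m)
            row[f"{m}_ci"] = summary.ci_halfwidth[m]
        rows.append(row)
    return pd.DataFrame(rows)
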