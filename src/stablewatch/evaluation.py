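"""Quality-control evaluation of predicted sequences against manual
annotation: accuracy, per-class f-score, deviations in phase statistics,
misclassified-run extraction and night validity filtering.

Metrics are computed between the *postprocessed* prediction and the
*equally postprocessed* annotation, so the reported error is the
methodological error of the classifier chain, not the (separately
reported) systematic error introduced by the postprocessing rules
themselves.  Nights in which the animal was Out at least 20% of the time
in either sequence are dismissed — they carry no evidence about the
activity budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (BehaviorLabel, LabelSequence, NightStats, Task,
                   phase_stats, vocabulary)
from .postprocess import PostprocessRuleSet, apply_ruleset

__all__ = [
    "accuracy",
    "f_score",
    "f_scores",
    "MisclassifiedRun",
    "extract_misclassified_runs",
    "EvaluationReport",
    "compare_night",
    "systematic_error",
    "filter_valid_nights",
    "OUT_DISMISSAL_THRESHOLD",
    "read_boris_csv",
    "rasterize_boris",
    "report_to_frame",
    "report_to_json",
]

OUT_DISMISSAL_THRESHOLD = 0.20  # ">= 20% Out" night dismissal rule


def _aligned_labels(pred: LabelSequence, truth: LabelSequence
                    ) -> tuple[tuple, tuple]:
    if Task(pred.task) is not Task(truth.task):
        raise ValueError("prediction and truth must share the task")
    if len(pred.labels) != len(truth.labels):
        raise ValueError(
            f"length mismatch: {len(pred.labels)} vs {len(truth.labels)}"
        )
    return pred.labels, truth.labels


def accuracy(pred: LabelSequence, truth: LabelSequence) -> float:
    """Proportion of intervals with matching labels."""
    s, t = _aligned_labels(pred, truth)
    if not s:
        raise ValueError("cannot compute accuracy of empty sequences")
    return sum(1 for a, b in zip(s, t) if a is b) / len(s)


def f_score(pred: LabelSequence, truth: LabelSequence,
            c: BehaviorLabel) -> float | None:
    """Per-class f-score tp / (tp + 0.5 (fp + fn)).

    ``None`` (not 0, not 1) when the class occurs in neither sequence:
    the score is undefined, and reporting it as a number would silently
    distort aggregated results.
    """
    s, t = _aligned_labels(pred, truth)
    c = BehaviorLabel(c)
    tp = sum(1 for a, b in zip(s, t) if a is c and b is c)
    fp = sum(1 for a, b in zip(s, t) if a is c and b is not c)
    fn = sum(1 for a, b in zip(s, t) if a is not c and b is c)
    if tp + fp + fn == 0:
        return None
    return tp / (tp + 0.5 * (fp + fn))


def f_scores(pred: LabelSequence, truth: LabelSequence
             ) -> dict[BehaviorLabel, float | None]:
    return {c: f_score(pred, truth, c) for c in vocabulary(pred.task)}


@dataclass(frozen=True)
class MisclassifiedRun:
    """Maximal run of a constant (truth, predicted) disagreement pair."""

    truth_label: BehaviorLabel
    pred_label: BehaviorLabel
    start: int
    end: int
    interval_seconds: int = 7

    @property
    def duration_s(self) -> int:
        return (self.end - self.start) * self.interval_seconds


def extract_misclassified_runs(pred: LabelSequence, truth: LabelSequence
                               ) -> list[MisclassifiedRun]:
    """Number, length and type of misclassified sequences.

    Runs are split wherever the (truth, pred) pair changes, so each run
    has a well-defined confusion type.
    """
    s, t = _aligned_labels(pred, truth)
    runs: list[MisclassifiedRun] = []
    start = None
    for i in range(len(s) + 1):
        pair = (t[i], s[i]) if i < len(s) and s[i] is not t[i] else None
        if start is not None and (pair is None or pair != current):
            runs.append(MisclassifiedRun(current[0], current[1], start, i,
                                         pred.interval_seconds))
            start = None
        if pair is not None and start is None:
            start, current = i, pair
    return runs


@dataclass
class EvaluationReport:
    night_id: str
    individual_id: str
    task: Task
    accuracy: float
    f_score: dict[BehaviorLabel, float | None]
    delta_phase_count: dict[BehaviorLabel, int]
    delta_median_phase_s: dict[BehaviorLabel, float | None]
    delta_percentage: dict[BehaviorLabel, float]
    misclassified_runs: list[MisclassifiedRun]
    pred_out_fraction: float
    truth_out_fraction: float
    pred_stats: NightStats | None = None
    truth_stats: NightStats | None = None


def _deltas(pred_stats: NightStats, truth_stats: NightStats, task: Task):
    """Signed (prediction - truth) deltas, exposing over/under-estimation."""
    vocab = vocabulary(task)
    d_count = {c: pred_stats.phase_count[c] - truth_stats.phase_count[c]
               for c in vocab}
    d_median = {}
    for c in vocab:
        a = pred_stats.median_phase_length_s[c]
        b = truth_stats.median_phase_length_s[c]
        d_median[c] = None if (np.isnan(a) or np.isnan(b)) else a - b
    d_pct = {c: pred_stats.percentage[c] - truth_stats.percentage[c]
             for c in vocab}
    return d_count, d_median, d_pct


def compare_night(pred: LabelSequence, truth: LabelSequence,
                  rules: PostprocessRuleSet) -> EvaluationReport:
    """Postprocess both sequences with the same rules, then compare.

    Applying the rules to the annotation as well makes the comparison
    symmetric: short real events that the rules would dismiss no longer
    count against the prediction.
    """
    if pred.night_id != truth.night_id or pred.individual_id != truth.individual_id:
        raise ValueError("prediction and truth must describe the same night")
    pp = apply_ruleset(pred, rules)
    tp = apply_ruleset(truth, rules)
    pred_stats = phase_stats(pp)
    truth_stats = phase_stats(tp)
    d_count, d_median, d_pct = _deltas(pred_stats, truth_stats, Task(pred.task))
    return EvaluationReport(
        night_id=pred.night_id,
        individual_id=pred.individual_id,
        task=Task(pred.task),
        accuracy=accuracy(pp, tp),
        f_score=f_scores(pp, tp),
        delta_phase_count=d_count,
        delta_median_phase_s=d_median,
        delta_percentage=d_pct,
        misclassified_runs=extract_misclassified_runs(pp, tp),
        pred_out_fraction=pp.out_fraction,
        truth_out_fraction=tp.out_fraction,
        pred_stats=pred_stats,
        truth_stats=truth_stats,
    )


def systematic_error(truth: LabelSequence,
                     rules: PostprocessRuleSet) -> EvaluationReport:
    """Postprocessed annotation vs raw annotation: the bias introduced by
    the rules themselves (short real events dismissed, phases lengthened)."""
    pp = apply_ruleset(truth, rules)
    pred_stats = phase_stats(pp)
    truth_stats = phase_stats(truth)
    d_count, d_median, d_pct = _deltas(pred_stats, truth_stats, Task(truth.task))
    return EvaluationReport(
        night_id=truth.night_id,
        individual_id=truth.individual_id,
        task=Task(truth.task),
        accuracy=accuracy(pp, truth),
        f_score=f_scores(pp, truth),
        delta_phase_count=d_count,
        delta_median_phase_s=d_median,
        delta_percentage=d_pct,
        misclassified_runs=extract_misclassified_runs(pp, truth),
        pred_out_fraction=pp.out_fraction,
        truth_out_fraction=truth.out_fraction,
        pred_stats=pred_stats,
        truth_stats=truth_stats,
    )


def filter_valid_nights(reports: Iterable[EvaluationReport],
                        threshold: float = OUT_DISMISSAL_THRESHOLD
                        ) -> list[EvaluationReport]:
    """Dismiss nights with Out fraction >= threshold ("at least 20%",
    inclusive) in either the predicted or the annotated sequence."""
    return [
        r for r in reports
        if r.pred_out_fraction < threshold and r.truth_out_fraction < threshold
    ]


# ---------------------------------------------------------------------------
# BORIS-style annotation ingestion


def read_boris_csv(path: str | Path) -> pd.DataFrame:
    """Read a BORIS-style tabular export (subject, behavior, start_s, stop_s)."""
    df = pd.read_csv(path)
    required = {"subject", "behavior", "start_s", "stop_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation export lacks columns {sorted(missing)}")
    return df


def rasterize_boris(df: pd.DataFrame, individual_id: str, night_id: str,
                    n_intervals: int, task: Task = Task.TOTAL,
                    interval_seconds: int = 7) -> LabelSequence:
    """Rasterize continuous annotated intervals onto the 7-s grid.

    Each grid interval takes the label of the annotation covering its
    midpoint; time not covered by any annotation is Out (the observer saw
    no animal to annotate).
    """
    sub = df[df["subject"] == individual_id]
    labels = []
    vocab = set(vocabulary(task))
    for i in range(n_intervals):
        mid = (i + 0.5) * interval_seconds
        hit = sub[(sub["start_s"] <= mid) & (mid < sub["stop_s"])]
        if len(hit):
            lab = BehaviorLabel(str(hit.iloc[0]["behavior"]).lower())
            if lab not in vocab:
                raise ValueError(f"behavior {lab.value!r} not in task vocabulary")
            labels.append(lab)
        else:
            labels.append(BehaviorLabel.OUT)
    return LabelSequence(night_id=night_id, individual_id=individual_id,
                         task=task, labels=tuple(labels),
                         interval_seconds=interval_seconds)


# ---------------------------------------------------------------------------
# Report serialization


def report_to_frame(reports: Iterable[EvaluationReport]) -> pd.DataFrame:
    """One row per night per class."""
    rows = []
    for r in reports:
        for c in vocabulary(r.task):
            rows.append({
                "night_id": r.night_id,
                "individual_id": r.individual_id,
                "task": r.task.value,
                "label": c.value,
                "accuracy": r.accuracy,
                "f_score": r.f_score[c],
                "delta_phase_count": r.delta_phase_count[c],
                "delta_median_phase_s": r.delta_median_phase_s[c],
                "delta_percentage": r.delta_percentage[c],
                "n_misclassified_runs": len(r.misclassified_runs),
            })
    return pd.DataFrame(rows)


def report_to_json(report: EvaluationReport) -> str:
    def enc(d: Mapping) -> dict:
        return {k.value: v for k, v in d.items()}

    return json.dumps({
        "night_id": report.night_id,
        "individual_id": report.individual_id,
        "task": report.task.value,
        "accuracy": report.accuracy,
        "f_score": enc(report.f_score),
        "delta_phase_count": enc(report.delta_phase_count),
        "delta_median_phase_s": enc(report.delta_median_phase_s),
        "delta_percentage": enc(report.delta_percentage),
        "pred_out_fraction": report.pred_out_fraction,
        "truth_out_fraction": report.truth_out_fraction,
        "misclassified_runs": [
            {"truth": m.truth_label.value, "pred": m.pred_label.value,
             "start": m.start, "duration_s": m.duration_s}
            for m in report.misclassified_runs
        ],
    }, indent=2)
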