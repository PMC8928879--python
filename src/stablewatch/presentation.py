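"""Presentation of predicted nights: per-night phase plot data, activity
budgets and the population timeline of behavioral states over the night.

Numbers are the tested surface; figure rendering is a thin optional layer
over the tabular plot data (matplotlib is imported lazily).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (BehaviorLabel, LabelSequence, NightStats, Task,
                   segment_phases, vocabulary)

__all__ = [
    "night_phase_plotdata",
    "plot_night",
    "activity_budget",
    "TimelineTable",
    "population_timeline",
    "summary_table",
]


def night_phase_plotdata(seq: LabelSequence) -> pd.DataFrame:
    """Ordered phase segments (label, start_s, end_s) tiling the night,
    ready to be drawn as a horizontal phase bar or written as CSV."""
    rows = [
        {
            "label": p.label.value,
            "start_s": p.start * seq.interval_seconds,
            "end_s": p.end * seq.interval_seconds,
        }
        for p in segment_phases(seq)
    ]
    return pd.DataFrame(rows, columns=["label", "start_s", "end_s"])


_LABEL_COLORS = {
    "standing": "#1f77b4",
    "lhu": "#2ca02c",
    "lhd": "#9467bd",
    "lying": "#2ca02c",
    "out": "#7f7f7f",
}


def plot_night(seq: LabelSequence, ax=None):
    """Horizontal phase bar of one night (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.5))
    for _, row in night_phase_plotdata(seq).iterrows():
        ax.barh(0, row["end_s"] - row["start_s"], left=row["start_s"],
                color=_LABEL_COLORS.get(row["label"], "k"), height=1.0)
    ax.set_yticks([])
    ax.set_xlabel("seconds since night start")
    ax.set_title(f"{seq.individual_id} — {seq.night_id} ({Task(seq.task).value})")
    return ax


def activity_budget(stats_by_individual: Mapping[str, Sequence[NightStats]]
                    ) -> pd.DataFrame:
    """Per-individual mean of per-night time percentages (unweighted over
    nights).  Nights with undefined percentages are skipped; an individual
    with no usable night is omitted with a warning."""
    rows = []
    for ind in sorted(stats_by_individual):
        nights = [s for s in stats_by_individual[ind] if not s.undefined]
        if not nights:
            warnings.warn(f"individual {ind!r} has no valid night; omitted")
            continue
        vocab = vocabulary(nights[0].task)
        row = {"individual_id": ind, "n_nights": len(nights)}
        for c in vocab:
            row[c.value] = float(np.mean([s.percentage[c] for s in nights]))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TimelineTable:
    """Population timeline: per clock timepoint, the mean fraction of
    (night, individual) pairs in each state among the non-missing ones."""

    table: pd.DataFrame  # index: seconds since earliest night start
    smooth_minutes: float
    window_intervals: int
    n_observations: pd.Series  # non-missing sequences per timepoint


def _start_offset_s(night_start: time, reference: time) -> int:
    ref = datetime(2000, 1, 1, reference.hour, reference.minute, reference.second)
    t = datetime(2000, 1, 1, night_start.hour, night_start.minute,
                 night_start.second)
    if t < ref:  # start after midnight relative to the reference
        t += timedelta(days=1)
    return int((t - ref).total_seconds())


def population_timeline(seqs: Sequence[LabelSequence],
                        smooth_minutes: float = 3.0) -> TimelineTable:
    """Mean behavioral-state fractions over all nights on a common clock,
    smoothed by a centered rolling average (3 min -> 25 intervals at 7 s).

    Nights are aligned by clock time of night start; timepoints a shorter
    night does not cover are excluded from its denominators rather than
    zero-filled.  The rolling mean is linear, so the per-timepoint
    fractions keep summing to one.
    """
    if not seqs:
        raise ValueError("population_timeline needs at least one sequence")
    task = Task(seqs[0].task)
    step = seqs[0].interval_seconds
    if any(Task(s.task) is not task or s.interval_seconds != step for s in seqs):
        raise ValueError("sequences must share task and interval length")
    vocab = vocabulary(task)
    reference = min((s.night_start for s in seqs),
                    key=lambda t: (t.hour, t.minute, t.second))
    offsets = [_start_offset_s(s.night_start, reference) // step for s in seqs]
    n_points = max(off + len(s) for off, s in zip(offsets, seqs))

    counts = np.zeros((n_points, len(vocab)))
    present = np.zeros(n_points)
    index = {l: i for i, l in enumerate(vocab)}
    for off, s in zip(offsets, seqs):
        for i, lab in enumerate(s.labels):
            counts[off + i, index[lab]] += 1
            present[off + i] += 1
    with np.errstate(invalid="ignore"):
        frac = counts / present[:, None]

    # nearest odd window (3 min at 7 s: 25.7 -> 25 intervals)
    window = max(1, 2 * int(round((smooth_minutes * 60 / step - 1) / 2)) + 1)
    times = np.arange(n_points) * step
    df = pd.DataFrame(frac, index=pd.Index(times, name="seconds"),
                      columns=[l.value for l in vocab])
    smoothed = df.rolling(window, center=True, min_periods=1).mean()
    return TimelineTable(
        table=smoothed,
        smooth_minutes=smooth_minutes,
        window_intervals=window,
        n_observations=pd.Series(present, index=df.index, name="n"),
    )


def summary_table(stats: Iterable[NightStats]) -> pd.DataFrame:
    """Per-individual summary: nights, mean percentages, median of nightly
    phase counts and of nightly median phase lengths, per label."""
    by_ind: dict[tuple[str, Task], list[NightStats]] = {}
    for s in stats:
        by_ind.setdefault((s.individual_id, Task(s.task)), []).append(s)
    rows = []
    for (ind, task), nights in sorted(by_ind.items(), key=lambda kv: kv[0][0]):
        usable = [s for s in nights if not s.undefined]
        for c in vocabulary(task):
            counts = [s.phase_count[c] for s in nights]
            medians = [s.median_phase_length_s[c] for s in nights
                       if not np.isnan(s.median_phase_length_s[c])]
            rows.append({
                "individual_id": ind,
                "task": task.value,
                "label": c.value,
                "n_nights": len(nights),
                "mean_percentage": (
                    float(np.mean([s.percentage[c] for s in usable]))
                    if usable else np.nan
                ),
                "median_nightly_phase_count": float(np.median(counts)),
                "median_nightly_median_phase_s": (
                    float(np.median(medians)) if medians else np.nan
                ),
            })
    return pd.DataFrame(rows)
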