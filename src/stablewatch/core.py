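"""Core domain model: behavior labels, nightly label sequences, phases and
per-night descriptive statistics.

The atomic time unit is the 7-second interval into which a 1-fps night is
discretized; every sequence is a vector of ethogram labels on that grid.
Two classification tasks exist: the *total* task distinguishes Standing,
Lying-head-up (LHU), Lying-head-down (LHD) and Out (animal not visible),
while the *binary* task collapses LHU and LHD into Lying.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Task",
    "BehaviorLabel",
    "vocabulary",
    "LabelSequence",
    "Phase",
    "NightStats",
    "map_total_to_binary",
    "segment_phases",
    "expand_phases",
    "phase_stats",
    "sequences_to_frame",
    "frame_to_sequences",
    "write_sequences_csv",
    "read_sequences_csv",
    "stats_to_frame",
]


class Task(str, enum.Enum):
    """Classification task: 3 behavior classes + Out, or 2 + Out."""

    TOTAL = "total"
    BINARY = "binary"


class BehaviorLabel(str, enum.Enum):
    STANDING = "standing"
    LHU = "lhu"  # lying, head up
    LHD = "lhd"  # lying, head down (REM-sleep posture proxy)
    LYING = "lying"  # binary task only: LHU union LHD
    OUT = "out"  # animal not (sufficiently) visible

    def __str__(self) -> str:  # stable CSV serialization
        return self.value


# Vocabulary order doubles as the deterministic tie-break order for argmax.
_TOTAL_VOCAB = (
    BehaviorLabel.STANDING,
    BehaviorLabel.LHU,
    BehaviorLabel.LHD,
    BehaviorLabel.OUT,
)
_BINARY_VOCAB = (BehaviorLabel.STANDING, BehaviorLabel.LYING, BehaviorLabel.OUT)


def vocabulary(task: Task) -> tuple[BehaviorLabel, ...]:
    """The ordered label vocabulary of a task (order = tie-break order)."""
    return _TOTAL_VOCAB if Task(task) is Task.TOTAL else _BINARY_VOCAB


@dataclass
class LabelSequence:
    """Per-night, per-individual label sequence on the 7-s interval grid."""

    night_id: str
    individual_id: str
    task: Task
    labels: tuple[BehaviorLabel, ...]
    interval_seconds: int = 7
    night_start: time = time(17, 0)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.labels = tuple(BehaviorLabel(l) for l in self.labels)
        if self.interval_seconds <= 0:
            raise ValueError("interval_seconds must be positive")
        vocab = set(vocabulary(self.task))
        bad = {l for l in self.labels} - vocab
        if bad:
            raise ValueError(
                f"labels {sorted(b.value for b in bad)} not in the "
                f"{self.task.value}-task vocabulary"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> int:
        return len(self.labels) * self.interval_seconds

    @property
    def out_fraction(self) -> float:
        """Fraction of intervals labeled Out (0.0 for an empty night)."""
        if not self.labels:
            return 0.0
        n_out = sum(1 for l in self.labels if l is BehaviorLabel.OUT)
        return n_out / len(self.labels)

    def with_labels(self, labels: Iterable[BehaviorLabel]) -> "LabelSequence":
        return replace(self, labels=tuple(labels))


@dataclass(frozen=True)
class Phase:
    """Maximal run of one label; indices are 0-based, half-open [start, end)."""

    label: BehaviorLabel
    start: int
    end: int
    interval_seconds: int = 7

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("phase must span at least one interval")

    @property
    def n_intervals(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> int:
        return (self.end - self.start) * self.interval_seconds


@dataclass
class NightStats:
    """Per-night descriptive statistics: phase counts, median phase lengths
    and time percentages per label.

    ``percentage`` is normalized over all intervals, or over non-Out
    intervals when ``exclude_out`` is set.  A night that is entirely Out
    with ``exclude_out`` has no defined percentages; ``undefined`` is set
    instead of silently reporting zeros.
    """

    night_id: str
    individual_id: str
    task: Task
    exclude_out: bool
    phase_count: dict[BehaviorLabel, int]
    median_phase_length_s: dict[BehaviorLabel, float]
    percentage: dict[BehaviorLabel, float]
    out_fraction: float
    undefined: bool = False


def map_total_to_binary(seq: LabelSequence) -> LabelSequence:
    """Collapse a total-task sequence to the binary task (Lying = LHU u LHD)."""
    if Task(seq.task) is not Task.TOTAL:
        raise ValueError("map_total_to_binary requires a total-task sequence")
    mapping = {
        BehaviorLabel.STANDING: BehaviorLabel.STANDING,
        BehaviorLabel.LHU: BehaviorLabel.LYING,
        BehaviorLabel.LHD: BehaviorLabel.LYING,
        BehaviorLabel.OUT: BehaviorLabel.OUT,
    }
    return LabelSequence(
        night_id=seq.night_id,
        individual_id=seq.individual_id,
        task=Task.BINARY,
        labels=tuple(mapping[l] for l in seq.labels),
        interval_seconds=seq.interval_seconds,
        night_start=seq.night_start,
    )


def segment_phases(seq: LabelSequence | Sequence[BehaviorLabel],
                   interval_seconds: int | None = None) -> list[Phase]:
    """Run-length encode a sequence into maximal single-label phases.

    The returned phases tile the sequence exactly: concatenating them in
    order reconstructs the input.
    """
    if isinstance(seq, LabelSequence):
        labels = seq.labels
        step = seq.interval_seconds
    else:
        labels = tuple(seq)
        step = interval_seconds if interval_seconds is not None else 7
    phases: list[Phase] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            phases.append(Phase(labels[start], start, i, step))
            start = i
    return phases


def expand_phases(phases: Sequence[Phase]) -> tuple[BehaviorLabel, ...]:
    """Inverse of :func:`segment_phases` (used by round-trip checks)."""
    labels: list[BehaviorLabel] = []
    for p in phases:
        labels.extend([p.label] * p.n_intervals)
    return tuple(labels)


def phase_stats(seq: LabelSequence, exclude_out: bool = False) -> NightStats:
    """Phase counts, median phase lengths and time percentages for a night."""
    phases = segment_phases(seq)
    vocab = vocabulary(seq.task)
    counts: dict[BehaviorLabel, int] = {l: 0 for l in vocab}
    lengths: dict[BehaviorLabel, list[int]] = {l: [] for l in vocab}
    interval_count: dict[BehaviorLabel, int] = {l: 0 for l in vocab}
    for p in phases:
        counts[p.label] += 1
        lengths[p.label].append(p.duration_s)
        interval_count[p.label] += p.n_intervals

    medians = {
        l: (statistics.median(v) if v else float("nan")) for l, v in lengths.items()
    }
    if exclude_out:
        denom = sum(n for l, n in interval_count.items() if l is not BehaviorLabel.OUT)
    else:
        denom = len(seq.labels)
    undefined = denom == 0
    if undefined:
        percentage = {l: float("nan") for l in vocab}
    else:
        percentage = {
            l: (0.0 if (exclude_out and l is BehaviorLabel.OUT)
                else interval_count[l] / denom)
            for l in vocab
        }
    return NightStats(
        night_id=seq.night_id,
        individual_id=seq.individual_id,
        task=seq.task,
        exclude_out=exclude_out,
        phase_count=counts,
        median_phase_length_s=medians,
        percentage=percentage,
        out_fraction=seq.out_fraction,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# CSV interchange: one row per interval / one row per (night, label)


def sequences_to_frame(seqs: Iterable[LabelSequence]) -> pd.DataFrame:
    rows = []
    for s in seqs:
        for i, l in enumerate(s.labels):
            rows.append(
                {
                    "night_id": s.night_id,
                    "individual_id": s.individual_id,
                    "task": s.task.value,
                    "interval_index": i,
                    "label": l.value,
                }
            )
    return pd.DataFrame(
        rows, columns=["night_id", "individual_id", "task", "interval_index", "label"]
    )


def frame_to_sequences(df: pd.DataFrame, interval_seconds: int = 7,
                       night_start: time = time(17, 0)) -> list[LabelSequence]:
    seqs = []
    for (night, ind, task), grp in df.groupby(
        ["night_id", "individual_id", "task"], sort=True
    ):
        grp = grp.sort_values("interval_index")
        idx = grp["interval_index"].to_numpy()
        if len(idx) and (idx[0] != 0 or (idx[1:] != idx[:-1] + 1).any()):
            raise ValueError(f"non-contiguous interval indices for night {night!r}")
        seqs.append(
            LabelSequence(
                night_id=str(night),
                individual_id=str(ind),
                task=Task(task),
                labels=tuple(BehaviorLabel(v) for v in grp["label"]),
                interval_seconds=interval_seconds,
                night_start=night_start,
            )
        )
    return seqs


def write_sequences_csv(path: str | Path, seqs: Iterable[LabelSequence]) -> None:
    sequences_to_frame(seqs).to_csv(path, index=False)


def read_sequences_csv(path: str | Path, **kwargs) -> list[LabelSequence]:
    return frame_to_sequences(pd.read_csv(path), **kwargs)


def stats_to_frame(stats: Iterable[NightStats]) -> pd.DataFrame:
    """One row per (individual, night, label)."""
    rows = []
    for st in stats:
        for label in vocabulary(st.task):
            rows.append(
                {
                    "night_id": st.night_id,
                    "individual_id": st.individual_id,
                    "task": st.task.value,
                    "label": label.value,
                    "phase_count": st.phase_count[label],
                    "median_phase_length_s": st.median_phase_length_s[label],
                    "percentage": st.percentage[label],
                    "out_fraction": st.out_fraction,
                    "exclude_out": st.exclude_out,
                    "undefined": st.undefined,
                }
            )
    return pd.DataFrame(rows)
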