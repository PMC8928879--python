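"""Flicker-suppressing postprocessing of predicted label sequences.

Video action classifiers flicker: very short runs of a wrong label barely
move accuracy or f-score but wreck phase counts and phase-length
statistics.  Three rules repair this, applied in a fixed order:

1. *Out-flicker merge* — a short Out run flanked on both sides by the same
   behavior is relabeled to that behavior (the detector briefly lost the
   animal, it did not actually leave).
2. *Rolling smooth* — each interval is relabeled to the modal label of a
   centered odd window; ties keep the original label.
3. *Short-phase dismissal* — iteratively, the shortest phase no longer
   than its label's minimum duration is absorbed into its longer
   neighbor, until no dismissible phase remains.

Thresholds are task- and age-dependent configuration (binary rhythms are
studied at a 5-minute granularity; nonadult animals show shorter phases
than adults, so their dismissal thresholds are smaller).  ``apply_ruleset``
iterates the three-rule pass to a fixed point so that re-applying the
rules never changes an already-postprocessed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import BehaviorLabel, LabelSequence, Task, vocabulary

__all__ = [
    "PostprocessRuleSet",
    "merge_out_flicker",
    "rolling_smooth",
    "dismiss_short_phases",
    "apply_ruleset",
    "load_ruleset_yaml",
]


@dataclass
class PostprocessRuleSet:
    """Smoothing window, Out-merge threshold and per-label minimum phase
    durations for one task and age class.

    Shipped defaults: binary task 300 s (inclusive, "up to 5 min") for
    Standing and Lying; total task 60 s (adult) / 30 s (nonadult) per
    behavior; Out-merge up to 56 s (8 intervals); rolling window 5
    intervals.  All values are configuration, overridable via YAML.
    """

    task: Task
    age_class: str = "adult"
    rolling_window: int = 5
    out_merge_max_s: float = 56.0
    min_phase_s: dict[BehaviorLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.age_class not in ("adult", "nonadult"):
            raise ValueError("age_class must be 'adult' or 'nonadult'")
        if self.rolling_window < 1 or self.rolling_window % 2 == 0:
            raise ValueError("rolling_window must be an odd integer >= 1")
        if self.out_merge_max_s < 0:
            raise ValueError("out_merge_max_s must be >= 0")
        self.min_phase_s = {BehaviorLabel(k): float(v)
                            for k, v in self.min_phase_s.items()}
        if any(v < 0 for v in self.min_phase_s.values()):
            raise ValueError("min_phase_s thresholds must be >= 0")
        if not self.min_phase_s:
            self.min_phase_s = self._default_thresholds()

    def _default_thresholds(self) -> dict[BehaviorLabel, float]:
        if self.task is Task.BINARY:
            base = {BehaviorLabel.STANDING: 300.0, BehaviorLabel.LYING: 300.0}
        else:
            t = 60.0 if self.age_class == "adult" else 30.0
            base = {BehaviorLabel.STANDING: t, BehaviorLabel.LHU: t,
                    BehaviorLabel.LHD: t}
        # Out dismissal aligned with the Out-merge threshold: an Out run
        # short enough to be merge-repaired between equal flanks is also
        # short enough to dismiss when it straddles a transition, where
        # merging cannot reach it.  Genuine Out bouts are minutes long.
        base[BehaviorLabel.OUT] = self.out_merge_max_s
        return base

    @classmethod
    def default(cls, task: Task, age_class: str = "adult") -> "PostprocessRuleSet":
        return cls(task=task, age_class=age_class)


# ---------------------------------------------------------------------------
# The rules operate internally on run-length encodings for speed.


def _runs(labels: Sequence[BehaviorLabel]) -> list[list]:
    runs: list[list] = []
    for l in labels:
        if runs and runs[-1][0] is l:
            runs[-1][1] += 1
        else:
            runs.append([l, 1])
    return runs


def _expand(runs: Sequence[Sequence]) -> list[BehaviorLabel]:
    out: list[BehaviorLabel] = []
    for label, n in runs:
        out.extend([label] * n)
    return out


def merge_out_flicker(seq: LabelSequence,
                      out_merge_max_s: float | None = None) -> LabelSequence:
    """Relabel short Out runs flanked on both sides by the same behavior.

    Runs at the sequence ends or between differing behaviors are kept: the
    animal may genuinely have been out of view there.
    """
    if out_merge_max_s is None:
        out_merge_max_s = 56.0
    runs = _runs(seq.labels)
    step = seq.interval_seconds
    for i in range(1, len(runs) - 1):
        label, n = runs[i]
        if (
            label is BehaviorLabel.OUT
            and n * step <= out_merge_max_s
            and runs[i - 1][0] is runs[i + 1][0]
            and runs[i - 1][0] is not BehaviorLabel.OUT
        ):
            runs[i][0] = runs[i - 1][0]
    return seq.with_labels(_expand(runs))


def rolling_smooth(seq: LabelSequence, window: int = 5) -> LabelSequence:
    """Relabel each interval to the modal label of the centered window.

    The window is truncated at the sequence boundaries; a tie in the modal
    count keeps the original label.  Sequences no longer than the half
    window are effectively relabeled to their overall majority.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(seq.labels)
    if n == 0 or window == 1:
        return seq.with_labels(seq.labels)
    vocab = vocabulary(seq.task)
    index = {l: i for i, l in enumerate(vocab)}
    codes = np.fromiter((index[l] for l in seq.labels), dtype=np.intp, count=n)
    onehot = np.zeros((n, len(vocab)), dtype=np.int32)
    onehot[np.arange(n), codes] = 1
    csum = np.vstack([np.zeros((1, len(vocab)), dtype=np.int32),
                      np.cumsum(onehot, axis=0)])
    half = window // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    counts = csum[hi] - csum[lo]  # (n, k) label counts per truncated window
    best = counts.argmax(axis=1)
    maxc = counts.max(axis=1)
    tie = (counts == maxc[:, None]).sum(axis=1) > 1
    new_codes = np.where(tie, codes, best)
    return seq.with_labels(vocab[c] for c in new_codes)


def _dismiss_runs(runs: list[list], thresholds: Mapping[BehaviorLabel, float],
                  step: int) -> list[list]:
    """Fixpoint absorption of dismissible runs (shortest first, earliest on
    ties) into the longer neighbor (preceding neighbor on ties)."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        best = None
        for i, (label, n) in enumerate(runs):
            thr = thresholds.get(label, 0.0)
            if n * step <= thr and (best is None or n < runs[best][1]):
                best = i
        if best is None:
            break
        prev_i = best - 1 if best > 0 else None
        next_i = best + 1 if best < len(runs) - 1 else None
        if prev_i is None:
            target = next_i
        elif next_i is None:
            target = prev_i
        elif runs[next_i][1] > runs[prev_i][1]:
            target = next_i
        else:
            target = prev_i  # longer neighbor wins; tie -> preceding
        runs[best][0] = runs[target][0]
        # coalesce with equal-label neighbors
        merged = []
        for label, n in runs:
            if merged and merged[-1][0] is label:
                merged[-1][1] += n
            else:
                merged.append([label, n])
        runs = merged
    return runs


def dismiss_short_phases(seq: LabelSequence,
                         min_phase_s: Mapping[BehaviorLabel, float]) -> LabelSequence:
    """Iteratively absorb phases of duration <= their label's threshold
    (inclusive: "up to 5 min" dismisses a 5-min phase) into the longer
    neighbor.  A phase spanning the whole sequence has no neighbor and is
    kept regardless of its length.
    """
    thresholds = {BehaviorLabel(k): float(v) for k, v in min_phase_s.items()}
    runs = _dismiss_runs(_runs(seq.labels), thresholds, seq.interval_seconds)
    return seq.with_labels(_expand(runs))


def apply_ruleset(seq: LabelSequence, rules: PostprocessRuleSet,
                  max_passes: int = 100) -> LabelSequence:
    """Out-merge, then smooth, then dismiss — iterated to a fixed point.

    Smoothing can shrink an Out run below the merge threshold, so a single
    pass is not idempotent in general; the pass is repeated until the
    sequence stabilizes (almost always 2-3 passes).  Length is conserved
    throughout.
    """
    if Task(rules.task) is not Task(seq.task):
        raise ValueError(
            f"ruleset task {rules.task.value!r} does not match "
            f"sequence task {Task(seq.task).value!r}"
        )
    current = seq
    for _ in range(max_passes):
        out = merge_out_flicker(current, rules.out_merge_max_s)
        out = rolling_smooth(out, rules.rolling_window)
        out = dismiss_short_phases(out, rules.min_phase_s)
        if out.labels == current.labels:
            return out
        current = out
    return current


def load_ruleset_yaml(source: str | Path | Mapping) -> PostprocessRuleSet:
    """Build a ruleset from YAML of the form::

        postprocess:
          task: binary
          age_class: adult
          rolling_window: 5
          out_merge_max_s: 56
          min_phase_s: {standing: 300, lying: 300}
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    cfg = cfg.get("postprocess", cfg)
    return PostprocessRuleSet(
        task=Task(cfg["task"]),
        age_class=cfg.get("age_class", "adult"),
        rolling_window=int(cfg.get("rolling_window", 5)),
        out_merge_max_s=float(cfg.get("out_merge_max_s", 56.0)),
        min_phase_s=cfg.get("min_phase_s", {}),
    )
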