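"""Fusion of single-frame and multiple-frame classifier outputs, plus the
training-set machinery around them: hard/random example mining, class
balancing by upsampling, and stratified train/validation splitting.

The per-interval label is the argmax of the average of the single-frame
aggregate (mean over the four per-frame probability vectors) and the
multiple-frame probability vector.  An interval whose four images are all
black bypasses fusion and is labeled Out.  A *hard* example is an interval
where the two classifiers disagree or the fused confidence is low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .core import BehaviorLabel, Task, vocabulary

__all__ = [
    "IntervalPrediction",
    "ExampleRef",
    "MiningSelection",
    "sf_aggregate",
    "fuse_interval",
    "mine_hard_examples",
    "sample_balanced",
    "rebalance_upsample",
    "split_train_val",
    "predictions_to_frame",
]

_PROB_TOL = 1e-6


def _validate_prob_vector(v: np.ndarray, k: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (k,):
        raise ValueError(f"{name} must have {k} entries, got shape {v.shape}")
    if (v < -_PROB_TOL).any() or abs(v.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} is not a probability vector (sum {v.sum():.8f})")
    return v


@dataclass
class IntervalPrediction:
    """Probability vectors and fused label for one interval of one animal."""

    interval_index: int
    individual_id: str
    task: Task
    sf_probs: np.ndarray | None  # (4, k) per-frame vectors; None if bypassed
    mf_probs: np.ndarray | None  # (k,)
    fused_probs: np.ndarray      # (k,)
    fused_label: BehaviorLabel
    confidence: float
    night_id: str = ""

    @property
    def sf_agg(self) -> np.ndarray | None:
        return None if self.sf_probs is None else self.sf_probs.mean(axis=0)

    @property
    def sf_label(self) -> BehaviorLabel | None:
        agg = self.sf_agg
        if agg is None:
            return None
        return vocabulary(self.task)[int(np.argmax(agg))]

    @property
    def mf_label(self) -> BehaviorLabel | None:
        if self.mf_probs is None:
            return None
        return vocabulary(self.task)[int(np.argmax(self.mf_probs))]


def sf_aggregate(sf_probs: np.ndarray) -> np.ndarray:
    """Order-invariant aggregation of the four per-frame vectors (mean)."""
    return np.asarray(sf_probs, dtype=float).mean(axis=0)


def fuse_interval(sf_probs: np.ndarray | Sequence[Sequence[float]] | None,
                  mf_probs: np.ndarray | Sequence[float] | None,
                  task: Task,
                  interval_index: int = 0,
                  individual_id: str = "",
                  night_id: str = "",
                  all_black: bool = False) -> IntervalPrediction:
    """Average the single-frame aggregate with the multiple-frame vector.

    The fused label is the argmax, ties broken by the fixed class order of
    the task vocabulary (Standing < LHU < LHD < Out).  ``all_black``
    bypasses fusion entirely: no animal was visible on any of the four
    frames, so the interval is Out with full confidence.
    """
    task = Task(task)
    vocab = vocabulary(task)
    k = len(vocab)
    if all_black:
        fused = np.zeros(k)
        fused[vocab.index(BehaviorLabel.OUT)] = 1.0
        return IntervalPrediction(
            interval_index, individual_id, task, None, None, fused,
            BehaviorLabel.OUT, 1.0, night_id,
        )
    sf = np.asarray(sf_probs, dtype=float)
    if sf.ndim != 2:
        raise ValueError("sf_probs must be a stack of per-frame vectors")
    for i, row in enumerate(sf):
        _validate_prob_vector(row, k, f"sf_probs[{i}]")
    mf = _validate_prob_vector(np.asarray(mf_probs, dtype=float), k, "mf_probs")
    fused = (sf.mean(axis=0) + mf) / 2.0
    label = vocab[int(np.argmax(fused))]  # argmax returns the first maximum
    return IntervalPrediction(
        interval_index, individual_id, task, sf, mf, fused, label,
        float(fused.max()), night_id,
    )


@dataclass(frozen=True)
class ExampleRef:
    night_id: str
    interval_index: int
    individual_id: str
    label: BehaviorLabel | None = None


@dataclass
class MiningSelection:
    """A reproducible selection of training examples (random or hard)."""

    kind: str  # "random" | "hard"
    refs: tuple[ExampleRef, ...]
    seed: int | None = None
    quota: int | None = None
    shortfall: dict[BehaviorLabel, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("random", "hard"):
            raise ValueError("kind must be 'random' or 'hard'")
        if len(set(self.refs)) != len(self.refs):
            raise ValueError("duplicate example refs in selection")


def _ref(p: IntervalPrediction) -> ExampleRef:
    return ExampleRef(p.night_id, p.interval_index, p.individual_id, p.fused_label)


def mine_hard_examples(preds: Iterable[IntervalPrediction],
                       tau: float = 0.75) -> MiningSelection:
    """Intervals where SF and MF disagree, or fused confidence < tau.

    Bypassed (all-black) intervals carry no classifier signal and are not
    minable.  The hard set grows monotonically with tau.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    refs = []
    for p in preds:
        if p.sf_probs is None or p.mf_probs is None:
            continue
        if p.sf_label != p.mf_label or p.confidence < tau:
            refs.append(_ref(p))
    return MiningSelection(kind="hard", refs=tuple(refs))


def sample_balanced(preds: Sequence[IntervalPrediction], n_per_class: int,
                    seed: int) -> MiningSelection:
    """Random examples: per class, up to ``n_per_class`` intervals sampled
    without replacement, stratified as evenly as possible across nights.

    Scarcity is capped, not an error: a class with fewer available
    intervals contributes everything it has and the shortfall is reported.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    by_class: dict[BehaviorLabel, dict[str, list[IntervalPrediction]]] = {}
    for p in preds:
        by_class.setdefault(p.fused_label, {}).setdefault(p.night_id, []).append(p)

    refs: list[ExampleRef] = []
    shortfall: dict[BehaviorLabel, int] = {}
    for label in sorted(by_class, key=lambda l: l.value):
        nights = by_class[label]
        pools = {
            night: list(rng.permutation(len(items)))
            for night, items in sorted(nights.items())
        }
        chosen: list[IntervalPrediction] = []
        # round-robin over nights for an even spread of the quota
        while len(chosen) < n_per_class and any(pools.values()):
            for night in sorted(pools):
                if pools[night] and len(chosen) < n_per_class:
                    chosen.append(nights[night][pools[night].pop()])
        refs.extend(_ref(p) for p in chosen)
        if len(chosen) < n_per_class:
            shortfall[label] = n_per_class - len(chosen)
    return MiningSelection(kind="random", refs=tuple(refs), seed=seed,
                           quota=n_per_class, shortfall=shortfall)


T = TypeVar("T")


def rebalance_upsample(examples_by_class: Mapping[BehaviorLabel, Sequence[T]],
                       seed: int) -> dict[BehaviorLabel, list[T]]:
    """Duplication plan equalizing class sizes by random upsampling.

    Returns, per class, the extra examples (drawn with replacement, seeded)
    needed to reach the majority-class count; already-balanced input yields
    empty lists.  A class with zero examples cannot be upsampled.
    """
    for label, ex in examples_by_class.items():
        if len(ex) == 0:
            raise ValueError(
                f"class {label} has no examples; cannot upsample from nothing"
            )
    rng = np.random.default_rng(seed)
    target = max(len(ex) for ex in examples_by_class.values())
    plan: dict[BehaviorLabel, list[T]] = {}
    for label in sorted(examples_by_class, key=lambda l: str(l)):
        ex = examples_by_class[label]
        n_extra = target - len(ex)
        idx = rng.integers(0, len(ex), size=n_extra)
        plan[label] = [ex[i] for i in idx]
    return plan


def split_train_val(examples: Sequence[T], labels: Sequence,
                    val_fraction: float, seed: int) -> tuple[list[T], list[T]]:
    """Seeded, per-class stratified split into disjoint, exhaustive
    train/validation sets (e.g. 90/10 for classifiers, 95/5 for detectors)."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    if len(examples) != len(labels):
        raise ValueError("examples and labels must align")
    rng = np.random.default_rng(seed)
    by_class: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    val_idx: set[int] = set()
    for lab in sorted(by_class, key=str):
        idx = by_class[lab]
        n_val = int(round(len(idx) * val_fraction))
        if len(idx) >= 2:
            n_val = min(max(n_val, 1), len(idx) - 1)
        else:
            n_val = 0
        picked = rng.choice(len(idx), size=n_val, replace=False)
        val_idx.update(idx[i] for i in picked)
    train = [examples[i] for i in range(len(examples)) if i not in val_idx]
    val = [examples[i] for i in range(len(examples)) if i in val_idx]
    return train, val


def predictions_to_frame(preds: Iterable[IntervalPrediction]) -> pd.DataFrame:
    """Prediction table: sf_agg_*, mf_*, fused_* probabilities per interval."""
    rows = []
    for p in preds:
        vocab = vocabulary(p.task)
        row = {
            "night_id": p.night_id,
            "individual_id": p.individual_id,
            "task": p.task.value,
            "interval_index": p.interval_index,
            "label": p.fused_label.value,
            "confidence": p.confidence,
        }
        agg = p.sf_agg
        for i, lab in enumerate(vocab):
            row[f"sf_agg_{lab.value}"] = float(agg[i]) if agg is not None else np.nan
            row[f"mf_{lab.value}"] = (
                float(p.mf_probs[i]) if p.mf_probs is not None else np.nan
            )
            row[f"fused_{lab.value}"] = float(p.fused_probs[i])
        rows.append(row)
    return pd.DataFrame(rows)
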