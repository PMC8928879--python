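"""Classifier-backend contract and the shape-heuristic mock classifier.

A classifier backend maps a (cropped, resized) grayscale image to a
probability vector over the task vocabulary.  Real deployments plug a
trained network in here; tests and the end-to-end identity check use the
deterministic shape heuristic below, which decodes the postures the toy
renderer draws:

* an (almost) empty crop is Out,
* a crop filled wall-to-wall with foreground is Standing (the tall body
  is the whole bounding box),
* otherwise the animal is lying, and the placement of the background
  tells the head position: background concentrated in the upper half
  means a raised head (LHU); background split evenly over a full-height
  gap means the head rests on the ground in front of the body (LHD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .core import BehaviorLabel, Task, vocabulary

__all__ = ["ClassifierBackend", "ShapeHeuristicClassifier"]


class ClassifierBackend(Protocol):
    task: Task

    def predict_proba(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class ShapeHeuristicClassifier:
    """Deterministic posture classifier for renderer output."""

    task: Task = Task.TOTAL
    fg_threshold: int = 100     # background ~20, body 200, head 255
    empty_fg_max: float = 0.02  # below: no animal in the crop -> Out
    standing_bg_max: float = 0.08
    lhu_top_share_min: float = 0.70

    def _onehot(self, label: BehaviorLabel) -> np.ndarray:
        vocab = vocabulary(self.task)
        v = np.zeros(len(vocab))
        v[vocab.index(label)] = 1.0
        return v

    def predict_label(self, image: np.ndarray) -> BehaviorLabel:
        fg = np.asarray(image) > self.fg_threshold
        fg_frac = fg.mean()
        if fg_frac < self.empty_fg_max:
            return BehaviorLabel.OUT
        if 1.0 - fg_frac < self.standing_bg_max:
            return BehaviorLabel.STANDING
        if Task(self.task) is Task.BINARY:
            return BehaviorLabel.LYING
        bg = ~fg
        top = bg[: bg.shape[0] // 2].sum()
        share = top / bg.sum()
        return BehaviorLabel.LHU if share >= self.lhu_top_share_min \
            else BehaviorLabel.LHD

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return self._onehot(self.predict_label(image))

    def predict_proba_tile(self, tile: np.ndarray,
                           layout: tuple[int, int] = (2, 2)) -> np.ndarray:
        """Multi-frame prediction: classify each tile quadrant, average.

        This keeps the mock faithful to a real multi-frame network's
        interface (one probability vector per encoded image) while staying
        a pure function of the tile's pixels.
        """
        rows, cols = layout
        h, w = tile.shape[0] // rows, tile.shape[1] // cols
        votes = [
            self.predict_proba(tile[r * h:(r + 1) * h, c * w:(c + 1) * w])
            for r in range(rows) for c in range(cols)
        ]
        return np.mean(votes, axis=0)
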