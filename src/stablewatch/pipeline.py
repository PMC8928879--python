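"""Glue for the full prediction chain of one night:

frames -> detector -> per-interval crops & multi-frame tile ->
single-frame + multiple-frame classification -> fusion -> label sequence
(optionally postprocessed).
"""

from __future__ import annotations

from datetime import time
from typing import Sequence

import numpy as np

from .core import BehaviorLabel, LabelSequence, Task, vocabulary
from .detection import DetectionRecord, detection_density, select_individual_boxes
from .encoding import (DEFAULT_CROP_SIZE, FrameStore, assemble_interval_frames,
                       build_interval_grid, tile_multiframe)
from .fusion import IntervalPrediction, fuse_interval
from .postprocess import PostprocessRuleSet, apply_ruleset

__all__ = ["predict_night"]


def _out_onehot(task: Task) -> np.ndarray:
    vocab = vocabulary(task)
    v = np.zeros(len(vocab))
    v[vocab.index(BehaviorLabel.OUT)] = 1.0
    return v


def predict_night(frame_store: FrameStore, detector, sf_classifier,
                  mf_classifier, n_frames: int, individual_id: str,
                  night_id: str, task: Task = Task.TOTAL,
                  crop_size: tuple[int, int] = DEFAULT_CROP_SIZE,
                  min_confidence: float = 0.5,
                  tile_layout: tuple[int, int] = (2, 2),
                  rules: PostprocessRuleSet | None = None,
                  night_start: time = time(17, 0),
                  ) -> tuple[LabelSequence, list[IntervalPrediction], dict]:
    """Predict one individual's night.

    The detector is queried on the four sampled frames of each 7-s
    interval; a frame where the detector misses the individual becomes a
    black image, and an interval with four black images bypasses fusion
    as Out.  Returns the (optionally postprocessed) label sequence, the
    per-interval predictions, and the detection density over the sampled
    frames (QC 1).
    """
    task = Task(task)
    grid = build_interval_grid(n_frames, night_start)
    preds: list[IntervalPrediction] = []
    labels: list[BehaviorLabel] = []
    kept_records: list[DetectionRecord] = []
    n_sampled_frames = 0

    for i in range(grid.n_intervals):
        frames = [f for f in grid.frames_of_interval(i) if f < n_frames]
        n_sampled_frames += len(frames)
        proposals: list[DetectionRecord] = []
        for f in frames:
            proposals.extend(detector.detect(f))
        kept = select_individual_boxes(proposals, min_confidence)
        boxes = {
            f: rec.box for (f, ind), rec in kept.items() if ind == individual_id
        }
        kept_records.extend(
            rec for (f, ind), rec in kept.items() if ind == individual_id
        )
        batch = assemble_interval_frames(grid, i, frame_store, boxes,
                                         individual_id, crop_size)
        if batch.all_black:
            pred = fuse_interval(None, None, task, i, individual_id,
                                 night_id, all_black=True)
        else:
            sf = np.stack([
                _out_onehot(task) if black else sf_classifier.predict_proba(img)
                for img, black in zip(batch.images, batch.is_black)
            ])
            tile = tile_multiframe(batch, tile_layout)
            mf = mf_classifier.predict_proba_tile(tile, tile_layout)
            pred = fuse_interval(sf, mf, task, i, individual_id, night_id)
        preds.append(pred)
        labels.append(pred.fused_label)

    seq = LabelSequence(night_id=night_id, individual_id=individual_id,
                        task=task, labels=tuple(labels),
                        night_start=night_start)
    if rules is not None:
        seq = apply_ruleset(seq, rules)
    density = (
        detection_density(kept_records, n_sampled_frames)
        if n_sampled_frames else {}
    )
    return seq, preds, density
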