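"""Synthetic nights: ground-truth behavior sequences, classifier-like
corruption, and toy rendered frames with exact bounding boxes.

The generator emulates the nightly behavior of stalled ungulates as an
alternating semi-Markov process: Standing and Lying bouts alternate, bout
durations are log-normal with demographic-specific medians (adult males
lie longest, adult females shortest, nonadults stand in shorter bouts),
and Lying bouts contain LHD (head-down, REM-posture) sub-bouts entered
only from LHU — an animal lowers its head from lying, never from
standing.  Occasional Out bouts model the animal leaving the camera's
field of view for a few minutes.

The corruption model reproduces what a frame classifier chain does to
such a sequence: independent per-interval confusion flips, short bursts
of a wrong label (classification flickering), and Out runs caused by
detection dropout.  The renderer draws deliberately crude shape-coded
frames whose only job is deterministic separability for the mock
classifier, so the whole pipeline can be exercised end to end without
trained network weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

from .core import BehaviorLabel, LabelSequence, Task, vocabulary
from .detection import DetectionRecord, write_voc_xml

__all__ = [
    "SyntheticProfile",
    "NoiseModel",
    "EnclosureSpec",
    "SyntheticNightRenderer",
    "sample_night_sequence",
    "corrupt_prediction",
    "render_synthetic_frames",
    "load_scenario",
]

_DEMOGRAPHIC_MEDIANS_MIN = {
    # demographic: (standing, lying, lhd) median bout lengths in minutes
    "adult_male": (30.8, 89.6, 4.6),
    "adult_female": (35.5, 59.3, 3.7),
    "nonadult": (21.2, 78.5, 4.4),
}
# Median LHU stretch between LHD sub-bouts inside a Lying bout; calibrated
# so nightly LHD phase counts fall near the reported per-group bands.
_LHU_GAP_MEDIANS_MIN = {"adult_male": 50.0, "adult_female": 55.0,
                        "nonadult": 15.0}


@dataclass
class SyntheticProfile:
    """Dwell-time distributions and bout structure of one demographic.

    Dwell times are log-normal: the ``*_median_min`` values are the
    distribution medians (exp of the log-scale location), ``sigma`` the
    log-scale shape.  ``states`` lists the alternating macro-states; a
    single-state profile produces a constant night.
    """

    demographic: str = "adult_female"
    standing_median_min: float = 35.5
    lying_median_min: float = 59.3
    lhd_median_min: float = 3.7
    lhu_gap_median_min: float = 55.0
    sigma: float = 0.6
    out_bout_rate_per_h: float = 0.1
    out_median_s: float = 300.0
    night_length_h: float = 14.0
    interval_seconds: int = 7
    start_lying_prob: float = 0.5
    states: tuple[str, ...] = ("standing", "lying")

    def __post_init__(self) -> None:
        for name in ("standing_median_min", "lying_median_min",
                     "lhd_median_min", "lhu_gap_median_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma < 0 or self.out_bout_rate_per_h < 0:
            raise ValueError("sigma and out_bout_rate_per_h must be >= 0")
        if not set(self.states) <= {"standing", "lying"}:
            raise ValueError("states must be drawn from {'standing', 'lying'}")
        if not self.states:
            raise ValueError("at least one state required")

    @property
    def n_intervals(self) -> int:
        return int(round(self.night_length_h * 3600 / self.interval_seconds))

    @classmethod
    def for_demographic(cls, demographic: str, **overrides) -> "SyntheticProfile":
        try:
            standing, lying, lhd = _DEMOGRAPHIC_MEDIANS_MIN[demographic]
        except KeyError:
            raise ValueError(
                f"unknown demographic {demographic!r}; expected one of "
                f"{sorted(_DEMOGRAPHIC_MEDIANS_MIN)}"
            ) from None
        params = {
            "demographic": demographic,
            "standing_median_min": standing,
            "lying_median_min": lying,
            "lhd_median_min": lhd,
            "lhu_gap_median_min": _LHU_GAP_MEDIANS_MIN[demographic],
        }
        params.update(overrides)
        return cls(**params)


def _dwell_intervals(rng: np.random.Generator, median_min: float,
                     sigma: float, step_s: int) -> int:
    minutes = rng.lognormal(mean=np.log(median_min), sigma=sigma)
    return max(1, int(round(minutes * 60 / step_s)))


def sample_night_sequence(profile: SyntheticProfile, seed: int,
                          night_id: str = "night", individual_id: str = "ind",
                          task: Task = Task.TOTAL) -> LabelSequence:
    """Draw one ground-truth night, deterministic per seed.

    Standing/Lying bouts alternate with log-normal dwell times, truncated
    at night's end.  Inside each Lying bout, LHU stretches and LHD
    sub-bouts alternate (starting with LHU).  Out bouts (Poisson count,
    uniform start, log-normal duration) overwrite whatever behavior they
    land on, splitting the underlying phase — as a real departure from
    the field of view does.
    """
    rng = np.random.default_rng(seed)
    n = profile.n_intervals
    step = profile.interval_seconds
    labels = np.empty(n, dtype=object)

    if len(profile.states) == 1:
        state = profile.states[0]
    else:
        state = "lying" if rng.random() < profile.start_lying_prob else "standing"

    pos = 0
    while pos < n:
        if state == "standing":
            length = _dwell_intervals(rng, profile.standing_median_min,
                                      profile.sigma, step)
            end = min(pos + length, n)
            labels[pos:end] = BehaviorLabel.STANDING
        else:
            length = _dwell_intervals(rng, profile.lying_median_min,
                                      profile.sigma, step)
            end = min(pos + length, n)
            # LHU / LHD alternation inside the lying bout, LHU first: LHD
            # is entered only from LHU.
            sub = pos
            in_lhd = False
            while sub < end:
                med = (profile.lhd_median_min if in_lhd
                       else profile.lhu_gap_median_min)
                seg = _dwell_intervals(rng, med, profile.sigma, step)
                sub_end = min(sub + seg, end)
                labels[sub:sub_end] = (BehaviorLabel.LHD if in_lhd
                                       else BehaviorLabel.LHU)
                sub = sub_end
                in_lhd = not in_lhd
        pos = end
        if len(profile.states) > 1:
            state = "lying" if state == "standing" else "standing"

    # Out bouts lie within Standing bouts: leaving the camera's field of
    # view requires the animal to be on its feet, so a Lying bout is
    # never interrupted by Out in the ground truth (detection dropout
    # during lying is prediction noise, modeled separately).
    n_out = rng.poisson(profile.out_bout_rate_per_h * profile.night_length_h)
    standing_idx = np.flatnonzero(labels == BehaviorLabel.STANDING)
    for _ in range(n_out):
        if standing_idx.size == 0:
            break
        start = int(rng.choice(standing_idx))
        dur_s = rng.lognormal(mean=np.log(profile.out_median_s),
                              sigma=profile.sigma)
        length = max(1, int(round(dur_s / step)))
        bout_end = start
        while bout_end < n and labels[bout_end] is BehaviorLabel.STANDING:
            bout_end += 1
        labels[start:min(start + length, bout_end)] = BehaviorLabel.OUT

    seq = LabelSequence(night_id=night_id, individual_id=individual_id,
                        task=Task.TOTAL, labels=tuple(labels),
                        interval_seconds=step)
    if Task(task) is Task.BINARY:
        from .core import map_total_to_binary

        seq = map_total_to_binary(seq)
    return seq


@dataclass
class NoiseModel:
    """Classifier-chain noise: per-interval confusion flips, flicker
    bursts, and detection dropout.

    ``confusion`` maps each true label to its output distribution (rows
    sum to 1); ``None`` means the identity.  Bursts arrive at
    ``burst_rate_per_h`` with geometric lengths (mean
    ``burst_length_mean_intervals``, optionally capped) and carry a
    uniformly chosen wrong label.  ``detection_dropout`` is the per-frame
    probability that the detector misses the animal; an interval turns
    Out only when all four sampled frames are missed (independently).
    """

    confusion: Mapping[BehaviorLabel, Mapping[BehaviorLabel, float]] | None = None
    burst_rate_per_h: float = 0.0
    burst_length_mean_intervals: float = 3.0
    burst_length_max_intervals: int | None = None
    detection_dropout: float = 0.0
    frames_per_interval: int = 4

    def __post_init__(self) -> None:
        if self.burst_rate_per_h < 0 or self.burst_length_mean_intervals < 1:
            raise ValueError("invalid burst parameters")
        if not 0.0 <= self.detection_dropout <= 1.0:
            raise ValueError("detection_dropout must lie in [0, 1]")
        if self.confusion is not None:
            conf = {
                BehaviorLabel(k): {BehaviorLabel(kk): float(vv)
                                   for kk, vv in row.items()}
                for k, row in self.confusion.items()
            }
            for k, row in conf.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row for {k} does not sum to 1")
            self.confusion = conf

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls()

    @classmethod
    def flicker(cls, task: Task, flip_p: float = 0.0,
                burst_rate_per_h: float = 0.0,
                burst_length_mean_intervals: float = 3.0,
                burst_length_max_intervals: int | None = None,
                detection_dropout: float = 0.0) -> "NoiseModel":
        """Uniform confusion: each interval flips to any other label of the
        task vocabulary with total probability ``flip_p``."""
        vocab = vocabulary(task)
        conf = {
            a: {b: (1.0 - flip_p if a is b else flip_p / (len(vocab) - 1))
                for b in vocab}
            for a in vocab
        }
        return cls(confusion=conf, burst_rate_per_h=burst_rate_per_h,
                   burst_length_mean_intervals=burst_length_mean_intervals,
                   burst_length_max_intervals=burst_length_max_intervals,
                   detection_dropout=detection_dropout)


def corrupt_prediction(truth: LabelSequence, noise: NoiseModel,
                       seed: int) -> LabelSequence:
    """Apply confusion flips, then bursts, then dropout-Out runs; seeded.

    A zero-noise model returns the input labels unchanged.
    """
    rng = np.random.default_rng(seed)
    vocab = vocabulary(truth.task)
    index = {l: i for i, l in enumerate(vocab)}
    n = len(truth.labels)
    codes = np.fromiter((index[l] for l in truth.labels), dtype=np.intp, count=n)
    out = codes.copy()

    if noise.confusion is not None:
        P = np.array([[noise.confusion[a].get(b, 0.0) for b in vocab]
                      for a in vocab])
        if not np.allclose(P, np.eye(len(vocab))):
            for c in range(len(vocab)):
                mask = codes == c
                if mask.any():
                    out[mask] = rng.choice(len(vocab), size=int(mask.sum()),
                                           p=P[c])

    hours = n * truth.interval_seconds / 3600.0
    n_bursts = rng.poisson(noise.burst_rate_per_h * hours) \
        if noise.burst_rate_per_h > 0 else 0
    for _ in range(n_bursts):
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / noise.burst_length_mean_intervals))
        if noise.burst_length_max_intervals is not None:
            length = min(length, noise.burst_length_max_intervals)
        wrong = [i for i in range(len(vocab)) if i != codes[start]]
        out[start:start + length] = int(rng.choice(wrong))

    if noise.detection_dropout > 0:
        p_interval = noise.detection_dropout ** noise.frames_per_interval
        mask = rng.random(n) < p_interval
        out[mask] = index[BehaviorLabel.OUT]

    return truth.with_labels(vocab[c] for c in out)


# ---------------------------------------------------------------------------
# Toy frame renderer


@dataclass(frozen=True)
class EnclosureSpec:
    """Geometry and intensities of the toy enclosure renderer."""

    width: int = 160
    height: int = 120
    ground_y: int = 100  # animals stand/lie on this line
    jitter_px: int = 2
    bg_level: int = 20
    bg_noise: int = 8
    body_level: int = 200
    head_level: int = 255


class SyntheticNightRenderer:
    """Deterministic frame-by-frame renderer for one synthetic night.

    Each frame shows a shape encoding the interval's state: a tall
    rectangle for Standing (box height > width), a flat rectangle with a
    raised head blob for LHU, a flat rectangle with a low head blob in
    front for LHD, and nothing for Out.  The exact foreground bounding
    box is emitted as ground truth.  Frames listed in ``gap_frames``
    simulate recorder failures and render fully black.
    """

    def __init__(self, seq: LabelSequence, enclosure: EnclosureSpec | None = None,
                 seed: int = 0, gap_frames: set[int] | None = None):
        if Task(seq.task) is not Task.TOTAL:
            raise ValueError("renderer needs a total-task sequence")
        self.seq = seq
        self.enclosure = enclosure or EnclosureSpec()
        self.seed = int(seed)
        self.gap_frames = gap_frames or set()
        self.n_frames = len(seq.labels) * seq.interval_seconds

    def label_of_frame(self, frame_index: int) -> BehaviorLabel:
        return self.seq.labels[frame_index // self.seq.interval_seconds]

    def _geometry(self, frame_index: int):
        """Foreground rectangles [(x0, y0, x1, y1, level), ...] or None."""
        e = self.enclosure
        label = self.label_of_frame(frame_index)
        if label is BehaviorLabel.OUT:
            return None
        rng = np.random.default_rng([self.seed, frame_index])
        dx = int(rng.integers(-e.jitter_px, e.jitter_px + 1)) if e.jitter_px else 0
        dy = int(rng.integers(-e.jitter_px, e.jitter_px + 1)) if e.jitter_px else 0
        g = e.ground_y + dy
        if label is BehaviorLabel.STANDING:
            rects = [(60 + dx, g - 60, 90 + dx, g, e.body_level)]
        elif label is BehaviorLabel.LHU:
            rects = [
                (50 + dx, g - 20, 110 + dx, g, e.body_level),      # body
                (50 + dx, g - 50, 66 + dx, g - 28, e.head_level),  # raised head
            ]
        else:  # LHD: head resting on the ground in front of the body
            rects = [
                (50 + dx, g - 20, 110 + dx, g, e.body_level),
                (26 + dx, g - 16, 42 + dx, g, e.head_level),
            ]
        return rects

    def box(self, frame_index: int) -> tuple[float, float, float, float] | None:
        """Exact foreground bounding box, or None for Out / gap frames."""
        if frame_index in self.gap_frames:
            return None
        rects = self._geometry(frame_index)
        if rects is None:
            return None
        x0 = min(r[0] for r in rects)
        y0 = min(r[1] for r in rects)
        x1 = max(r[2] for r in rects)
        y1 = max(r[3] for r in rects)
        return (float(x0), float(y0), float(x1), float(y1))

    def get_frame(self, frame_index: int) -> np.ndarray:
        e = self.enclosure
        if frame_index in self.gap_frames:
            return np.zeros((e.height, e.width), dtype=np.uint8)
        rng = np.random.default_rng([self.seed, frame_index, 1])
        img = rng.integers(max(0, e.bg_level - e.bg_noise),
                           e.bg_level + e.bg_noise + 1,
                           size=(e.height, e.width)).astype(np.uint8)
        rects = self._geometry(frame_index)
        if rects is not None:
            for x0, y0, x1, y1, level in rects:
                img[max(0, y0):y1, max(0, x0):x1] = level
        return img

    def detections(self, frame_index: int) -> list[DetectionRecord]:
        box = self.box(frame_index)
        if box is None:
            return []
        return [DetectionRecord(frame_index, self.seq.individual_id, box, 1.0)]

    def write_voc(self, out_dir: str | Path,
                  frame_indices: Sequence[int] | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        e = self.enclosure
        indices = range(self.n_frames) if frame_indices is None else frame_indices
        for f in indices:
            recs = self.detections(f)
            if recs:  # no XML file at all when nothing was annotated
                write_voc_xml(out_dir / f"{f}.xml", recs, (e.width, e.height))

    def write_frames(self, out_dir: str | Path,
                     frame_indices: Sequence[int] | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        indices = range(self.n_frames) if frame_indices is None else frame_indices
        for f in indices:
            Image.fromarray(self.get_frame(f)).save(out_dir / f"{f}.png")


def render_synthetic_frames(seq: LabelSequence,
                            enclosure: EnclosureSpec | None = None,
                            seed: int = 0,
                            out_dir: str | Path | None = None,
                            frame_indices: Sequence[int] | None = None,
                            write_images: bool = True,
                            ) -> SyntheticNightRenderer:
    """Render a night; optionally write PNG frames and VOC XML boxes."""
    renderer = SyntheticNightRenderer(seq, enclosure, seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        renderer.write_voc(out_dir / "annotations", frame_indices)
        if write_images:
            renderer.write_frames(out_dir / "frames", frame_indices)
    return renderer


def load_scenario(source: str | Path | Mapping) -> dict:
    """Load a scenario YAML: profiles, noise, number of nights, seeds.

    Returns ``{"profiles": {name: SyntheticProfile}, "noise": NoiseModel,
    "n_nights": int, "seed": int}``.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    profiles = {}
    for name, spec in cfg.get("profiles", {}).items():
        spec = dict(spec or {})
        demographic = spec.pop("demographic", name)
        profiles[name] = SyntheticProfile.for_demographic(demographic, **spec)
    noise_cfg = cfg.get("noise") or {}
    task = Task(noise_cfg.pop("task", "total"))
    noise = NoiseModel.flicker(task, **noise_cfg) if noise_cfg else NoiseModel.none()
    return {
        "profiles": profiles,
        "noise": noise,
        "n_nights": int(cfg.get("n_nights", 1)),
        "seed": int(cfg.get("seed", 0)),
    }
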