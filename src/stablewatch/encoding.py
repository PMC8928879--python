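"""Interval encoding of nightly frame sequences.

A night recorded at 1 fps is discretized into 7-second intervals.  For each
interval four frames (offsets 0, 2, 4, 6 within the 7-frame window) are
cropped to the individual's bounding box, resized to the classifier input
size, and additionally tiled into a single 2x2 multi-frame image that
exposes the temporal dimension to a single-image classifier.  Missing
frames or missing detections become black images; an interval whose four
images are all black is labeled Out downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import time
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "IntervalGrid",
    "FrameBatch",
    "FrameStore",
    "DirectoryFrameStore",
    "build_interval_grid",
    "crop_to_box",
    "black_image",
    "assemble_interval_frames",
    "tile_multiframe",
]

DEFAULT_FRAME_OFFSETS = (0, 2, 4, 6)
DEFAULT_CROP_SIZE = (300, 300)  # classifier input (width, height)

Box = tuple[float, float, float, float]  # x_min, y_min, x_max, y_max


@dataclass(frozen=True)
class IntervalGrid:
    """Partition of a night's frames into 7-s intervals.

    Frame ``f`` belongs to interval ``f // interval_seconds``; a trailing
    partial interval is retained (padded with black downstream) so the
    nominal night length is preserved.
    """

    n_frames: int
    night_start: time = time(17, 0)
    interval_seconds: int = 7
    frames_per_interval: int = 4
    frame_offsets: tuple[int, ...] = DEFAULT_FRAME_OFFSETS

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        if len(self.frame_offsets) != self.frames_per_interval:
            raise ValueError("frame_offsets length must equal frames_per_interval")
        if any(o < 0 or o >= self.interval_seconds for o in self.frame_offsets):
            raise ValueError("frame offsets must lie within the interval window")

    @property
    def n_intervals(self) -> int:
        return math.ceil(self.n_frames / self.interval_seconds)

    def interval_of_frame(self, frame_index: int) -> int:
        if not 0 <= frame_index < self.n_frames:
            raise IndexError("frame index outside the night")
        return frame_index // self.interval_seconds

    def frames_of_interval(self, interval_index: int) -> tuple[int, ...]:
        """The (up to 4) sampled frame indices of an interval; indices past
        the end of the night are reported as-is and filled black later."""
        base = interval_index * self.interval_seconds
        return tuple(base + o for o in self.frame_offsets)


def build_interval_grid(n_frames: int, night_start: time = time(17, 0),
                        interval_seconds: int = 7,
                        frame_offsets: Sequence[int] = DEFAULT_FRAME_OFFSETS,
                        ) -> IntervalGrid:
    return IntervalGrid(
        n_frames=n_frames,
        night_start=night_start,
        interval_seconds=interval_seconds,
        frames_per_interval=len(frame_offsets),
        frame_offsets=tuple(frame_offsets),
    )


class FrameStore(Protocol):
    """Anything that yields a grayscale frame raster (or None if missing)."""

    def get_frame(self, frame_index: int) -> np.ndarray | None: ...


class DirectoryFrameStore:
    """Frame store over ``<root>/<night_id>/<frame_index>.png`` files."""

    def __init__(self, root: str | Path, night_id: str | None = None):
        self.root = Path(root) if night_id is None else Path(root) / night_id

    def get_frame(self, frame_index: int) -> np.ndarray | None:
        for name in (f"{frame_index}.png", f"{frame_index:06d}.png",
                     f"{frame_index}.jpg"):
            p = self.root / name
            if p.exists():
                return np.asarray(Image.open(p).convert("L"))
        return None


def black_image(crop_size: tuple[int, int] = DEFAULT_CROP_SIZE) -> np.ndarray:
    w, h = crop_size
    return np.zeros((h, w), dtype=np.uint8)


def crop_to_box(image: np.ndarray, box: Box,
                crop_size: tuple[int, int] = DEFAULT_CROP_SIZE) -> np.ndarray:
    """Crop an image to a bounding box (clipped to the image bounds) and
    resize to the classifier input size.

    Raises on a degenerate box; a box lying fully outside the image is a
    detection error and also rejected (callers treat it as no detection).
    """
    x_min, y_min, x_max, y_max = box
    if x_max <= x_min or y_max <= y_min:
        raise ValueError(f"degenerate box {box}")
    h, w = image.shape[:2]
    xa, ya = max(0, int(math.floor(x_min))), max(0, int(math.floor(y_min)))
    xb, yb = min(w, int(math.ceil(x_max))), min(h, int(math.ceil(y_max)))
    if xb <= xa or yb <= ya:
        raise ValueError(f"box {box} lies outside the {w}x{h} image")
    crop = image[ya:yb, xa:xb]
    out = Image.fromarray(np.ascontiguousarray(crop)).resize(
        crop_size, Image.BILINEAR
    )
    return np.asarray(out)


@dataclass
class FrameBatch:
    """The four (cropped, resized) images representing one interval."""

    interval_index: int
    individual_id: str
    images: tuple[np.ndarray, ...]
    is_black: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.is_black):
            raise ValueError("images and is_black must align")

    @property
    def all_black(self) -> bool:
        return all(self.is_black)


def assemble_interval_frames(grid: IntervalGrid, interval_index: int,
                             frame_store: FrameStore,
                             boxes: Mapping[int, Box],
                             individual_id: str = "",
                             crop_size: tuple[int, int] = DEFAULT_CROP_SIZE,
                             ) -> FrameBatch:
    """Collect the interval's four cropped images.

    A frame beyond the end of the night, an unreadable frame, or a frame
    without a detection box yields a black image flagged in ``is_black``;
    missingness is data, not an error.
    """
    images: list[np.ndarray] = []
    flags: list[bool] = []
    for f in grid.frames_of_interval(interval_index):
        img = frame_store.get_frame(f) if f < grid.n_frames else None
        box = boxes.get(f)
        if img is None or box is None:
            images.append(black_image(crop_size))
            flags.append(True)
            continue
        try:
            images.append(crop_to_box(img, box, crop_size))
            flags.append(False)
        except ValueError:  # box fully outside bounds = no usable detection
            images.append(black_image(crop_size))
            flags.append(True)
    return FrameBatch(
        interval_index=interval_index,
        individual_id=individual_id,
        images=tuple(images),
        is_black=tuple(flags),
    )


def tile_multiframe(batch: FrameBatch | Sequence[np.ndarray],
                    layout: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Tile the 4 interval images into one multi-frame encoded image.

    Default layout is a 2x2 grid in row-major temporal order
    (t0 t1 / t2 t3); a 1x4 strip is available via ``layout=(1, 4)``.
    """
    images = batch.images if isinstance(batch, FrameBatch) else tuple(batch)
    rows, cols = layout
    if rows * cols != len(images):
        raise ValueError(f"layout {layout} does not fit {len(images)} images")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("tile_multiframe requires uniformly sized images")
    return np.block(
        [[images[r * cols + c] for c in range(cols)] for r in range(rows)]
    )
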