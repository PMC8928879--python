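"""Object-detection I/O: the detector-backend contract, per-individual box
selection, detection-density quality control and box-quality bookkeeping.

The detector itself is a pluggable backend; this package ships a
file-backed mock that replays ground-truth Pascal-VOC XML (the LabelImg
dialect) with optional coordinate jitter.  A trained network can be
adapted behind the same ``detect(frame_index) -> [DetectionRecord]``
contract.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "BoxQualityRecord",
    "BoxQualitySummary",
    "BOX_QUALITY_CATEGORIES",
    "select_individual_boxes",
    "detection_density",
    "summarize_box_quality",
    "read_voc_xml",
    "write_voc_xml",
    "FileBackedDetector",
    "density_report",
]

BOX_QUALITY_CATEGORIES = ("good", "okay", "poor", "swapped")


@dataclass(frozen=True)
class DetectionRecord:
    """One proposed bounding box: pixel coordinates, 0-based,
    x_max/y_max exclusive, with the detector's confidence in [0, 1]."""

    frame_index: int
    individual_id: str
    box: tuple[float, float, float, float]
    confidence: float

    def __post_init__(self) -> None:
        x_min, y_min, x_max, y_max = self.box
        if x_max <= x_min or y_max <= y_min:
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class BoxQualityRecord:
    """Human judgement of one automatically drawn box (good/okay/poor/swapped)."""

    frame_index: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in BOX_QUALITY_CATEGORIES:
            raise ValueError(f"unknown quality category {self.category!r}")


@dataclass
class BoxQualitySummary:
    counts: dict[str, int]
    correction_fraction: float | None  # (poor + swapped) / total; None if empty


def select_individual_boxes(
    proposals: Iterable[DetectionRecord], min_confidence: float = 0.5
) -> dict[tuple[int, str], DetectionRecord]:
    """Keep at most one box per (frame, individual).

    Proposals below ``min_confidence`` are dropped; among survivors the
    highest-confidence box wins, ties broken deterministically by smaller
    x_min.
    """
    kept: dict[tuple[int, str], DetectionRecord] = {}
    for rec in proposals:
        if rec.confidence < min_confidence:
            continue
        key = (rec.frame_index, rec.individual_id)
        cur = kept.get(key)
        if (
            cur is None
            or rec.confidence > cur.confidence
            or (rec.confidence == cur.confidence and rec.box[0] < cur.box[0])
        ):
            kept[key] = rec
    return kept


def detection_density(
    selected: Mapping[tuple[int, str], DetectionRecord] | Iterable[DetectionRecord],
    n_frames: int,
) -> dict[str, float]:
    """Per-individual fraction of frames with a kept detection (QC 1)."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    records = selected.values() if isinstance(selected, Mapping) else selected
    frames_per_ind: dict[str, set[int]] = {}
    for rec in records:
        frames_per_ind.setdefault(rec.individual_id, set()).add(rec.frame_index)
    return {ind: len(frames) / n_frames for ind, frames in frames_per_ind.items()}


def summarize_box_quality(records: Sequence[BoxQualityRecord]) -> BoxQualitySummary:
    """Counts per category plus the fraction needing manual correction
    (poor or swapped boxes are redrawn by hand and become hard examples)."""
    counts = {c: 0 for c in BOX_QUALITY_CATEGORIES}
    for r in records:
        counts[r.category] += 1
    total = len(records)
    frac = None if total == 0 else (counts["poor"] + counts["swapped"]) / total
    return BoxQualitySummary(counts=counts, correction_fraction=frac)


# ---------------------------------------------------------------------------
# Pascal-VOC XML (LabelImg dialect)


def read_voc_xml(path: str | Path, frame_index: int | None = None
                 ) -> list[DetectionRecord]:
    """Read LabelImg-style VOC XML (``<object><name>``, ``<bndbox>``).

    ``frame_index`` defaults to the integer file stem.  A ``<confidence>``
    child of ``<object>`` is honored if present (1.0 otherwise — manual
    annotations are certain).
    """
    path = Path(path)
    if frame_index is None:
        frame_index = int(path.stem)
    root = ET.parse(path).getroot()
    records = []
    for obj in root.iter("object"):
        name = obj.findtext("name", default="")
        bnd = obj.find("bndbox")
        if bnd is None:
            continue
        box = tuple(
            float(bnd.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax")
        )
        conf = float(obj.findtext("confidence", default="1.0"))
        records.append(DetectionRecord(frame_index, name, box, conf))
    return records


def write_voc_xml(path: str | Path, records: Sequence[DetectionRecord],
                  image_size: tuple[int, int], filename: str | None = None) -> None:
    """Write boxes of one frame as LabelImg-style VOC XML."""
    path = Path(path)
    w, h = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name
    ET.SubElement(root, "filename").text = filename or path.with_suffix(".png").name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "1"
    for rec in records:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = rec.individual_id
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        ET.SubElement(obj, "confidence").text = f"{rec.confidence:.6f}"
        bnd = ET.SubElement(obj, "bndbox")
        for k, v in zip(("xmin", "ymin", "xmax", "ymax"), rec.box):
            ET.SubElement(bnd, k).text = f"{v:g}"
    ET.ElementTree(root).write(path, encoding="unicode")


class FileBackedDetector:
    """Mock detector replaying ground-truth VOC XML from a directory.

    ``jitter_px`` adds seeded uniform coordinate noise to emulate an
    imperfect detector; a missing XML file means no detections for that
    frame (a dropout).
    """

    def __init__(self, xml_dir: str | Path, jitter_px: float = 0.0,
                 seed: int = 0):
        self.xml_dir = Path(xml_dir)
        self.jitter_px = float(jitter_px)
        self.seed = int(seed)

    def detect(self, frame_index: int) -> list[DetectionRecord]:
        path = self.xml_dir / f"{frame_index}.xml"
        if not path.exists():
            return []
        records = read_voc_xml(path, frame_index)
        if self.jitter_px <= 0:
            return records
        rng = np.random.default_rng([self.seed, frame_index])
        out = []
        for rec in records:
            d = rng.uniform(-self.jitter_px, self.jitter_px, size=4)
            x_min, y_min, x_max, y_max = rec.box
            box = (x_min + d[0], y_min + d[1], x_max + d[2], y_max + d[3])
            if box[2] <= box[0] or box[3] <= box[1]:
                box = rec.box
            out.append(DetectionRecord(frame_index, rec.individual_id, box,
                                       rec.confidence))
        return out


def density_report(densities: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Tabulate detection density as night_id, individual_id, density rows."""
    rows = [
        {"night_id": night, "individual_id": ind, "density": d}
        for night, per_ind in densities.items()
        for ind, d in per_ind.items()
    ]
    return pd.DataFrame(rows, columns=["night_id", "individual_id", "density"])
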