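"""Data model and readers/writers for bounding-box annotations and detections.

The bounding box is the universal geometric unit of this package: detector
output, ground-truth annotation, the overlap (IoU) computation and the aging
movement score all operate on axis-aligned rectangles in continuous image
coordinates (origin top-left, x rightward, y downward, units of pixels).

Supported interchange formats:

* Pascal VOC XML as written by ``labelImg`` (ground-truth annotations).
  VOC stores 1-based *inclusive* integer pixel coordinates; an object
  spanning pixels ``xmin..xmax`` therefore has width ``xmax - xmin + 1``.
  On read, coordinates widen to the continuous box ``[xmin - 1, xmax]`` on
  each axis; :func:`write_voc` inverts this exactly, so integer-coordinate
  round-trips are lossless.
* COCO-style detection JSON (``images``/``annotations``/``categories`` with a
  ``score`` per annotation; bbox is ``[x, y, width, height]``).
* A flat CSV detection table with columns
  ``frame_id,label,confidence,x_min,y_min,x_max,y_max``.
* YAML calibration files mapping pixels and frame indices to mm and minutes.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from lxml import etree

__all__ = [
    "Box",
    "DetectionRecord",
    "FrameRecord",
    "CalibrationConfig",
    "read_voc",
    "write_voc",
    "read_detections",
    "write_detections_csv",
    "write_detections_coco",
    "filter_confidence",
]

CSV_COLUMNS = ["frame_id", "label", "confidence", "x_min", "y_min", "x_max", "y_max"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive area.

    Coordinates are continuous pixels; ``x_min < x_max`` and
    ``y_min < y_max`` are enforced at construction.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        for v in (self.x_min, self.y_min, self.x_max, self.y_max):
            if not math.isfinite(v):
                raise ValueError(f"non-finite box coordinate: {self}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box (need x_min < x_max and y_min < y_max): "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def translated(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output: a box, a class label, and a confidence in [0, 1]."""

    box: Box
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("detection label must be nonempty")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class FrameRecord:
    """All annotations and detections attached to one image/frame.

    ``ground_truth`` holds ``(Box, label)`` pairs; ``timestamp`` is in minutes
    when known. Frames with no detections are meaningful (explicit gaps in a
    time series) and are never dropped by the readers.
    """

    frame_id: str
    image_size: tuple[int, int] | None = None  # (width, height)
    timestamp: float | None = None
    detections: list[DetectionRecord] = field(default_factory=list)
    ground_truth: list[tuple[Box, str]] = field(default_factory=list)


@dataclass(frozen=True)
class CalibrationConfig:
    """Spatial and temporal calibration of an imaging rig.

    mm_per_pixel
        Physical length of one pixel, mm. Converts centroid distances to mm.
    frame_interval
        Minutes between consecutive frames of the native acquisition.
    """

    mm_per_pixel: float
    frame_interval: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0 or self.frame_interval <= 0:
            raise ValueError("mm_per_pixel and frame_interval must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {"mm_per_pixel", "frame_interval"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown calibration keys: {sorted(extra)}")
        return cls(float(data["mm_per_pixel"]), float(data["frame_interval"]))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"mm_per_pixel": self.mm_per_pixel, "frame_interval": self.frame_interval},
                fh,
            )


# ---------------------------------------------------------------------------
# Pascal VOC XML (labelImg dialect)
# ---------------------------------------------------------------------------

def _voc_to_box(xmin: float, ymin: float, xmax: float, ymax: float) -> Box:
    # 1-based inclusive integer convention: pixel span xmin..xmax has width
    # xmax - xmin + 1, hence the continuous box [xmin - 1, xmax].
    if xmin > xmax or ymin > ymax:
        raise ValueError(f"VOC box has min > max: ({xmin}, {ymin}, {xmax}, {ymax})")
    return Box(xmin - 1.0, ymin - 1.0, float(xmax), float(ymax))


def read_voc(path: str | Path) -> FrameRecord:
    """Read a labelImg-style Pascal VOC annotation file into a FrameRecord.

    Every ``<object>`` becomes a ground-truth ``(Box, label)`` pair.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    root = tree.getroot()

    frame_id = root.findtext("filename") or path.stem
    size_el = root.find("size")
    image_size = None
    if size_el is not None:
        w = size_el.findtext("width")
        h = size_el.findtext("height")
        if w is not None and h is not None:
            image_size = (int(w), int(h))

    ground_truth: list[tuple[Box, str]] = []
    for obj in root.iterfind("object"):
        label = obj.findtext("name") or ""
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"object without bndbox in {path}")
        try:
            box = _voc_to_box(
                float(bb.findtext("xmin")),
                float(bb.findtext("ymin")),
                float(bb.findtext("xmax")),
                float(bb.findtext("ymax")),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid bndbox in {path}: {exc}") from exc
        ground_truth.append((box, label))

    return FrameRecord(frame_id=frame_id, image_size=image_size, ground_truth=ground_truth)


def write_voc(frame: FrameRecord, path: str | Path) -> None:
    """Write a FrameRecord's ground truth as labelImg-style Pascal VOC XML."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = frame.frame_id
    if frame.image_size is not None:
        size = etree.SubElement(root, "size")
        etree.SubElement(size, "width").text = str(frame.image_size[0])
        etree.SubElement(size, "height").text = str(frame.image_size[1])
        etree.SubElement(size, "depth").text = "1"
    for box, label in frame.ground_truth:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        bb = etree.SubElement(obj, "bndbox")
        # inverse of _voc_to_box; integer VOC coords survive exactly
        etree.SubElement(bb, "xmin").text = _fmt(box.x_min + 1.0)
        etree.SubElement(bb, "ymin").text = _fmt(box.y_min + 1.0)
        etree.SubElement(bb, "xmax").text = _fmt(box.x_max)
        etree.SubElement(bb, "ymax").text = _fmt(box.y_max)
    etree.ElementTree(root).write(str(path), pretty_print=True, encoding="utf-8")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Detections: COCO-style JSON and CSV
# ---------------------------------------------------------------------------

def read_detections(path: str | Path, format: str) -> list[FrameRecord]:
    """Read detector output into frame records.

    Parameters
    ----------
    format
        ``"coco_json"`` or ``"csv"``. COCO bboxes ``[x, y, w, h]`` convert to
        corner form ``[x, y, x+w, y+h]``. Frames are returned grouped by
        frame id, preserving file order; frames with zero detections are kept.
    """
    if format == "coco_json":
        return _read_coco(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown detections format: {format!r}")


def _read_coco(path: str | Path) -> list[FrameRecord]:
    with open(path) as fh:
        data = json.load(fh)
    cats = {c["id"]: c["name"] for c in data.get("categories", [])}
    frames: dict[object, FrameRecord] = {}
    for img in data["images"]:
        fr = FrameRecord(
            frame_id=str(img.get("file_name", img["id"])),
            image_size=(img["width"], img["height"]) if "width" in img else None,
            timestamp=img.get("timestamp"),
        )
        frames[img["id"]] = fr
    for ann in data.get("annotations", []):
        if ann["category_id"] not in cats:
            raise ValueError(f"unknown category id {ann['category_id']} in {path}")
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(f"non-positive bbox width/height in {path}: {ann['bbox']}")
        frames[ann["image_id"]].detections.append(
            DetectionRecord(Box(x, y, x + w, y + h), cats[ann["category_id"]], float(ann["score"]))
        )
    return list(frames.values())


def _read_csv(path: str | Path) -> list[FrameRecord]:
    frames: dict[str, FrameRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"CSV {path} missing columns: {sorted(missing)}")
        for row in reader:
            fid = row["frame_id"]
            fr = frames.setdefault(fid, FrameRecord(frame_id=fid))
            if row["label"] == "" and row["x_min"] == "":
                continue  # explicit empty-frame placeholder row
            box = Box(
                float(row["x_min"]), float(row["y_min"]),
                float(row["x_max"]), float(row["y_max"]),
            )
            fr.detections.append(DetectionRecord(box, row["label"], float(row["confidence"])))
    return list(frames.values())


def write_detections_csv(frames: Iterable[FrameRecord], path: str | Path) -> None:
    """Write detections as a flat CSV; frames without detections emit a
    placeholder row so the explicit gap survives a round-trip."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for fr in frames:
            if not fr.detections:
                writer.writerow([fr.frame_id, "", "", "", "", "", ""])
                continue
            for det in fr.detections:
                writer.writerow(
                    [fr.frame_id, det.label, repr(float(det.confidence)),
                     repr(float(det.box.x_min)), repr(float(det.box.y_min)),
                     repr(float(det.box.x_max)), repr(float(det.box.y_max))]
                )


def write_detections_coco(frames: Sequence[FrameRecord], path: str | Path) -> None:
    """Write detections as COCO-style JSON (bbox = [x, y, width, height])."""
    labels = sorted({d.label for fr in frames for d in fr.detections})
    cat_id = {lbl: i + 1 for i, lbl in enumerate(labels)}
    images, annotations = [], []
    for img_id, fr in enumerate(frames, start=1):
        entry: dict = {"id": img_id, "file_name": fr.frame_id}
        if fr.image_size is not None:
            entry["width"], entry["height"] = fr.image_size
        if fr.timestamp is not None:
            entry["timestamp"] = fr.timestamp
        images.append(entry)
        for det in fr.detections:
            annotations.append(
                {
                    "id": len(annotations) + 1,
                    "image_id": img_id,
                    "category_id": cat_id[det.label],
                    "bbox": [det.box.x_min, det.box.y_min, det.box.width, det.box.height],
                    "score": det.confidence,
                }
            )
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": lbl} for lbl, i in cat_id.items()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def filter_confidence(
    frames: Sequence[FrameRecord], label: str, threshold: float
) -> list[FrameRecord]:
    """Keep detections of ``label`` with confidence >= threshold.

    Detections of other labels pass through untouched; the operation is
    idempotent and monotone in the threshold. Frames are shallow-copied so the
    input is never mutated.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"confidence threshold {threshold} outside [0, 1]")
    out = []
    for fr in frames:
        kept = [
            d for d in fr.detections
            if d.label != label or d.confidence >= threshold
        ]
        out.append(
            FrameRecord(
                frame_id=fr.frame_id,
                image_size=fr.image_size,
                timestamp=fr.timestamp,
                detections=kept,
                ground_truth=list(fr.ground_truth),
            )
        )
    return out
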