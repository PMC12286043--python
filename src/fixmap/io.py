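"""Domain types and on-disk formats for fixation-wise AOI annotation.

Fixation tables follow the CSV dialect of Pupil-Core-style exports
(normalized gaze position with a bottom-left origin, a world-video frame
index per fixation).  Scene frames come from any :class:`FramesSource`;
annotations round-trip through a single JSON document.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FixationRecord", "AOISchema", "Annotation", "FramesSource",
    "DirectoryFrames", "ArrayFrames", "DEFAULT_DIALECT",
    "read_fixation_table", "write_fixation_table", "fixation_to_pixel",
    "extract_patch", "persist_annotations", "load_annotations",
    "SchemaError", "ValidationError",
]


class SchemaError(ValueError):
    """A file or label does not match the expected schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class FixationRecord:
    """One detected fixation, the unit being annotated."""

    fixation_id: int
    start_ts: float          # seconds
    duration_ms: float
    norm_x: float            # in [0, 1], origin bottom-left
    norm_y: float
    frame_index: int
    phase: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.norm_x <= 1.0 and 0.0 <= self.norm_y <= 1.0):
            raise ValidationError(
                f"fixation {self.fixation_id}: normalized position "
                f"({self.norm_x}, {self.norm_y}) outside [0, 1]")
        if self.duration_ms <= 0:
            raise ValidationError(f"fixation {self.fixation_id}: duration must be > 0")
        if self.frame_index < 0:
            raise ValidationError(f"fixation {self.fixation_id}: negative frame index")


@dataclass(frozen=True)
class AOISchema:
    """Ordered AOI class names plus the reserved background label."""

    aoi_names: tuple
    bg_name: str = "BG"

    def __post_init__(self):
        object.__setattr__(self, "aoi_names", tuple(self.aoi_names))
        names = self.aoi_names
        if len(names) < 2:
            raise SchemaError("need at least 2 AOI classes")
        if len(set(names)) != len(names):
            raise SchemaError("AOI names must be unique")
        if self.bg_name in names:
            raise SchemaError("background label must not be an AOI name")

    @property
    def n_classes(self) -> int:
        return len(self.aoi_names)

    @property
    def labels(self) -> tuple:
        """All labels: AOIs in schema order, background last."""
        return self.aoi_names + (self.bg_name,)

    def index(self, name: str) -> int:
        return self.aoi_names.index(name)

    def validate_label(self, label: str) -> str:
        if label not in self.labels:
            raise SchemaError(f"unknown label {label!r}")
        return label


@dataclass
class Annotation:
    fixation_id: int
    label: str
    source: str = "manual"       # manual | confirmed | corrected
    wall_time: float = 0.0       # seconds spent on this annotation

    _SOURCES = ("manual", "confirmed", "corrected")

    def __post_init__(self):
        if self.source not in self._SOURCES:
            raise ValidationError(f"unknown annotation source {self.source!r}")


class FramesSource:
    """Abstract provider mapping frame_index -> H×W×3 uint8 image.

    Implementations must be deterministic: the same index always yields
    identical pixels.
    """

    width: int
    height: int
    n_frames: int

    def get_frame(self, index: int) -> np.ndarray:
        raise NotImplementedError

    def _check_index(self, index: int) -> None:
        if not (0 <= index < self.n_frames):
            raise KeyError(f"frame index {index} outside [0, {self.n_frames})")


class DirectoryFrames(FramesSource):
    """Frames stored as ``frame_<index>.png`` in a directory."""

    def __init__(self, directory, pattern: str = "frame_{index}.png"):
        from PIL import Image

        self._dir = Path(directory)
        self._pattern = pattern
        self._Image = Image
        indices = []
        prefix, suffix = pattern.split("{index}")
        for p in self._dir.glob(pattern.format(index="*")):
            stem = p.name[len(prefix):len(p.name) - len(suffix)]
            if stem.isdigit():
                indices.append(int(stem))
        if not indices:
            raise FileNotFoundError(f"no frames matching {pattern!r} in {directory}")
        self.n_frames = max(indices) + 1
        first = self.get_frame(min(indices))
        self.height, self.width = first.shape[:2]

    def get_frame(self, index: int) -> np.ndarray:
        path = self._dir / self._pattern.format(index=index)
        if not path.exists():
            raise KeyError(f"missing frame file {path}")
        with self._Image.open(path) as im:
            return np.asarray(im.convert("RGB"))


class ArrayFrames(FramesSource):
    """In-memory frames (used by tests and the synthetic generator)."""

    def __init__(self, frames: Sequence[np.ndarray]):
        self._frames = [np.asarray(f) for f in frames]
        self.n_frames = len(self._frames)
        self.height, self.width = self._frames[0].shape[:2]

    def get_frame(self, index: int) -> np.ndarray:
        self._check_index(index)
        return self._frames[index]


#: standard column names of a Pupil-Core-like fixation export
DEFAULT_DIALECT: Mapping[str, str] = {
    "fixation_id": "id",
    "start_ts": "start_timestamp",
    "duration_ms": "duration",
    "norm_x": "norm_pos_x",
    "norm_y": "norm_pos_y",
    "frame_index": "world_index",
    "phase": "phase",            # optional
}


def read_fixation_table(path, dialect: Mapping[str, str] | None = None) -> list:
    """Read a fixation CSV into validated :class:`FixationRecord` objects.

    Records are returned sorted by start timestamp.  Rows violating an
    invariant raise :class:`ValidationError` naming the offending row.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    # round_trip float parsing so write -> read preserves values exactly
    df = pd.read_csv(path, float_precision="round_trip")
    mandatory = ["fixation_id", "start_ts", "duration_ms", "norm_x", "norm_y", "frame_index"]
    for key in mandatory:
        if cols[key] not in df.columns:
            raise SchemaError(f"missing mandatory column {cols[key]!r}")
    has_phase = cols["phase"] in df.columns
    records = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            records.append(FixationRecord(
                fixation_id=int(row[cols["fixation_id"]]),
                start_ts=float(row[cols["start_ts"]]),
                duration_ms=float(row[cols["duration_ms"]]),
                norm_x=float(row[cols["norm_x"]]),
                norm_y=float(row[cols["norm_y"]]),
                frame_index=int(row[cols["frame_index"]]),
                phase=str(row[cols["phase"]]) if has_phase else None,
            ))
        except ValidationError as e:
            raise ValidationError(f"row {row_no}: {e}") from None
    ids = [r.fixation_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate fixation ids")
    records.sort(key=lambda r: r.start_ts)
    return records


def write_fixation_table(records: Sequence[FixationRecord], path,
                         dialect: Mapping[str, str] | None = None) -> None:
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = {
        cols["fixation_id"]: [r.fixation_id for r in records],
        # floats go through repr for exact round-trip through the CSV
        cols["start_ts"]: [repr(float(r.start_ts)) for r in records],
        cols["duration_ms"]: [repr(float(r.duration_ms)) for r in records],
        cols["norm_x"]: [repr(float(r.norm_x)) for r in records],
        cols["norm_y"]: [repr(float(r.norm_y)) for r in records],
        cols["frame_index"]: [r.frame_index for r in records],
    }
    if any(r.phase is not None for r in records):
        rows[cols["phase"]] = [r.phase for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fixation_to_pixel(f: FixationRecord, width: int, height: int,
                      y_origin: str = "bottom") -> tuple:
    """Map a normalized gaze position to pixel coordinates.

    The default bottom-left origin (y up) matches Pupil exports, so
    ``y_px = round((1 - norm_y) * (height - 1))``; pass ``y_origin="top"``
    for image-style coordinates.
    """
    if width < 1 or height < 1:
        raise ValueError("frame dimensions must be >= 1")
    x = f.norm_x * (width - 1)
    y = ((1.0 - f.norm_y) if y_origin == "bottom" else f.norm_y) * (height - 1)
    return _round_half_away(x), _round_half_away(y)


def extract_patch(frames: FramesSource, f: FixationRecord, size: int = 64,
                  y_origin: str = "bottom") -> np.ndarray:
    """Crop a ``size``×``size`` patch centered at the fixation pixel.

    Regions outside the frame are filled by edge replication so that the
    output shape never depends on the fixation position.
    """
    if size < 8 or size % 2:
        raise ValueError("patch size must be even and >= 8")
    frame = frames.get_frame(f.frame_index)
    x, y = fixation_to_pixel(f, frames.width, frames.height, y_origin=y_origin)
    half = size // 2
    pad = ((size, size), (size, size)) + ((0, 0),) * (frame.ndim - 2)
    padded = np.pad(frame, pad, mode="edge")
    ys, xs = y + size - half, x + size - half
    return padded[ys:ys + size, xs:xs + size]


def persist_annotations(store: Sequence[Annotation], schema: AOISchema, path) -> None:
    """Write annotations with their schema as a single JSON document."""
    doc = {
        "schema": {"aoi_names": list(schema.aoi_names), "bg_name": schema.bg_name},
        "annotations": [asdict(a) for a in store],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_annotations(path) -> tuple:
    """Load annotations; returns ``(annotations, schema)``.

    Labels not in the stored schema raise :class:`SchemaError`.
    """
    doc = json.loads(Path(path).read_text())
    schema = AOISchema(tuple(doc["schema"]["aoi_names"]), doc["schema"]["bg_name"])
    annotations = []
    for rec in doc["annotations"]:
        schema.validate_label(rec["label"])
        annotations.append(Annotation(**rec))
    return annotations, schema
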