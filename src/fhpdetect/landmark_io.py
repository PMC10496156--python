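"""Reading and writing 2-D pose-landmark files.

Two on-disk dialects are supported:

* pose-estimator JSON in the common ``{"people": [{"pose_keypoints_2d":
  [x0, y0, c0, x1, y1, c1, ...]}]}`` shape, in the 18-keypoint layout
  (COCO order).  Files in the 25-keypoint layout are mapped onto the
  18-point layout by index table at read time.  A (0, 0, 0) triplet means
  the detector did not find that keypoint; such points are recorded as
  missing.
* flat CSV landmark tables with ``subject_id``, ``kp{i}_x``, ``kp{i}_y``,
  ``kp{i}_c`` columns plus demographic columns, one subject per row.

The four anatomical feature points are resolved from the raw keypoints by
:func:`extract_anatomical_points`: shoulder ← keypoint 2, nose ← 0,
eye ← 14, ear ← 16, each required to reach a confidence threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .errors import FormatError, IncompleteLandmarksError, SchemaError
from .features import AnatomicalPoints

#: 18-keypoint layout (COCO order).
KEYPOINT_NAMES = [
    "nose", "neck", "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist", "right_hip", "right_knee",
    "right_ankle", "left_hip", "left_knee", "left_ankle", "right_eye",
    "left_eye", "right_ear", "left_ear",
]
N_KEYPOINTS = 18

#: index of each 18-layout keypoint inside a 25-keypoint (BODY_25) array
_BODY25_TO_18 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18]

#: keypoint index of each anatomical feature point
ANATOMICAL_KEYPOINTS = {"RAP": 2, "NP": 0, "RPCP": 14, "REAMP": 16}

DEFAULT_CONF_MIN = 0.3

DEMOGRAPHIC_COLUMNS = ["gender", "age", "height", "weight", "bmi", "label"]


@dataclass(frozen=True)
class Keypoint:
    index: int
    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self):
        if not 0 <= self.index < N_KEYPOINTS:
            raise ValueError(f"keypoint index {self.index} outside [0, 17]")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.confidence > 0 and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("detected keypoint has non-finite coordinates")


@dataclass
class PoseRecord:
    """One subject's detected keypoints; absent indices mean missing points."""

    subject_id: str
    keypoints: Dict[int, Keypoint] = field(default_factory=dict)
    image_width: Optional[int] = None
    image_height: Optional[int] = None
    view: str = "right_side"

    def __post_init__(self):
        if self.image_width is not None and self.image_height is not None:
            for kp in self.keypoints.values():
                if not (0 <= kp.x <= self.image_width and 0 <= kp.y <= self.image_height):
                    raise ValueError(
                        f"keypoint {kp.index} at ({kp.x}, {kp.y}) outside "
                        f"{self.image_width}x{self.image_height} image"
                    )


@dataclass
class SubjectMeta:
    gender: Optional[str] = None     # "female" | "male"
    age: Optional[float] = None      # years
    height: Optional[float] = None   # cm
    weight: Optional[float] = None   # kg
    bmi: Optional[float] = None      # kg/m^2
    label: Optional[str] = None      # "FHP" | "normal" | None (prediction mode)

    def __post_init__(self):
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if None not in (self.bmi, self.height, self.weight):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with height/weight (implies {implied:.2f})"
                )


def _triplets_to_keypoints(flat: List[float]) -> Dict[int, Keypoint]:
    if len(flat) % 3 != 0:
        raise FormatError(f"keypoint array length {len(flat)} is not a multiple of 3")
    n = len(flat) // 3
    if n == N_KEYPOINTS:
        index_map = list(range(N_KEYPOINTS))
    elif n == 25:
        index_map = _BODY25_TO_18
    else:
        raise FormatError(f"unsupported keypoint count {n} (expected 18 or 25)")
    kps: Dict[int, Keypoint] = {}
    for out_idx, src_idx in enumerate(index_map):
        x, y, c = flat[3 * src_idx : 3 * src_idx + 3]
        if c <= 0:
            continue  # zero-confidence convention: missing
        kps[out_idx] = Keypoint(out_idx, KEYPOINT_NAMES[out_idx], float(x), float(y), float(c))
    return kps


def read_openpose_json(path) -> List[PoseRecord]:
    """Parse a pose-estimator JSON file into one record per detected person.

    Person order in the file is preserved; subject ids come from a
    ``subject_id`` field on each person when present, else
    ``<stem>_p<index>``.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "people" not in doc:
        raise FormatError(f"{path}: missing 'people' array")
    width = doc.get("image_width")
    height = doc.get("image_height")
    from pathlib import Path

    stem = Path(path).stem
    records = []
    for i, person in enumerate(doc["people"]):
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise FormatError(f"{path}: person {i} lacks 'pose_keypoints_2d'")
        records.append(
            PoseRecord(
                subject_id=str(person.get("subject_id", f"{stem}_p{i}")),
                keypoints=_triplets_to_keypoints(list(flat)),
                image_width=width,
                image_height=height,
                view=doc.get("view", "right_side"),
            )
        )
    return records


def write_openpose_json(records: List[PoseRecord], path, *, image_width=None, image_height=None) -> None:
    """Inverse of :func:`read_openpose_json` (18-keypoint dialect only)."""
    people = []
    for rec in records:
        flat: List[float] = []
        for i in range(N_KEYPOINTS):
            kp = rec.keypoints.get(i)
            flat.extend([kp.x, kp.y, kp.confidence] if kp else [0.0, 0.0, 0.0])
        people.append({"subject_id": rec.subject_id, "pose_keypoints_2d": flat})
    doc: dict = {"people": people}
    w = image_width if image_width is not None else (records[0].image_width if records else None)
    h = image_height if image_height is not None else (records[0].image_height if records else None)
    if w is not None:
        doc["image_width"] = w
    if h is not None:
        doc["image_height"] = h
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _kp_columns() -> List[str]:
    cols = []
    for i in range(N_KEYPOINTS):
        cols += [f"kp{i}_x", f"kp{i}_y", f"kp{i}_c"]
    return cols


def read_landmark_table(path) -> List[Tuple[PoseRecord, SubjectMeta]]:
    """Read a flat CSV of landmarks + demographics, one subject per row.

    Empty keypoint cells denote missing points.  Demographic columns are
    optional individually but the ``subject_id`` column is mandatory.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError("landmark table lacks mandatory 'subject_id' column")
    out = []
    for _, row in df.iterrows():
        kps: Dict[int, Keypoint] = {}
        for i in range(N_KEYPOINTS):
            cols = (f"kp{i}_x", f"kp{i}_y", f"kp{i}_c")
            if not all(c in df.columns for c in cols):
                continue
            x, y, c = (row[col] for col in cols)
            if pd.isna(x) or pd.isna(y) or pd.isna(c) or c <= 0:
                continue
            kps[i] = Keypoint(i, KEYPOINT_NAMES[i], float(x), float(y), float(c))
        meta = SubjectMeta(
            gender=None if pd.isna(row.get("gender")) else str(row["gender"]),
            age=None if pd.isna(row.get("age")) else float(row["age"]),
            height=None if pd.isna(row.get("height")) else float(row["height"]),
            weight=None if pd.isna(row.get("weight")) else float(row["weight"]),
            bmi=None if pd.isna(row.get("bmi")) else float(row["bmi"]),
            label=None if pd.isna(row.get("label")) else str(row["label"]),
        )
        out.append((PoseRecord(subject_id=str(row["subject_id"]), keypoints=kps), meta))
    return out


def write_landmark_table(pairs: List[Tuple[PoseRecord, SubjectMeta]], path) -> None:
    """Inverse of :func:`read_landmark_table`; deterministic column order."""
    rows = []
    for rec, meta in pairs:
        row: dict = {"subject_id": rec.subject_id}
        for i in range(N_KEYPOINTS):
            kp = rec.keypoints.get(i)
            row[f"kp{i}_x"] = kp.x if kp else None
            row[f"kp{i}_y"] = kp.y if kp else None
            row[f"kp{i}_c"] = kp.confidence if kp else None
        for col in DEMOGRAPHIC_COLUMNS:
            row[col] = getattr(meta, col)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id"] + _kp_columns() + DEMOGRAPHIC_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def extract_anatomical_points(record: PoseRecord, conf_min: float = DEFAULT_CONF_MIN) -> AnatomicalPoints:
    """Resolve the four feature vertices from raw keypoints.

    A pure projection: output coordinates equal the input keypoint
    coordinates.  Raises :class:`IncompleteLandmarksError` naming every
    point that is missing or below ``conf_min``.
    """
    coords = {}
    missing = []
    for name, idx in ANATOMICAL_KEYPOINTS.items():
        kp = record.keypoints.get(idx)
        if kp is None or kp.confidence < conf_min:
            missing.append(name)
        else:
            coords[name] = (kp.x, kp.y)
    if missing:
        raise IncompleteLandmarksError(missing, subject_id=record.subject_id)
    return AnatomicalPoints(**coords)
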