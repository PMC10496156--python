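"""Posture-angle geometry.

Forward head posture shows up in a lateral photograph as a reduced
inclination of the head landmarks above the shoulder.  With the right
acromion (shoulder) point as the vertex, four angles and three vertical
distances summarise the head--shoulder configuration:

* ``NAH`` -- angle between the shoulder→nose segment and the horizontal
  line through the shoulder;
* ``PAH`` -- same, for the shoulder→eye (pupil) segment;
* ``EAH`` -- same, for the shoulder→ear (external auditory meatus) segment;
* ``ENA`` -- angle at the shoulder between the ear and nose segments;
* ``d1``/``d2``/``d3`` -- unsigned vertical (image-row) distances of nose,
  eye and ear above the shoulder row.

All angles are computed from side lengths with the law of cosines and are
unsigned: the three horizontal angles lie in [0, 90] degrees, ``ENA`` in
[0, 180].  Image coordinates follow the image convention (origin top-left,
y increasing downward); because only unsigned differences enter, results
are invariant to translation and to mirroring in x, and the distances
scale linearly with image scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidTriangleError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .landmark_io import SubjectMeta

Point = Tuple[float, float]

#: Canonical column order of a feature table.
FEATURE_COLUMNS = [
    "NAH", "ENA", "PAH", "EAH", "d1", "d2", "d3",
    "gender", "age", "height", "weight", "bmi",
]
ANGLE_FEATURES = ["NAH", "ENA", "PAH", "EAH"]
TABLE_COLUMNS = ["subject_id"] + FEATURE_COLUMNS + ["label"]

#: Gender encoding used throughout (configurable at call sites).
GENDER_CODES = {"female": 0, "male": 1}

#: Tolerance absorbing floating-point overshoot on collinear triples.
COS_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class AnatomicalPoints:
    """The four feature vertices, in pixels.

    ``RAP`` right acromion (shoulder, the angle vertex), ``NP`` nasal point,
    ``RPCP`` right pupil centre (eye keypoint), ``REAMP`` right external
    auditory meatus (ear keypoint).
    """

    RAP: Point
    NP: Point
    RPCP: Point
    REAMP: Point

    def __post_init__(self):
        for name in ("RAP", "NP", "RPCP", "REAMP"):
            x, y = getattr(self, name)
            if not (math.isfinite(x) and math.isfinite(y)):
                raise DegenerateGeometryError(f"{name} has non-finite coordinates")


@dataclass
class FeatureVector:
    """One subject's 12-feature row (7 geometric + 5 demographic)."""

    NAH: float
    ENA: float
    PAH: float
    EAH: float
    d1: float
    d2: float
    d3: float
    gender: Optional[int] = None
    age: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    label: Optional[int] = None
    subject_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            **{k: getattr(self, k) for k in FEATURE_COLUMNS},
            "label": self.label,
        }


def law_of_cosines_angle(a: float, b: float, c: float, *, tol: float = 1e-9) -> float:
    """Angle A (degrees) opposite side ``a`` in a triangle with sides a, b, c.

    ``cos A = (b² + c² − a²) / (2bc)``.  The value is evaluated through the
    algebraically identical half-angle form
    ``tan(A/2) = sqrt((a² − (b−c)²) / ((b+c)² − a²))``,
    which stays well-conditioned for needle-like (near-collinear) triangles
    where arccos of the raw cosine loses several digits; negative radicands
    from round-off are clamped to zero (the analogue of clamping the cosine
    to [−1, 1]).  Raises :class:`DegenerateGeometryError` if ``b`` or ``c``
    is zero and :class:`InvalidTriangleError` if the sides violate the
    triangle inequality beyond a relative tolerance.
    """
    if b <= 0 or c <= 0:
        raise DegenerateGeometryError(
            f"triangle sides adjacent to the angle must be positive (b={b}, c={c})"
        )
    if a < 0:
        raise InvalidTriangleError(f"negative side length a={a}")
    slack = tol * max(a, b, c, 1.0)
    if a > b + c + slack or b > a + c + slack or c > a + b + slack:
        raise InvalidTriangleError(
            f"sides (a={a}, b={b}, c={c}) violate the triangle inequality"
        )
    num = max(0.0, (a + (b - c)) * (a - (b - c)))   # a² − (b−c)²
    den = max(0.0, ((b + c) + a) * ((b + c) - a))   # (b+c)² − a²
    return math.degrees(2.0 * math.atan2(math.sqrt(num), math.sqrt(den)))


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _vertex_angle(v: Point, p: Point, q: Point) -> float:
    """Angle at ``v`` between segments v→p and v→q, degrees in [0, 180].

    This is the law-of-cosines angle of the triangle (v, p, q): with
    b = |p−v|, c = |q−v|, a = |p−q| the identity
    ``b² + c² − a² = 2 (p−v)·(q−v)`` holds exactly, so the cosine-rule
    angle equals atan2(|(p−v) × (q−v)|, (p−v)·(q−v)).  Evaluating it this
    way avoids the precision loss of forming rounded side lengths first
    (several digits in near-collinear configurations).
    """
    ux, uy = p[0] - v[0], p[1] - v[1]
    wx, wy = q[0] - v[0], q[1] - v[1]
    if (ux == 0 and uy == 0) or (wx == 0 and wy == 0):
        raise DegenerateGeometryError("point coincides with the vertex")
    return math.degrees(math.atan2(abs(ux * wy - uy * wx), ux * wx + uy * wy))


def horizontal_angle(vertex: Point, p: Point) -> float:
    """Unsigned angle in [0, 90] degrees between segment vertex→p and the
    horizontal line through ``vertex``.

    The cosine-rule angle of the right triangle (vertex, p, H), with H the
    foot of the perpendicular from ``p`` onto the horizontal through
    ``vertex``; 90° when the segment is vertical.
    """
    if p == vertex:
        raise DegenerateGeometryError("point coincides with the vertex")
    if p[0] == vertex[0]:
        return 90.0
    return _vertex_angle(vertex, p, (p[0], vertex[1]))


def ena_angle(points: AnatomicalPoints) -> float:
    """Angle at the shoulder between the shoulder→ear and shoulder→nose
    segments, in [0, 180] degrees."""
    rap, np_, reamp = points.RAP, points.NP, points.REAMP
    if np_ == rap or reamp == rap:
        raise DegenerateGeometryError("NP or REAMP coincides with RAP")
    return _vertex_angle(rap, np_, reamp)


def vertical_distance(vertex: Point, p: Point) -> float:
    """Unsigned image-row distance |p.y − vertex.y| in pixels."""
    return abs(p[1] - vertex[1])


def compute_features(
    points: AnatomicalPoints,
    meta: "SubjectMeta | None" = None,
    *,
    subject_id: Optional[str] = None,
    gender_codes: dict = GENDER_CODES,
) -> FeatureVector:
    """Assemble the full feature vector from the four anatomical points plus
    optional demographics.

    BMI is recomputed from height/weight when absent.  Degenerate geometry
    raises with the offending feature named.
    """
    named = {}
    for feat, fn in (
        ("NAH", lambda: horizontal_angle(points.RAP, points.NP)),
        ("PAH", lambda: horizontal_angle(points.RAP, points.RPCP)),
        ("EAH", lambda: horizontal_angle(points.RAP, points.REAMP)),
        ("ENA", lambda: ena_angle(points)),
    ):
        try:
            named[feat] = fn()
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"{feat}: {exc}") from exc

    fv = FeatureVector(
        NAH=named["NAH"], ENA=named["ENA"], PAH=named["PAH"], EAH=named["EAH"],
        d1=vertical_distance(points.RAP, points.NP),
        d2=vertical_distance(points.RAP, points.RPCP),
        d3=vertical_distance(points.RAP, points.REAMP),
        subject_id=subject_id,
    )
    if meta is not None:
        fv.gender = gender_codes.get(meta.gender) if meta.gender is not None else None
        fv.age = meta.age
        fv.height = meta.height
        fv.weight = meta.weight
        fv.bmi = meta.bmi
        if fv.bmi is None and meta.height and meta.weight:
            fv.bmi = meta.weight / (meta.height / 100.0) ** 2
        if meta.label is not None:
            fv.label = 1 if str(meta.label).upper() in ("1", "FHP") else 0
    return fv


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table with the canonical column order."""
    rows = [fv.as_dict() for fv in vectors]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    df.to_csv(path, index=False, columns=TABLE_COLUMNS, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    return df
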