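"""Exception hierarchy shared across the package."""


class FHPError(Exception):
    """Base class for all package errors."""


class FormatError(FHPError):
    """A landmark file is structurally malformed (bad JSON, wrong array length)."""


class SchemaError(FHPError):
    """A table is missing mandatory columns or has incompatible columns."""


class IncompleteLandmarksError(FHPError):
    """One of the four anatomical feature points is missing or below the
    confidence threshold. ``missing`` names the offending point(s)."""

    def __init__(self, missing, subject_id=None):
        self.missing = list(missing)
        self.subject_id = subject_id
        where = f" for subject {subject_id!r}" if subject_id else ""
        super().__init__(
            f"anatomical point(s) {', '.join(self.missing)} missing or below "
            f"confidence threshold{where}"
        )


class DegenerateGeometryError(FHPError):
    """Coincident points or a zero-length triangle side make an angle undefined."""


class InvalidTriangleError(FHPError):
    """Side lengths violate the triangle inequality beyond tolerance."""


class DegenerateLabelsError(FHPError):
    """Training labels contain a single class where two are required."""


class EmptySubsetError(FHPError):
    """A feature mask with no bits set was submitted for evaluation."""
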