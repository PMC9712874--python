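"""Exception hierarchy shared across the package."""


class DcmForgeError(Exception):
    """Base class for all package-specific errors."""


class CodingError(DcmForgeError, ValueError):
    """Invalid coded-concept field content."""


class RegistryLookupError(DcmForgeError, LookupError):
    """Keyword not found in a code registry."""

    def __init__(self, registry: str, keyword: str):
        self.registry = registry
        self.keyword = keyword
        super().__init__(
            f"no concept with keyword {keyword!r} in registry {registry!r}"
        )


class ContextConsistencyError(DcmForgeError, ValueError):
    """Source datasets disagree on patient or study identity."""


class GeometryError(DcmForgeError, ValueError):
    """Invalid plane geometry (non-unit or non-orthogonal direction cosines)."""


class OutOfPlaneError(GeometryError):
    """A 3D point lies further from the image plane than the tolerance."""

    def __init__(self, distance_mm: float, tolerance_mm: float):
        self.distance_mm = distance_mm
        self.tolerance_mm = tolerance_mm
        super().__init__(
            f"point lies {distance_mm:.6g} mm from the image plane "
            f"(tolerance {tolerance_mm:.6g} mm)"
        )


class FramingError(DcmForgeError, ValueError):
    """Packed pixel-data byte stream has an impossible length."""


class SegmentOverlapError(DcmForgeError, ValueError):
    """Segments overlap where a single-label combination was requested."""


class StructureError(DcmForgeError, ValueError):
    """SR document tree does not follow the expected template structure."""


class VertexCountError(DcmForgeError, ValueError):
    """A graphic has the wrong number of vertices for its graphic type."""


class ValidationFailure(DcmForgeError, ValueError):
    """A built object failed constructor-time IOD validation."""

    def __init__(self, report):
        self.report = report
        lines = "; ".join(str(v) for v in report.errors)
        super().__init__(f"IOD validation failed: {lines}")
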