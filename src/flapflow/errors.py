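"""Exception hierarchy for flapflow."""


class FlapFlowError(Exception):
    """Base class for all flapflow errors."""


class ParameterError(FlapFlowError, ValueError):
    """Invalid kinetic or analysis parameter (non-positive time-to-peak, etc.)."""


class MetadataError(FlapFlowError):
    """Frame-stack sidecar metadata missing or inconsistent with the pixel data."""


class FormatError(FlapFlowError):
    """Raster stack is malformed (e.g. pages of different shapes)."""


class QualityCriteriaError(FlapFlowError):
    """Recording fails the inclusion criteria (e.g. shorter than the standard cut)."""


class GeometryError(FlapFlowError, ValueError):
    """Invalid flap geometry (empty mask, perforator on the midline, ...)."""


class DegenerateRiseError(FlapFlowError):
    """Fluorescence peaks at (or before) onset; a rise rate is undefined."""


class SchemaError(FlapFlowError):
    """Cohort table is missing mandatory columns or has unparseable levels."""
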