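"""Exception hierarchy for the berry3d pipeline.

Every hard failure in the measurement chain raises a subclass of
:class:`Berry3DError` carrying a short machine-readable ``code``.  The batch
driver maps these codes onto error rows so one bad reconstruction never
aborts a whole harvest's worth of clouds.
"""


class Berry3DError(Exception):
    """Base class for all berry3d pipeline failures."""

    code = "PIPELINE"


class PlyReadError(Berry3DError):
    """The PLY file could not be parsed or lacks required vertex properties."""

    code = "IO_PARSE"


class PlyWriteError(Berry3DError):
    code = "IO_WRITE"


class EmptyCloudError(Berry3DError):
    """Too few points survive a filtering stage (denoising, banding)."""

    code = "EMPTY_AFTER_FILTER"


class SegmentationError(Berry3DError):
    """Body or holder segment missing / below the minimum point count."""

    code = "SEGMENT_EMPTY"


class DegenerateGeometryError(Berry3DError):
    """A geometric primitive collapsed (zero extent, collinear slice, ...)."""

    code = "DEGENERATE"


class ScaleError(Berry3DError):
    """Holder z-extent too small to derive the unit-to-millimetre scale."""

    code = "SCALE_DEGENERATE"
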