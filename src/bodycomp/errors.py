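"""Exception hierarchy shared by all pipelines."""


class BodyCompError(Exception):
    """Base class for all package errors."""


class FormatError(BodyCompError):
    """An input file could not be parsed."""


class MetadataError(BodyCompError):
    """Required image metadata (e.g. pixel spacing) is missing."""


class SegmentationError(BodyCompError):
    """A segmentation stage produced an empty or unusable result.

    Parameters
    ----------
    message : str
    stage : str, optional
        Name of the pipeline stage that failed (e.g. ``"seed"``, ``"final"``).
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message if stage is None else f"[{stage}] {message}")
        self.stage = stage


class GeometryError(BodyCompError):
    """A user-supplied polyline/contour is geometrically invalid."""


class FitError(BodyCompError):
    """A numeric fit failed to converge."""
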