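"""Exception hierarchy.

All errors raised on bad user input derive from :class:`FacemetryError`
so callers can catch one base class; the subclasses mirror the distinct
failure modes of the pipeline (bad arguments, degenerate geometry,
missing landmarks, unreadable files).
"""


class FacemetryError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FacemetryError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(FacemetryError, ValueError):
    """Geometrically degenerate input (collinear/coincident points, ...)."""


class MissingLandmarkError(FacemetryError, KeyError):
    """A required named landmark is absent from a landmark set."""

    def __init__(self, name: str):
        self.landmark = name
        super().__init__(f"required landmark {name!r} is missing")


class UnsupportedFormatError(FacemetryError, ValueError):
    """File extension is not one of the supported on-disk formats."""


class ParseError(FacemetryError, ValueError):
    """A file exists but its contents could not be parsed."""
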