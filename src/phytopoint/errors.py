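"""Exception hierarchy.

Every failure mode surfaced to users derives from :class:`PhytopointError`
so pipelines can distinguish stage failures (``stage`` attribute on
:class:`StageError`) from programming errors.
"""


class PhytopointError(Exception):
    """Base class for all package errors."""


class EmptyInputError(PhytopointError):
    """An operation received an empty cloud/mesh/profile."""


class ParseError(PhytopointError):
    """A file could not be parsed; the message names the offending line."""


class ParameterError(PhytopointError):
    """A configuration or parameter value is out of its valid range."""


class DegenerateGeometryError(PhytopointError):
    """Input geometry is too degenerate for the requested operation."""


class NoBladeBaseError(PhytopointError):
    """The width-jump trigger never fired: no petiole/blade junction found."""


class RegistrationError(PhytopointError):
    """ICP could not run (e.g. fewer than 6 usable correspondences)."""


class StageError(PhytopointError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
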