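"""Exception hierarchy.

Every error raised by this package derives from :class:`QuartersiteError`,
so callers can catch one type at a pipeline boundary.
"""


class QuartersiteError(Exception):
    """Base class for all package errors."""


class SequenceError(QuartersiteError):
    """Invalid response-element sequence (length or alphabet)."""


class LabelError(QuartersiteError):
    """Unknown or out-of-range quarter-site position label."""


class FormatError(QuartersiteError):
    """Malformed multi-model coordinate file."""


class MappingError(QuartersiteError):
    """A selection or mapping entry resolved to no atoms."""


class RegistrationError(QuartersiteError):
    """Response-element sequence disagrees with the DNA topology."""


class WindowError(QuartersiteError):
    """Frame window resolved to an empty or out-of-bounds range."""


class SuperpositionError(QuartersiteError):
    """Too few or degenerate atoms for least-squares superposition."""
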