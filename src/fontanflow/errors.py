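"""Exception hierarchy.

Every error raised by the package derives from :class:`FontanFlowError` so
callers can catch pipeline failures with a single except clause while still
distinguishing geometry problems from format or numeric ones.
"""


class FontanFlowError(Exception):
    """Base class for all package errors."""


class GeometryError(FontanFlowError):
    """Grid metadata mismatch, plane missing the lumen, or empty lumen."""


class FormatError(FontanFlowError):
    """Malformed or incomplete on-disk input."""


class DomainError(FontanFlowError):
    """Empty voxel selection or missing segmentation region."""


class InputError(FontanFlowError):
    """Invalid argument values (empty point set, seed outside mask, ...)."""


class SpecError(FontanFlowError):
    """Invalid phantom specification (unbalanced flows, unresolvable lumen)."""


class DegenerateInputError(FontanFlowError):
    """Statistics requested on degenerate data (e.g. zero-variance regressor)."""
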