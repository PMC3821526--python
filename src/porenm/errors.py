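"""Exception hierarchy.

Every error carries an ``exit_code`` so the CLI can map failure classes to
distinct process exit codes (0 success, 2 parse/format, 3 specification or
parameter, 4 numerical/disconnection).
"""


class PorenmError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(PorenmError):
    """A file could not be read, written, or parsed."""

    exit_code = 2


class EmptyStructureError(FormatError):
    """A structure selection produced no atoms."""

    exit_code = 2


class ParameterError(PorenmError):
    """A parameter value is out of its valid domain."""

    exit_code = 3


class SpecificationError(PorenmError):
    """A bridge/edit specification does not resolve against the data."""

    exit_code = 3


class ResidueLookupError(SpecificationError):
    """A named residue or atom is absent from the structure."""

    exit_code = 3


class ComparisonError(PorenmError):
    """Two mode sets cannot be compared (mismatched node spaces)."""

    exit_code = 3


class DisconnectedNetworkError(PorenmError):
    """The spring network has more than six near-zero modes."""

    exit_code = 4
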