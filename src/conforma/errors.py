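"""Exception hierarchy shared across conforma modules."""


class ConformaError(Exception):
    """Base class for all conforma-specific errors."""


class PDBParseError(ConformaError):
    """A structure file line could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TopologyError(ConformaError):
    """Frames of one ensemble do not share an identical atom layout."""


class AtomTypingError(ConformaError):
    """An atom could not be assigned a scoring atom type."""


class ValidationError(ConformaError):
    """A domain object violates one of its invariants."""


class EmptyPotentialError(ConformaError):
    """No contact observation fell inside the requested distance binning."""


class PotentialFormatError(ConformaError):
    """A serialized potential is corrupt or of an unsupported version."""


class SelectionError(ConformaError):
    """An atom/residue selection is empty or cannot be resolved."""


class ConfigError(ConformaError):
    """Inconsistent or malformed analysis configuration."""


class ConstructionError(ConformaError):
    """A synthetic-geometry request is infeasible."""
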