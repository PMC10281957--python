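"""Exception hierarchy shared by all verbs."""


class CytoError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(CytoError):
    """File is not an FCS 3.0/3.1 file (or uses an unsupported dialect)."""


class UnsupportedModeError(CytoError):
    """FCS $MODE other than list mode ("L")."""


class CorruptFileError(CytoError):
    """FCS keywords and DATA segment disagree (truncation, bad offsets)."""


class MissingPanelError(CytoError):
    """Operation requires a Panel attribute but none is attached."""


class ChannelMismatchError(CytoError):
    """Tables to be bound do not share an identical channel set."""


class MissingColumnError(CytoError):
    """A named column does not exist on the table."""


class ChannelClassError(CytoError):
    """A technical-class or annotation column used where a marker is required."""


class AmbiguousJoinError(CytoError):
    """Sample metadata holds duplicate sample_id keys."""


class ParameterError(CytoError):
    """A parameter value violates its contract."""


class EmptyInputError(CytoError):
    """Input file or table holds no cells."""


class TooFewCellsError(CytoError):
    """A group is too small for the requested operation."""


class MissingReferenceError(CytoError):
    """A sample lacks the basal condition needed as comparison reference."""


class InsufficientReplicatesError(CytoError):
    """A test group has fewer samples than the test requires."""


class EmptyResultError(CytoError):
    """No testable units survive the missingness filter."""


class DegenerateDataError(CytoError):
    """Input carries no usable variation (e.g. all-constant matrix)."""


class ConfigError(CytoError):
    """Pipeline configuration fails schema or stage-order validation."""
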