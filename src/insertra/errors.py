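"""Exception hierarchy; each pipeline stage maps one class to one exit code."""


class InsertraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(InsertraError):
    """Invalid argument value or range."""

    exit_code = 2


class ConfigError(InsertraError):
    """Invalid or unknown configuration keys/values."""

    exit_code = 3


class LayoutError(InsertraError):
    """Overlapping or impossible genome placements."""

    exit_code = 4


class MotifError(InsertraError):
    """A required sequence motif is absent at the requested site."""

    exit_code = 5


class BoundsError(InsertraError):
    """Interval outside the reference sequence."""

    exit_code = 6


class FormatError(InsertraError):
    """Malformed input file (SAM/FASTA/...)."""

    exit_code = 7


class EvidenceError(InsertraError):
    """Not enough supporting reads/contigs to proceed."""

    exit_code = 8


class PrimerError(InsertraError):
    """Primer absent from, or not unique on, the template fragment."""

    exit_code = 9


class AssayFailureError(InsertraError):
    """The emulated assay cannot produce a product (e.g. amplicon too long)."""

    exit_code = 10


class DataError(InsertraError):
    """Degenerate data (e.g. zero reference depth)."""

    exit_code = 11
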