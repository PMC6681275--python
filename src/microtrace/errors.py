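"""Exception hierarchy shared across the package."""


class MicrotraceError(Exception):
    """Base class for package-specific errors."""


class FormatError(MicrotraceError, ValueError):
    """Malformed input file (FASTA/GFF3/alignment/table)."""


class CoordinateError(MicrotraceError, ValueError):
    """Feature coordinates fall outside the sequence they refer to."""


class InvariantError(MicrotraceError, ValueError):
    """A domain object violates one of its structural invariants."""


class GenerationError(MicrotraceError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
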