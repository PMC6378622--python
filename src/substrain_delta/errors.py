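"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage/configuration errors exit 2,
format errors exit 3, integrity / reference-mismatch errors exit 4.
"""


class SubstrainDeltaError(Exception):
    """Base class for all package errors."""


class UsageError(SubstrainDeltaError):
    """Caller misuse: bad arguments, missing inputs, inconsistent labels."""

    exit_code = 2


class ConfigurationError(SubstrainDeltaError):
    """A configuration that cannot be satisfied (e.g. infeasible placement)."""

    exit_code = 2


class FormatError(SubstrainDeltaError):
    """Malformed external file (VCF/GFF3/BED/GMT/FASTA/motif text)."""

    exit_code = 3


class EmptyInputError(FormatError):
    """A file parsed cleanly but yielded zero usable records."""

    exit_code = 3


class IntegrityError(SubstrainDeltaError):
    """Internal contract violated (unsorted input, duplicate keys, ...)."""

    exit_code = 4


class ReferenceMismatchError(IntegrityError):
    """A variant's REF allele does not match the genome sequence."""

    exit_code = 4


class AnnotationMismatchError(IntegrityError):
    """A variant references a chromosome absent from the annotation."""

    exit_code = 4
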