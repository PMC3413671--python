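class SapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SapError, ValueError):
    """A malformed input file (FASTA/FASTQ/SAM/VCF)."""


class ConsistencyError(SapError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


class ParameterError(SapError, ValueError):
    """An out-of-range or nonsensical parameter value."""
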