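"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its
subclasses) to exit code 1.
"""


class AllelicDosageError(Exception):
    """Base class for all package errors."""


class ConfigError(AllelicDosageError):
    """Malformed or incomplete configuration."""


class DataError(AllelicDosageError):
    """Invalid input data (violated contract, missing sample, ...)."""


class FormatError(DataError):
    """Structurally malformed input file (missing column, bad header)."""


class DegenerateLocusError(DataError):
    """Locus where the expected-VAF denominator vanishes (p=1, CN_t=0)."""
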