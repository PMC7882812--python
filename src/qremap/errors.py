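"""Exception hierarchy shared across the pipeline."""


class QremapError(Exception):
    """Base class for all package errors."""


class CoordinateError(QremapError, ValueError):
    """Invalid interval or out-of-range transcript/genome position."""


class FormatError(QremapError, ValueError):
    """Malformed input file (FASTA/GTF/narrowPeak/TSV)."""


class AnnotationError(QremapError, ValueError):
    """Inconsistent gene annotation (e.g. CDS outside exons)."""


class ConfigError(QremapError, ValueError):
    """Invalid configuration value or combination."""


class InputError(QremapError, ValueError):
    """Semantically invalid in-memory input (empty table, duplicate keys...)."""
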