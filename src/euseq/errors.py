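"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`FormatError` and
:class:`DesignError` are input problems (exit 2); :class:`AnalysisError`
is a computation-stage failure (exit 3).
"""


class EuseqError(Exception):
    """Base class for all package errors."""


class ParameterError(EuseqError, ValueError):
    """An argument or configuration field is out of its allowed range."""


class FormatError(EuseqError, ValueError):
    """A file does not conform to its declared format; message names the offending row/column."""


class DesignError(EuseqError, ValueError):
    """Sample/condition design is inconsistent with the data."""


class NormalizationError(EuseqError, ValueError):
    """Spike-in normalization cannot be computed (e.g. a sample with zero spike reads)."""


class AnnotationError(EuseqError, ValueError):
    """Gene annotation is missing or invalid for a requested computation."""


class AnalysisError(EuseqError, RuntimeError):
    """A downstream analysis stage cannot produce a result."""
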