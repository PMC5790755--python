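"""Exception hierarchy used across the pipeline."""


class SasmorphError(Exception):
    """Base class for all package errors."""


class ValidationError(SasmorphError, ValueError):
    """Invalid parameter or malformed input."""


class DegenerateGeometryError(SasmorphError):
    """Input too thin, too small or otherwise without measurable geometry."""


class TruncatedSegmentError(SasmorphError):
    """Operation refused because the segment touches the stack border."""


class IndeterminateClassification(SasmorphError):
    """A segment too degenerate for AS/SS classification."""


class DegenerateFitError(SasmorphError):
    """Distribution fit on a constant (zero-variance) sample."""
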