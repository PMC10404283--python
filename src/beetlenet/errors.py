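"""Exception hierarchy shared across the pipeline."""


class BeetlenetError(Exception):
    """Base class for all package-specific errors."""


class SurveyFormatError(BeetlenetError):
    """A delimited input file does not match the documented schema."""


class ValidationError(BeetlenetError, ValueError):
    """Data violate a documented invariant (negative counts, unknown labels...)."""


class InferenceError(BeetlenetError):
    """Network inference cannot proceed (too few samples, degenerate matrix...)."""
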