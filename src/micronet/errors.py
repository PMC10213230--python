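"""Exception types shared across the pipeline."""


class MicronetError(Exception):
    """Base class for all package errors."""


class ValidationError(MicronetError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(MicronetError, ValueError):
    """A file could not be parsed into the expected structure."""


class NotEvaluableError(MicronetError):
    """A statistic cannot be computed on this input (e.g. too few
    eigenvalues to unfold, or a degenerate spacing histogram)."""


class EmptyNetworkError(MicronetError):
    """No edge survives the similarity cutoff."""
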