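"""Exception hierarchy for toxgp."""


class ToxGPError(Exception):
    """Base class for all toxgp errors."""


class ValidationError(ToxGPError, ValueError):
    """A value in an input table violates its domain (e.g. a non-ternary
    expression cell or a non-positive BUN level)."""


class FormatError(ToxGPError, ValueError):
    """An input file is structurally malformed (missing annotation columns,
    wrong width, ...)."""


class MatchError(ToxGPError, ValueError):
    """Cross-source compound matching produced an unusable result
    (e.g. empty intersection)."""


class FitError(ToxGPError, RuntimeError):
    """Model fitting failed (non-positive-definite kernel after jitter
    escalation, optimizer failure on every restart, ...)."""
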