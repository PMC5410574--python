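"""Exception types shared across the pipeline."""


class CdpMarkovError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(CdpMarkovError, ValueError):
    """A parameter violates its contract (range, shape, emptiness)."""


class InvalidModelError(CdpMarkovError, ValueError):
    """A transition matrix is not row-stochastic."""


class InvalidSymbolError(CdpMarkovError, KeyError):
    """A token has no template/prototype/model entry."""


class InsufficientDataError(CdpMarkovError, ValueError):
    """Too few events or tokens for the requested computation."""


class ParseError(CdpMarkovError, ValueError):
    """A sequence file is malformed; message names the offending line."""


class UndefinedCellError(CdpMarkovError, ValueError):
    """Observed counts in a cell whose expected count is zero."""
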