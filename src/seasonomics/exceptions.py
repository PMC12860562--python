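"""Exception hierarchy shared across the pipeline."""


class SeasonomicsError(Exception):
    """Base class for all pipeline errors."""


class ParseError(SeasonomicsError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(SeasonomicsError, ValueError):
    """An in-memory object violates an invariant (coordinates, counts, vocab)."""


class InsufficientDataError(SeasonomicsError, ValueError):
    """Too few observations for the requested statistic (e.g. < 2 replicates)."""


class DegenerateDataError(SeasonomicsError, ValueError):
    """Input is formally valid but the operation is undefined on it
    (zero variance, fewer distinct profiles than clusters, ...)."""


class ConvergenceError(SeasonomicsError, RuntimeError):
    """An iterative procedure failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
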