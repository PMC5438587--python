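"""Exception types shared across the package."""


class NetworkValidationError(ValueError):
    """An input violates the bipartite-network invariants."""


class MatrixParseError(ValueError):
    """An interaction-matrix file could not be parsed."""


class ConvergenceError(RuntimeError):
    """An iterative scorer failed to converge.

    Carries the last iterate so callers can inspect how far the
    iteration got.
    """

    def __init__(self, message, last_iterate=None, n_iter=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.n_iter = n_iter
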