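"""Exception hierarchy for poishmm."""


class PoisHMMError(Exception):
    """Base class for all poishmm-specific errors."""


class InvalidObservationError(PoisHMMError):
    """An observation is negative, non-integer, or otherwise not a count."""


class DegenerateChainError(PoisHMMError):
    """The transition matrix does not admit a unique stationary distribution."""


class BoundaryError(PoisHMMError):
    """A parameter transform is undefined at the requested point."""


class EvaluationError(PoisHMMError):
    """The likelihood (or a derivative) evaluated to a non-finite value.

    Carries the offending working-parameter vector for diagnostics.
    """

    def __init__(self, message, working=None):
        super().__init__(message)
        self.working = working


class ConvergenceError(PoisHMMError):
    """An iterative procedure failed to converge within its budget."""
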