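"""Package-wide exception types."""


class GenerationError(RuntimeError):
    """A stochastic generator could not produce a valid object.

    Raised when edge budgets are infeasible, link placement fails after
    bounded retries, or no feasible & stable community parameterization is
    found within ``max_tries``. Carries whatever diagnostics the generator
    accumulated in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class ConsistencyError(RuntimeError):
    """An event or state update referenced an invalid site or species."""
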