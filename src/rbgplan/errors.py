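"""Exception types shared across the planner."""


class ParameterError(ValueError):
    """A design parameter is outside its valid domain.

    Carries the offending parameter name so callers (in particular the CLI)
    can report it without a stack trace.
    """

    def __init__(self, param: str, message: str):
        self.param = param
        super().__init__(f"{param}: {message}")


class InfeasibleDesignError(RuntimeError):
    """The requested recall design cannot be filled from the bioresource."""


class UnachievablePowerError(ValueError):
    """No sample size can reach the requested power (null effect)."""
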