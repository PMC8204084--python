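"""Exception hierarchy shared across the package."""


class GlucofluxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GlucofluxError):
    """A parameter or configuration value violates its contract."""


class SignalError(GlucofluxError):
    """A forcing signal evaluated to a non-finite value or is malformed."""

    def __init__(self, signal_name: str, t: float, message: str = ""):
        self.signal_name = signal_name
        self.t = t
        detail = message or f"signal {signal_name!r} is not finite at t={t:g} min"
        super().__init__(detail)


class InitializationError(GlucofluxError):
    """Steady-state initialization failed to converge."""


class SimulationError(GlucofluxError):
    """The ODE integrator failed or produced non-finite states."""


class ParseError(GlucofluxError):
    """A file does not conform to the documented dialect."""
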