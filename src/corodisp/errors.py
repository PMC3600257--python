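"""Exception hierarchy shared across the package."""


class CorodispError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CorodispError, ValueError):
    """An argument lies outside the physical/geometric domain of an operation."""


class ConfigurationError(CorodispError, ValueError):
    """A configuration or parameter set violates a type invariant."""


class SolverError(CorodispError, RuntimeError):
    """Numerical failure of the transport solver (instability, NaN blow-up)."""


class ConservationError(CorodispError, RuntimeError):
    """Tracer mass balance drifted beyond the accepted tolerance."""
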