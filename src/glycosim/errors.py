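"""Exception hierarchy for model configuration, validation and numerics."""


class GlycosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlycosimError):
    """A parameter file is missing or malformed (names reaction/parameter)."""


class ValidationError(GlycosimError):
    """A constructed object violates one of its declared invariants."""


class ConsistencyError(GlycosimError):
    """A rate law references a metabolite that cannot be resolved."""


class NumericalError(GlycosimError):
    """A rate or derivative evaluated to NaN/Inf (names the reaction)."""


class ConvergenceError(GlycosimError):
    """Steady-state integration failed in a way that cannot be reported as
    a non-converged result (e.g. negative concentrations beyond tolerance)."""


class ParseError(GlycosimError):
    """A data file could not be parsed; carries row/column context."""
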