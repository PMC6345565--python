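"""Exception hierarchy for scmskit.

Everything raised deliberately by the package derives from ScmskitError so
callers (and the CLI) can distinguish user/data problems from bugs.
"""


class ScmskitError(Exception):
    """Base class for all scmskit errors."""


class InvalidParameterError(ScmskitError, ValueError):
    """A rate constant, geometry or configuration value is out of range."""


class InvalidStateError(ScmskitError, ValueError):
    """A species state violates its invariants (negative abundance, broken conservation)."""


class SolverError(ScmskitError, RuntimeError):
    """The ODE integrator failed or produced out-of-tolerance output."""


class CrossoverNotFoundError(ScmskitError, RuntimeError):
    """No ternary/bivalent crossover exists in the searched concentration range."""


class DataError(ScmskitError, ValueError):
    """An input table is malformed, too small, or degenerate for the requested fit."""


class FitConvergenceError(ScmskitError, RuntimeError):
    """Nonlinear least squares failed to converge; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedValueError(ScmskitError, ZeroDivisionError):
    """A ratio or polarization is undefined for the given inputs."""


class ConfigError(ScmskitError, ValueError):
    """A run configuration is missing fields or contains unresolvable values."""
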