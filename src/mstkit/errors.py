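"""Exception hierarchy for mstkit.

All errors raised by the library derive from :class:`MstkitError` so callers
(and the CLI) can catch a single base class.
"""


class MstkitError(Exception):
    """Base class for all mstkit errors."""


class DataError(MstkitError):
    """Input data violates a precondition (non-positive counts, empty table, ...)."""


class WindowError(MstkitError):
    """An analysis window lies outside the trace or contains too few samples."""


class ConfigError(MstkitError):
    """A run configuration is incomplete or inconsistent."""


class DomainError(MstkitError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateSystemError(MstkitError):
    """The equilibrium system is degenerate (e.g. zero tracer, zero amplitude)."""


class FitError(MstkitError):
    """Nonlinear fit failed to converge from every start."""


class FlatCurveError(FitError):
    """Response amplitude indistinguishable from zero; no binding signal."""


class NotDecayingError(FitError):
    """Time course does not decay (fitted rate non-positive)."""


class UnidentifiableError(FitError):
    """The design cannot identify the requested parameter (flat series, IC50 > L0)."""


class SolverError(MstkitError):
    """Root-finding failed (no sign change or non-convergence)."""
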