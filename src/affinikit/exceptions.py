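"""Exception hierarchy for affinikit.

All package errors derive from :class:`AffinikitError` so callers can catch
one base class at pipeline boundaries; parameter-validation errors also
derive from :class:`ValueError` to behave like ordinary bad-argument errors.
"""


class AffinikitError(Exception):
    """Base class for all affinikit errors."""


class InvalidParameterError(AffinikitError, ValueError):
    """A model or protocol parameter violates its physical constraints."""


class IntegrationError(AffinikitError, RuntimeError):
    """The ODE integrator failed to produce a solution."""


class NoRootError(AffinikitError, RuntimeError):
    """Steady-state root finding failed to locate an admissible root."""


class FitConvergenceError(AffinikitError, RuntimeError):
    """A nonlinear fit failed to converge; diagnostics attached.

    Parameters recovered so far (if any) are available on ``diagnostics``
    and are never silently reported as converged results.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderDeterminedError(AffinikitError, ValueError):
    """Too few samples, concentrations or points to constrain the fit."""


class PhaseMissingError(AffinikitError, ValueError):
    """A sensorgram lacks a phase required by the requested analysis."""


class DataError(AffinikitError, ValueError):
    """Malformed input data (bad header, non-monotone time, bad labels...)."""


class NoBackgroundError(DataError):
    """A plate has no buffer-alone background wells."""


class DegenerateSeriesError(DataError):
    """A concentration series is too short or degenerate to analyze."""


class NoTransitionError(AffinikitError, RuntimeError):
    """An inhibition series shows no signal transition to fit."""


class MissingMolecularWeightError(AffinikitError, ValueError):
    """Analyte molecular weight required for unit conversion is not set."""
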