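"""Exception hierarchy shared across the package."""


class FeastFamineError(Exception):
    """Base class for all package errors."""


class InvalidStateError(FeastFamineError, ValueError):
    """A state vector violates its invariants (negative, NaN or Inf components)."""


class IntegrationError(FeastFamineError, RuntimeError):
    """ODE integration failed (stiffness, blow-up, or invariant violation).

    Attributes
    ----------
    last_valid_time : float or None
        Last time point at which the solver state was valid.
    cycle_index : int or None
        Dilution cycle in which the failure occurred, when applicable.
    """

    def __init__(self, message, last_valid_time=None, cycle_index=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time
        self.cycle_index = cycle_index


class DiagnosticError(FeastFamineError, RuntimeError):
    """A chaos diagnostic failed (orbit escape, NaN in the map).

    Carries ``last_state``, the last finite state seen before the failure.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FitError(FeastFamineError, RuntimeError):
    """An optimisation stage failed to produce a usable fit."""

    def __init__(self, message, trace=None, initial_guess=None):
        super().__init__(message)
        self.trace = trace
        self.initial_guess = initial_guess


class DataError(FeastFamineError, ValueError):
    """Malformed or out-of-domain observational data."""


class UnimputableError(DataError):
    """Zero-count imputation impossible: no countable parallel population.

    ``missing`` lists the offending (day, ecotype) pairs.
    """

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class CommunityExtinctError(FeastFamineError, ValueError):
    """Total biomass is zero where a resampling or frequency requires it positive."""


class ConfigError(FeastFamineError, ValueError):
    """Invalid or unknown configuration keys/values."""
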