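"""Exception hierarchy for covnet."""


class CovnetError(Exception):
    """Base class for all covnet errors."""


class AtlasError(CovnetError):
    """Malformed or mismatched region atlas."""


class CohortFormatError(CovnetError):
    """A cohort table violates the expected column/value contract."""


class ContractError(CovnetError):
    """An argument violates a documented precondition (e.g. asymmetric matrix)."""


class DegenerateDataError(CovnetError):
    """Data cannot support the requested estimate (zero variance, too few subjects)."""


class DisconnectedNetworkError(CovnetError):
    """A graph operation that requires a connected network received a
    disconnected one. ``component_sizes`` lists the sizes of the connected
    components found."""

    def __init__(self, message: str, component_sizes=None):
        super().__init__(message)
        self.component_sizes = tuple(component_sizes or ())


class NotPositiveSemidefiniteError(CovnetError):
    """A latent correlation matrix is not PSD. Carries the offending eigenvalue."""

    def __init__(self, message: str, min_eigenvalue: float):
        super().__init__(message)
        self.min_eigenvalue = float(min_eigenvalue)
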