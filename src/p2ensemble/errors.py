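"""Exception hierarchy shared across the package."""


class P2EnsembleError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(P2EnsembleError, ValueError):
    """A model parameter violates its domain (e.g. non-positive K1/2)."""


class DataError(P2EnsembleError, ValueError):
    """Input data violate a precondition (insufficient, degenerate, malformed)."""


class UndefinedRSquaredError(DataError):
    """R^2 is undefined because the observed responses have zero variance."""


class FitFailureError(P2EnsembleError, RuntimeError):
    """The optimizer did not converge; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CatalogMissError(P2EnsembleError, KeyError):
    """Unknown (receptor, species) pair; lists available pairs."""

    def __init__(self, message, available=()):
        super().__init__(message)
        self.available = tuple(available)

    def __str__(self):  # KeyError quotes its message otherwise
        return self.args[0]


class CollinearBasisError(DataError):
    """The design matrix is rank deficient; names the offending columns."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)
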