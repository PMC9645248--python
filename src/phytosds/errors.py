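"""Exception types shared across the package."""


class PhytoSDSError(Exception):
    """Base class for package-specific failures."""


class DegenerateEquilibriumError(PhytoSDSError, ValueError):
    """Raised when no coexistence equilibrium exists (e.g. mu = 0)."""


class IntegrationError(PhytoSDSError, RuntimeError):
    """Raised when a numerical integration fails or leaves the feasible set."""


class InsufficientDataError(PhytoSDSError, ValueError):
    """Raised when too few usable data points remain for a fit or transform."""


class NormalizationError(PhytoSDSError, ValueError):
    """Raised when a spectrum cannot be anchored to the reference bin."""
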