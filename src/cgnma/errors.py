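"""Exception hierarchy shared across the package."""


class CgnmaError(Exception):
    """Base class for all package errors."""


class StructureError(CgnmaError):
    """Invalid or unusable atomic structure / selection."""


class TopologyError(CgnmaError):
    """Inconsistent interaction topology."""


class NumericalError(CgnmaError):
    """Numerical failure (singular block, non-convergence, non-finite values)."""
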