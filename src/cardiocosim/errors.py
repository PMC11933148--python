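"""Exception hierarchy for cardiocosim."""


class CardioCosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioCosimError):
    """Invalid or incomplete model/run configuration."""


class StructuralError(CardioCosimError):
    """Inconsistent model structure (dimension mismatch, unknown node, ...)."""


class NumericalError(CardioCosimError):
    """Non-finite values or solver breakdown during integration."""


class ConvergenceError(NumericalError):
    """Iterative solve reached its iteration cap above tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class InterfaceError(CardioCosimError):
    """Unknown value reference or other co-simulation interface misuse."""


class CausalityError(InterfaceError):
    """Attempt to write an output or read with the wrong causality."""


class ProtocolError(CardioCosimError):
    """Out-of-order stepping or other co-simulation protocol violation."""


class PackagingError(CardioCosimError):
    """FMU archive cannot be produced from an invalid variable registry."""
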