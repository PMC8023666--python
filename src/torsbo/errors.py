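"""Exception hierarchy shared across the package."""


class TorsboError(Exception):
    """Base class for all package errors."""


class ConfigError(TorsboError):
    """Invalid user configuration (exit code 2 from the CLI)."""


class DegenerateGeometryError(TorsboError):
    """A dihedral definition contains a collinear atom triplet."""


class NonRotatableBondError(TorsboError):
    """The central bond of a dihedral lies in a ring and cannot be rotated."""


class XYZParseError(TorsboError):
    """Malformed XYZ input; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConditioningError(TorsboError):
    """Gram matrix remained singular after jitter escalation."""


class NotFittedError(TorsboError):
    """Posterior queried on an unfitted surrogate model."""


class AcquisitionError(TorsboError):
    """All acquisition-optimizer starts failed; carries diagnostics."""


class CalculatorError(TorsboError):
    """Backend failed to produce a finite energy (exit code 3 from the CLI)."""


class NonConvergenceError(TorsboError):
    """Relaxation step limit exceeded; carries the last geometry."""

    def __init__(self, message: str, geometry=None, energy=None):
        super().__init__(message)
        self.geometry = geometry
        self.energy = energy
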