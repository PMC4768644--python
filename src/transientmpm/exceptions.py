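"""Exception hierarchy for the package."""


class TransientMPMError(Exception):
    """Base class for all package errors."""


class InvalidMatrixError(TransientMPMError, ValueError):
    """Matrix is not square, has negative entries, or is otherwise not a
    valid projection matrix."""


class DimensionMismatchError(TransientMPMError, ValueError):
    """Operand dimensions do not agree."""


class ErgodicityError(TransientMPMError, ValueError):
    """Dominant eigenstructure is degenerate (non-unique dominant
    eigenvector, or dominant eigenvalue not effectively real on a matrix
    flagged ergodic)."""


class DegenerateInputError(TransientMPMError, ValueError):
    """Input carries no usable signal (e.g. a zero stage vector)."""


class DecompositionUndefinedError(TransientMPMError, ValueError):
    """The growth decomposition is undefined (projected abundance is zero)."""


class UndefinedPartitionError(TransientMPMError, ValueError):
    """A variance partition is undefined, e.g. a component has zero
    variance or every replicate is degenerate."""


class GeneratorInfeasibleError(TransientMPMError, ValueError):
    """The synthetic-matrix generator cannot reach the requested target
    under its biological constraints."""


class FormatError(TransientMPMError, ValueError):
    """A matrix exchange file violates the format contract."""


class ValidationError(TransientMPMError, ValueError):
    """Required metadata is missing or inconsistent."""


class SimulationFailedError(TransientMPMError, RuntimeError):
    """Every replicate of a simulation was degenerate."""
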