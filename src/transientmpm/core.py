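"""Eigen-analysis of single projection matrices.

A projection matrix A is a square non-negative matrix of per-capita annual
rates.  For an irreducible, primitive ("ergodic") matrix the Perron-Frobenius
theorem guarantees a real, positive, simple dominant eigenvalue lambda_max
with a strictly positive right eigenvector w (the stable stage structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .exceptions import (
    DimensionMismatchError,
    ErgodicityError,
    InvalidMatrixError,
)

# |imag| <= IMAG_RTOL * (1 + |real|) counts as real (eigen-solver dust)
IMAG_RTOL = 1e-8


def as_projection_matrix(A) -> np.ndarray:
    """Validate and return ``A`` as a float array.

    Raises
    ------
    InvalidMatrixError
        If ``A`` is not a square 2-d array of non-negative finite entries
        with dimension >= 2.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidMatrixError(f"projection matrix must be square, got shape {A.shape}")
    if A.shape[0] < 1:
        raise InvalidMatrixError("projection matrix must be at least 1x1")
    if not np.all(np.isfinite(A)):
        raise InvalidMatrixError("projection matrix has non-finite entries")
    if np.any(A < 0):
        raise InvalidMatrixError("projection matrix has negative entries")
    return A


def as_stage_vector(x, dim: int | None = None) -> np.ndarray:
    """Validate and return ``x`` as a 1-d non-negative float array."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidMatrixError(f"stage vector must be 1-d, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidMatrixError("stage vector has non-finite entries")
    if np.any(x < 0):
        raise InvalidMatrixError("stage vector has negative entries")
    if dim is not None and x.shape[0] != dim:
        raise DimensionMismatchError(
            f"stage vector length {x.shape[0]} does not match matrix dimension {dim}"
        )
    return x


def dominant_eigenvalue(A, *, check_ergodic: bool = False) -> float:
    """Dominant eigenvalue lambda_max of ``A`` (maximum modulus, real part).

    Parameters
    ----------
    A : array_like
        Square non-negative projection matrix.
    check_ergodic : bool
        If True, raise :class:`ErgodicityError` when the dominant eigenvalue
        has a non-negligible imaginary part — which cannot happen for a
        primitive irreducible matrix.
    """
    A = as_projection_matrix(A)
    eigvals = np.linalg.eigvals(A)
    lam = eigvals[np.argmax(np.abs(eigvals))]
    if check_ergodic and abs(lam.imag) > IMAG_RTOL * (1.0 + abs(lam.real)):
        raise ErgodicityError(
            f"dominant eigenvalue {lam} has non-negligible imaginary part "
            "for a matrix flagged ergodic"
        )
    return float(lam.real)


def stable_structure(A) -> np.ndarray:
    """Stable stage structure w: dominant right eigenvector, one-norm 1.

    Raises
    ------
    ErgodicityError
        If the dominant eigenvalue is not simple (the dominant eigenspace is
        not one-dimensional, e.g. the identity matrix), so w is not unique
        up to scale.
    """
    A = as_projection_matrix(A)
    eigvals, eigvecs = np.linalg.eig(A)
    moduli = np.abs(eigvals)
    i = int(np.argmax(moduli))
    lam = eigvals[i]
    # dominant value repeated (same complex value within tolerance) => degenerate
    tol = 1e-9 * (1.0 + moduli[i])
    same = np.abs(eigvals - lam) <= tol
    if same.sum() > 1:
        raise ErgodicityError(
            "dominant eigenvalue is not simple; stable structure undefined"
        )
    w = eigvecs[:, i]
    if abs(lam.imag) > IMAG_RTOL * (1.0 + abs(lam.real)):
        raise ErgodicityError(f"dominant eigenvalue {lam} is not real")
    w = np.real(w)
    # Perron vector of a non-negative matrix can be taken non-negative
    if w.sum() < 0:
        w = -w
    w = np.where(np.abs(w) < 1e-14 * np.abs(w).max(), 0.0, w)
    if np.any(w < 0):
        raise ErgodicityError("dominant eigenvector is not sign-definite")
    s = w.sum()
    if s <= 0:
        raise ErgodicityError("dominant eigenvector has zero one-norm")
    return w / s


def project(A, x) -> np.ndarray:
    """One projection step: returns ``A @ x``."""
    A = as_projection_matrix(A)
    x = as_stage_vector(x, dim=A.shape[0])
    return A @ x


@dataclass(frozen=True)
class ErgodicityReport:
    """Verdict of :func:`is_ergodic` with its two ingredients."""

    irreducible: bool
    primitive: bool

    @property
    def ergodic(self) -> bool:
        return self.irreducible and self.primitive

    def __bool__(self) -> bool:  # truthiness == ergodicity
        return self.ergodic


def is_ergodic(A) -> ErgodicityReport:
    """Check irreducibility and primitivity of the non-negative pattern of A.

    Irreducibility is strong connectivity of the digraph with an edge j -> i
    wherever A[i, j] > 0.  Primitivity is checked on the Boolean pattern via
    the Wielandt bound: a primitive s x s matrix satisfies
    A**(s**2 - 2s + 2) > 0 entry-wise.
    """
    A = as_projection_matrix(A)
    s = A.shape[0]
    pattern = A > 0
    if s == 1:
        return ErgodicityReport(irreducible=bool(pattern[0, 0]), primitive=bool(pattern[0, 0]))
    n_comp, _ = csgraph.connected_components(
        csr_matrix(pattern), directed=True, connection="strong"
    )
    irreducible = n_comp == 1
    if not irreducible:
        return ErgodicityReport(irreducible=False, primitive=False)
    primitive = _boolean_power_positive(pattern, s * s - 2 * s + 2)
    return ErgodicityReport(irreducible=True, primitive=primitive)


def _boolean_power_positive(pattern: np.ndarray, k: int) -> bool:
    """Whether the Boolean k-th power of ``pattern`` is all-True."""
    result = np.eye(pattern.shape[0], dtype=bool)
    base = pattern.copy()
    while k > 0:
        if k & 1:
            result = (result @ base) > 0
        k >>= 1
        if k:
            base = (base @ base) > 0
    return bool(result.all())


def mean_matrix(matrices) -> np.ndarray:
    """Element-wise arithmetic mean of a non-empty list of same-size matrices."""
    mats = [as_projection_matrix(A) for A in matrices]
    if not mats:
        raise InvalidMatrixError("cannot average an empty list of matrices")
    dims = {A.shape[0] for A in mats}
    if len(dims) != 1:
        raise DimensionMismatchError(f"matrices have mixed dimensions: {sorted(dims)}")
    return np.mean(mats, axis=0)
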