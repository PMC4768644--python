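"""Per-timestep decomposition of observed growth.

Every one-step growth rate of a structured population factorizes as

    lambda_obs(t) = lambda_max(t) * reactivity(t)

with lambda_obs = ||A x|| / ||x|| (one-norms), lambda_max the dominant
eigenvalue of A(t), and reactivity = || (A / lambda_max) (x / ||x||) ||.
On the log scale the factorization is additive:

    log lambda_obs = log lambda_max + log reactivity

The net decomposition can hide strong-but-opposing forces (asymptotic decline
masked by transient boom, or vice versa), so the *absolute dynamic*

    log lambda_abs = |log lambda_max| + |log reactivity|

measures the total magnitude of both forces regardless of sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import as_projection_matrix, as_stage_vector, dominant_eigenvalue
from .exceptions import DecompositionUndefinedError, DegenerateInputError


@dataclass(frozen=True)
class StepDecomposition:
    """One timestep's growth decomposition on the (natural-)log scale.

    Invariants: ``log_lambda_obs == log_lambda_max + log_reactivity`` and
    ``log_lambda_abs == |log_lambda_max| + |log_reactivity|``, so
    ``log_lambda_abs >= |log_lambda_obs|`` by the triangle inequality.
    """

    log_lambda_obs: float
    log_lambda_max: float
    log_reactivity: float
    log_lambda_abs: float


def observed_growth(A, x) -> float:
    """Observed one-step growth rate lambda_obs = ||A x||_1 / ||x||_1.

    Returns 0.0 if the projected vector is exactly zero (the population is
    extinguished); the log-scale decomposition is then undefined.
    """
    A = as_projection_matrix(A)
    x = as_stage_vector(x, dim=A.shape[0])
    nx = x.sum()
    if nx == 0:
        raise DegenerateInputError("stage vector is zero; observed growth undefined")
    return float((A @ x).sum() / nx)


def reactivity(A, x, *, lambda_max: float | None = None) -> float:
    """One-step transient amplification (>1, boom) or attenuation (<1, bust).

    reactivity = || (A / lambda_max) . (x / ||x||_1) ||_1.  Equals 1 exactly
    when x is proportional to the stable stage structure of A.

    ``lambda_max`` may be passed to avoid recomputing the eigenvalue.
    """
    A = as_projection_matrix(A)
    x = as_stage_vector(x, dim=A.shape[0])
    if lambda_max is None:
        lambda_max = dominant_eigenvalue(A)
    if lambda_max <= 0:
        raise DegenerateInputError(f"lambda_max must be positive, got {lambda_max}")
    nx = x.sum()
    if nx == 0:
        raise DegenerateInputError("stage vector is zero; reactivity undefined")
    return float((A @ (x / nx)).sum() / lambda_max)


def decompose_step(A, x, *, lambda_max: float | None = None) -> StepDecomposition:
    """Full log-scale decomposition of one projection step.

    Raises
    ------
    DecompositionUndefinedError
        If A x = 0, i.e. the population is extinguished this step.
    """
    A = as_projection_matrix(A)
    x = as_stage_vector(x, dim=A.shape[0])
    if lambda_max is None:
        lambda_max = dominant_eigenvalue(A)
    lam_obs = observed_growth(A, x)
    if lam_obs <= 0:
        raise DecompositionUndefinedError(
            "projected abundance is zero; log decomposition undefined"
        )
    log_obs = math.log(lam_obs)
    log_max = math.log(lambda_max)
    # computed by subtraction so the additive identity holds to rounding
    log_react = log_obs - log_max
    return StepDecomposition(
        log_lambda_obs=log_obs,
        log_lambda_max=log_max,
        log_reactivity=log_react,
        log_lambda_abs=absolute_dynamic(log_max, log_react),
    )


def absolute_dynamic(log_lambda_max: float, log_reactivity: float) -> float:
    """Absolute dynamic log lambda_abs = |log lambda_max| + |log reactivity|."""
    if not (np.isfinite(log_lambda_max) and np.isfinite(log_reactivity)):
        raise DegenerateInputError("absolute dynamic requires finite log components")
    return abs(log_lambda_max) + abs(log_reactivity)
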