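"""Stochastic simulation protocol.

Each population is a set of annual projection matrices.  A replicate starts
with equal numbers in every stage, draws a matrix i.i.d. uniformly (with
replacement) each time step for a burn-in of ``burn_in`` steps, then draws
one more matrix and records the one-step growth decomposition between
t = burn_in and t = burn_in + 1.  The stage vector is renormalized to
one-norm 1 every step; all recorded metrics depend on x only through
x / ||x||_1, so renormalization changes nothing but prevents overflow.

The default protocol is 1000 replicates per population with a burn-in of
500 steps.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import as_projection_matrix, dominant_eigenvalue
from .exceptions import (
    DimensionMismatchError,
    SimulationFailedError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROWTH_FORMS = ("herbaceous_perennial", "shrub", "succulent", "palm", "tree")

METRIC_COLUMNS = (
    "log_lambda_obs",
    "log_lambda_max",
    "log_reactivity",
    "log_lambda_abs",
)


@dataclass
class PopulationModel:
    """A population's annual matrices plus comparative metadata."""

    population_id: str
    species_id: str
    growth_form: str
    matrices: list = field(default_factory=list)
    manipulated: bool = False
    is_mean_matrix: bool = False

    def __post_init__(self):
        if self.growth_form not in GROWTH_FORMS:
            raise ValidationError(
                f"unknown growth form {self.growth_form!r}; expected one of {GROWTH_FORMS}"
            )
        self.matrices = [as_projection_matrix(A) for A in self.matrices]
        dims = {A.shape[0] for A in self.matrices}
        if len(dims) > 1:
            raise DimensionMismatchError(
                f"population {self.population_id}: matrices have mixed dimensions {sorted(dims)}"
            )

    @property
    def dim(self) -> int:
        if not self.matrices:
            raise ValidationError(f"population {self.population_id} has no matrices")
        return self.matrices[0].shape[0]

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation protocol parameters (defaults follow the standard protocol)."""

    n_replicates: int = 1000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.burn_in < 0:
            raise ValidationError("burn_in must be >= 0")


def population_rng(seed: int, population_id: str) -> np.random.Generator:
    """Deterministic per-population generator, independent of execution order.

    The stream is keyed by (seed, CRC32 of the population id), so simulating
    populations in any order or in parallel yields identical results.
    """
    key = zlib.crc32(population_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_population(pop: PopulationModel, cfg: SimulationConfig) -> pd.DataFrame:
    """Run the replicate simulation for one population.

    Returns the metrics table: one row per non-degenerate replicate with
    columns ``log_lambda_obs``, ``log_lambda_max``, ``log_reactivity``,
    ``log_lambda_abs`` and ``population_id``; the index is the replicate id.

    Raises
    ------
    ValidationError
        If the population holds no matrices.
    SimulationFailedError
        If every replicate is degenerate (extinguished).
    """
    if not pop.matrices:
        raise ValidationError(f"population {pop.population_id} has no matrices")
    mats = np.stack(pop.matrices)  # (k, s, s)
    k, s, _ = mats.shape
    log_lams = np.empty(k)
    for j in range(k):
        log_lams[j] = np.log(dominant_eigenvalue(mats[j], check_ergodic=False))
    if not np.all(np.isfinite(log_lams)):
        raise SimulationFailedError(
            f"population {pop.population_id}: a matrix has non-positive lambda_max"
        )

    rng = population_rng(cfg.seed, pop.population_id)
    n = cfg.n_replicates
    # draws[t, r]: matrix index used between t and t+1 (t = 0 .. burn_in)
    draws = rng.integers(0, k, size=(cfg.burn_in + 1, n))

    x = np.full((s, n), 1.0 / s)  # equal numbers in every stage
    alive = np.ones(n, dtype=bool)
    for t in range(cfg.burn_in):
        idx = draws[t]
        new_x = np.empty_like(x)
        for j in range(k):
            cols = idx == j
            if cols.any():
                new_x[:, cols] = mats[j] @ x[:, cols]
        totals = new_x.sum(axis=0)
        dead = alive & (totals == 0)
        if dead.any():
            alive &= ~dead
            totals = np.where(totals == 0, 1.0, totals)
        x = new_x / totals

    # measured step: one fresh draw after burn-in
    idx = draws[cfg.burn_in]
    growth = np.empty(n)
    for j in range(k):
        cols = idx == j
        if cols.any():
            growth[cols] = (mats[j] @ x[:, cols]).sum(axis=0)
    alive &= growth > 0

    n_excluded = int((~alive).sum())
    if n_excluded:
        logger.warning(
            "population %s: excluded %d extinguished replicate(s)",
            pop.population_id,
            n_excluded,
        )
    if not alive.any():
        raise SimulationFailedError(
            f"population {pop.population_id}: all {n} replicates degenerate"
        )

    log_obs = np.log(growth[alive])  # x already has one-norm 1
    log_max = log_lams[idx[alive]]
    log_react = log_obs - log_max
    table = pd.DataFrame(
        {
            "log_lambda_obs": log_obs,
            "log_lambda_max": log_max,
            "log_reactivity": log_react,
            "log_lambda_abs": np.abs(log_max) + np.abs(log_react),
            "population_id": pop.population_id,
        },
        index=pd.Index(np.flatnonzero(alive), name="replicate_id"),
    )
    return table


def metrics_table(results) -> pd.DataFrame:
    """Concatenate per-replicate metric tables into one rectangular table."""
    if isinstance(results, pd.DataFrame):
        frames = [results]
    else:
        frames = list(results)
    if not frames:
        raise ValidationError("no simulation results to tabulate")
    table = pd.concat(frames)
    missing = [c for c in (*METRIC_COLUMNS, "population_id") if c not in table.columns]
    if missing:
        raise ValidationError(f"metrics table is missing columns {missing}")
    return table


def simulate_database(populations, cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate every population and stack the metric tables.

    Populations whose simulation fails outright (non-positive lambda_max or
    all replicates degenerate) are skipped with a logged reason.
    """
    frames = []
    for pop in populations:
        try:
            frames.append(simulate_population(pop, cfg))
        except SimulationFailedError as exc:
            logger.warning("skipping population %s: %s", pop.population_id, exc)
    if not frames:
        raise SimulationFailedError("no population produced usable replicates")
    return metrics_table(frames)
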