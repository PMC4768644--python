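"""Collapse replicate metrics into per-population response variables.

Six responses per population, computed over its simulation replicates:

(i)   r2_asym   — squared Pearson correlation of log lambda_obs with
                  log lambda_max: share of observed-growth variance
                  explained by fluctuating asymptotic growth.
(ii)  r2_trans  — squared Pearson correlation of log lambda_obs with
                  log reactivity: share explained by transients.  Because
                  the two components covary, (i) + (ii) need not equal 1.
(iii) prop_abs_trans — mean over replicates of
                  |log reactivity| / log lambda_abs: the share of the
                  absolute dynamic due to transients.
(iv)  mean_log_lambda_obs  — the stochastic growth rate.
(v)   mean_log_lambda_max  — mean asymptotic growth.
(vi)  mean_log_reactivity  — mean transient growth (the boom/bust tendency).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import UndefinedPartitionError
from .simulate import PopulationModel

_VAR_TOL = 1e-300  # exact-zero variance guard; relative check applied too


@dataclass(frozen=True)
class PartitionSummary:
    """Per-population response variables plus comparative covariates."""

    population_id: str
    species_id: str
    growth_form: str
    matrix_dimension: int
    n_replicates_used: int
    r2_asym: float
    r2_trans: float
    prop_abs_trans: float
    mean_log_lambda_obs: float
    mean_log_lambda_max: float
    mean_log_reactivity: float


def _pearson_r2(x: np.ndarray, y: np.ndarray, name: str) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise UndefinedPartitionError("need at least 3 replicates for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    # sample (n-1) normalization; cancels in r but fixed for the record
    vx = (xc @ xc) / (x.size - 1)
    vy = (yc @ yc) / (y.size - 1)
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if vx <= _VAR_TOL or vy <= _VAR_TOL or min(vx, vy) < (1e-15 * scale) ** 2:
        raise UndefinedPartitionError(f"zero variance in component {name!r}")
    r = (xc @ yc) / (x.size - 1) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


def variance_explained(table: pd.DataFrame) -> tuple[float, float]:
    """(r2_asym, r2_trans): variance shares of observed growth.

    Raises
    ------
    UndefinedPartitionError
        If either component has zero variance across replicates (e.g. a
        single-matrix population, where log lambda_max is constant).
    """
    obs = table["log_lambda_obs"].to_numpy()
    r2_asym = _pearson_r2(obs, table["log_lambda_max"].to_numpy(), "log_lambda_max")
    r2_trans = _pearson_r2(obs, table["log_reactivity"].to_numpy(), "log_reactivity")
    return r2_asym, r2_trans


def transient_proportion(table: pd.DataFrame) -> float:
    """Mean share of the absolute dynamic due to transients.

    Per replicate: |log reactivity| / log lambda_abs.  Replicates with
    log lambda_abs = 0 (no dynamics at all) carry no information about the
    partition and are excluded from the mean.
    """
    react = np.abs(table["log_reactivity"].to_numpy())
    absd = table["log_lambda_abs"].to_numpy()
    usable = absd > 0
    if not usable.any():
        raise UndefinedPartitionError(
            "all replicates have zero absolute dynamic; proportion undefined"
        )
    return float(np.mean(react[usable] / absd[usable]))


def summarize_population(pop: PopulationModel, table: pd.DataFrame) -> PartitionSummary:
    """All six response variables for one population's metrics table."""
    try:
        r2_asym, r2_trans = variance_explained(table)
        prop = transient_proportion(table)
    except UndefinedPartitionError as exc:
        raise UndefinedPartitionError(f"population {pop.population_id}: {exc}") from exc
    return PartitionSummary(
        population_id=pop.population_id,
        species_id=pop.species_id,
        growth_form=pop.growth_form,
        matrix_dimension=pop.dim,
        n_replicates_used=int(len(table)),
        r2_asym=r2_asym,
        r2_trans=r2_trans,
        prop_abs_trans=prop,
        mean_log_lambda_obs=float(table["log_lambda_obs"].mean()),
        mean_log_lambda_max=float(table["log_lambda_max"].mean()),
        mean_log_reactivity=float(table["log_reactivity"].mean()),
    )


def summaries_frame(summaries) -> pd.DataFrame:
    """Stack PartitionSummary records into a DataFrame (one row/population)."""
    rows = [asdict(s) if isinstance(s, PartitionSummary) else dict(s) for s in summaries]
    return pd.DataFrame(rows)


def summarize_database(populations, table: pd.DataFrame) -> pd.DataFrame:
    """Summarize every population present in a stacked metrics table.

    Populations whose partition is undefined (e.g. single-matrix) are skipped
    with their reason collected; returns the summary frame.
    """
    by_pop = dict(tuple(table.groupby("population_id", sort=False)))
    out = []
    for pop in populations:
        sub = by_pop.get(pop.population_id)
        if sub is None:
            continue
        out.append(summarize_population(pop, sub))
    return summaries_frame(out)
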