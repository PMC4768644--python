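"""Synthetic stage-structured matrix database.

Generates populations of annual Lefkovitch-style projection matrices with
the statistical structure of a large comparative plant-demography database:
one to a few populations per species, 2-15 life stages (mean near 5.3),
five growth forms, several annual matrices per population, and asymptotic
growth rates distributed near 1 (log lambda_max near 0).

Matrix anatomy: each column j holds that stage's survival, split between
stasis (diagonal), progression to the next stage (subdiagonal) and a small
retrogression term; per-column survival sums stay <= 1.  Fecundities occupy
the top row for the later ("reproductive") stages.  Growth-form archetypes
set the stasis/survival/fecundity weightings (trees and palms: high stasis,
low fecundity variance; herbaceous perennials: low stasis, high fecundity).

Year-to-year variation multiplies fecundities by mean-preserving lognormal
noise and perturbs survival on the logit scale (which respects the
column-sum bound), both with a common coefficient of variation.  A
species-level random intercept on the temporal CV makes the comparative
model's species random effect real, and ``dimension_effect`` couples matrix
dimension to the temporal CV for parameter-recovery experiments.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import dominant_eigenvalue
from .exceptions import FormatError, GeneratorInfeasibleError, ValidationError
from .simulate import GROWTH_FORMS, PopulationModel

# growth-form archetypes: survival range across stages, stasis share of
# survival, and a multiplier on fecundity noise
_ARCHETYPES = {
    "herbaceous_perennial": {"surv": (0.30, 0.80), "stay": 0.25, "fec_noise": 1.3},
    "shrub": {"surv": (0.50, 0.90), "stay": 0.45, "fec_noise": 1.0},
    "succulent": {"surv": (0.60, 0.92), "stay": 0.55, "fec_noise": 0.9},
    "palm": {"surv": (0.70, 0.95), "stay": 0.70, "fec_noise": 0.6},
    "tree": {"surv": (0.75, 0.97), "stay": 0.75, "fec_noise": 0.5},
}

_RETRO_SHARE = 0.05  # share of survival that retrogresses one stage (cols >= 3)

CSV_COLUMNS = (
    "population_id",
    "species_id",
    "growth_form",
    "matrix_id",
    "row",
    "col",
    "value",
    "manipulated",
    "is_mean_matrix",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls for the synthetic database.

    ``populations_per_species`` is either an integer (constant) or a
    probability vector over counts 1, 2, ... .  ``target_log_lambda`` is the
    (mean, sd) of per-population log lambda_max targets for the rescaled
    mean matrix.  ``dimension_effect`` is a log-scale slope coupling matrix
    dimension (centred at ``dim_mean``) to the realized temporal CV.
    """

    n_species: int = 100
    populations_per_species: object = (0.5, 0.3, 0.2)
    dim_range: tuple = (2, 15)
    dim_mean: float = 5.3
    matrices_per_population: int = 5
    growth_form_mix: tuple = (0.55, 0.15, 0.10, 0.08, 0.12)
    target_log_lambda: tuple = (0.0, 0.1)
    temporal_cv: float = 0.3
    species_cv_sd: float = 0.3
    population_cv_sd: float = 0.15
    dimension_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.dim_range[0] <= self.dim_range[1] <= 50):
            raise ValidationError(f"dim_range must lie within [2, 50], got {self.dim_range}")
        if self.matrices_per_population < 1:
            raise ValidationError("matrices_per_population must be >= 1")
        if self.temporal_cv < 0:
            raise ValidationError("temporal_cv must be >= 0")
        mix = np.asarray(self.growth_form_mix, dtype=float)
        if mix.size != len(GROWTH_FORMS) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ValidationError("growth_form_mix must be 5 probabilities summing to 1")
        if not isinstance(self.populations_per_species, (int, np.integer)):
            p = np.asarray(self.populations_per_species, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValidationError("populations_per_species probabilities must sum to 1")


@dataclass
class SyntheticDatabase:
    """A generated set of populations plus generator bookkeeping."""

    populations: list = field(default_factory=list)
    provenance: GeneratorConfig | None = None
    bookkeeping: object = None  # per-population frame: dim, realized_cv, target

    def __iter__(self):
        return iter(self.populations)

    def __len__(self):
        return len(self.populations)


def _mean_structure(dim, archetype, rng):
    """Mean-matrix skeleton: survival part, unit fecundity pattern, masks."""
    arch = _ARCHETYPES[archetype]
    lo, hi = arch["surv"]
    ranks = np.linspace(0.0, 1.0, dim)
    surv = np.clip(lo + (hi - lo) * ranks + rng.normal(0.0, 0.05, dim), 0.05, 0.97)
    stay = np.clip(arch["stay"] + rng.normal(0.0, 0.08, dim), 0.05, 0.95)

    S = np.zeros((dim, dim))
    for j in range(dim):
        shares = {}
        if j == dim - 1:
            shares[(j, j)] = 1.0
        else:
            shares[(j, j)] = stay[j]
            shares[(j + 1, j)] = 1.0 - stay[j]
        if j >= 2:  # retrogression; never lands on the fecundity row
            total = 1.0 - _RETRO_SHARE
            shares = {rc: v * total for rc, v in shares.items()}
            shares[(j - 1, j)] = _RETRO_SHARE
        for (r, c), v in shares.items():
            S[r, c] = surv[j] * v

    # reproductive stages: the last ceil(dim/2), weight increasing with stage
    n_repro = max(1, math.ceil(dim / 2))
    F_unit = np.zeros((dim, dim))
    weights = 1.5 ** np.arange(n_repro)
    weights /= weights.max()
    for k, j in enumerate(range(dim - n_repro, dim)):
        F_unit[0, j] = weights[k]
    return S, F_unit


def _rescale_to_target(S, F_unit, target_log_lambda):
    """Scale fecundities (and survival if needed) so log lambda_max hits target."""
    target = math.exp(target_log_lambda)
    lam0 = dominant_eigenvalue(S) if S.any() else 0.0
    if lam0 >= target:
        # survival alone already exceeds the target growth rate; damp it
        S = S * (0.9 * target / lam0)

    def f(u):
        return math.log(dominant_eigenvalue(S + math.exp(u) * F_unit)) - target_log_lambda

    try:
        u = brentq(f, -40.0, 40.0, xtol=1e-13, rtol=8.9e-16)
    except ValueError as exc:
        raise GeneratorInfeasibleError(
            f"cannot reach log lambda_max = {target_log_lambda} under survival bounds"
        ) from exc
    M = S + math.exp(u) * F_unit
    if abs(math.log(dominant_eigenvalue(M)) - target_log_lambda) > 1e-6:
        raise GeneratorInfeasibleError(
            f"rescaling failed to reach log lambda_max = {target_log_lambda}"
        )
    return S, M - S


def generate_matrix_set(
    dim: int,
    n_matrices: int,
    archetype: str = "herbaceous_perennial",
    temporal_cv: float = 0.3,
    target_log_lambda: float = 0.0,
    seed=None,
    rng: np.random.Generator | None = None,
    fec_noise_mult: float | None = None,
):
    """Generate one population's set of annual matrices.

    The population's mean matrix is rescaled so its log dominant eigenvalue
    equals ``target_log_lambda`` to within 1e-6; annual matrices add
    mean-preserving lognormal noise (CV = ``temporal_cv``) to fecundities and
    logit-scale noise to survival.  ``temporal_cv = 0`` returns ``n_matrices``
    identical copies of the mean matrix.
    """
    if dim < 2:
        raise ValidationError("dim must be >= 2")
    if n_matrices < 1:
        raise ValidationError("n_matrices must be >= 1")
    if archetype not in _ARCHETYPES:
        raise ValidationError(f"unknown archetype {archetype!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if fec_noise_mult is None:
        fec_noise_mult = _ARCHETYPES[archetype]["fec_noise"]

    S, F_unit = _mean_structure(dim, archetype, rng)
    S, F = _rescale_to_target(S, F_unit, target_log_lambda)

    if temporal_cv == 0:
        return [S + F for _ in range(n_matrices)]

    surv_totals = S.sum(axis=0)  # per-column survival, in (0, 1)
    shares = np.divide(S, surv_totals, out=np.zeros_like(S), where=surv_totals > 0)
    fec_sigma = math.sqrt(math.log(1.0 + (temporal_cv * fec_noise_mult) ** 2))
    # logit-scale sd matched so the small-noise CV of survival ~ temporal_cv
    surv_sigma = np.minimum(temporal_cv / np.maximum(1.0 - surv_totals, 0.05), 2.0)

    surv_parts, fec_parts = [], []
    for _ in range(n_matrices):
        tot_t = expit(logit(surv_totals) + rng.normal(0.0, 1.0, dim) * surv_sigma)
        # jitter the stasis/progression/retrogression split, renormalized
        share_noise = np.exp(rng.normal(0.0, temporal_cv, S.shape))
        sh = shares * share_noise
        colsum = sh.sum(axis=0)
        sh = np.divide(sh, colsum, out=np.zeros_like(sh), where=colsum > 0)
        surv_parts.append(sh * tot_t)
        fec_parts.append(F * np.exp(rng.normal(-0.5 * fec_sigma**2, fec_sigma, F.shape)))

    # noise biases lambda_max downward (concavity of survival on the logit
    # scale); re-centre the set by a common fecundity scalar so the mean of
    # log lambda_max across the annual matrices equals the target
    def mean_log_lam(u):
        c = math.exp(u)
        logs = [
            math.log(dominant_eigenvalue(S_t + c * F_t))
            for S_t, F_t in zip(surv_parts, fec_parts)
        ]
        return float(np.mean(logs)) - target_log_lambda

    try:
        u = brentq(mean_log_lam, -20.0, 20.0, xtol=1e-10)
        c = math.exp(u)
    except ValueError:
        c = 1.0  # survival alone pins the set above/below target; leave as drawn
    return [S_t + c * F_t for S_t, F_t in zip(surv_parts, fec_parts)]


def _draw_populations_per_species(spec, rng):
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    p = np.asarray(spec, dtype=float)
    return int(rng.choice(np.arange(1, p.size + 1), p=p / p.sum()))


def _draw_dimension(cfg: GeneratorConfig, rng) -> int:
    lo, hi = cfg.dim_range
    for _ in range(1000):
        d = lo + rng.poisson(max(cfg.dim_mean - lo, 0.0))
        if lo <= d <= hi:
            return int(d)
    return int(np.clip(d, lo, hi))


def generate_database(cfg: GeneratorConfig) -> SyntheticDatabase:
    """Generate a full synthetic database under ``cfg`` (seed-reproducible).

    Species share a growth form and matrix dimension; each species carries a
    lognormal random intercept on its temporal CV; each population adds its
    own smaller intercept plus the dimension coupling:

        log cv_pop = log temporal_cv + species effect
                     + dimension_effect * (dim - dim_mean) + population effect
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    populations, rows = [], []
    mu_t, sd_t = cfg.target_log_lambda
    for i in range(cfg.n_species):
        species_id = f"sp{i:03d}"
        form = GROWTH_FORMS[rng.choice(len(GROWTH_FORMS), p=np.asarray(cfg.growth_form_mix))]
        dim = _draw_dimension(cfg, rng)
        species_effect = rng.normal(0.0, cfg.species_cv_sd)
        n_pops = _draw_populations_per_species(cfg.populations_per_species, rng)
        for p in range(n_pops):
            pop_id = f"{species_id}_pop{p:02d}"
            log_cv = (
                math.log(max(cfg.temporal_cv, 1e-12))
                + species_effect
                + cfg.dimension_effect * (dim - cfg.dim_mean)
                + rng.normal(0.0, cfg.population_cv_sd)
            )
            realized_cv = 0.0 if cfg.temporal_cv == 0 else math.exp(log_cv)
            target = rng.normal(mu_t, sd_t)
            mats = generate_matrix_set(
                dim,
                cfg.matrices_per_population,
                archetype=form,
                temporal_cv=realized_cv,
                target_log_lambda=target,
                rng=rng,
            )
            populations.append(
                PopulationModel(
                    population_id=pop_id,
                    species_id=species_id,
                    growth_form=form,
                    matrices=mats,
                )
            )
            rows.append(
                {
                    "population_id": pop_id,
                    "species_id": species_id,
                    "growth_form": form,
                    "matrix_dimension": dim,
                    "realized_cv": realized_cv,
                    "target_log_lambda": target,
                }
            )
    return SyntheticDatabase(
        populations=populations,
        provenance=cfg,
        bookkeeping=pd.DataFrame(rows),
    )


def apply_inclusion_filters(db, exclude_species=()):
    """Apply the inclusion criteria: >= 3 annual matrices, not experimentally
    manipulated, not a mean of multiple matrices; plus an optional explicit
    species exclusion list.

    Returns ``(kept, exclusion_log)`` where the log lists
    ``(population_id, reason)`` pairs.
    """
    populations = list(db.populations) if isinstance(db, SyntheticDatabase) else list(db)
    kept, log = [], []
    for pop in populations:
        for flag in ("manipulated", "is_mean_matrix"):
            if not hasattr(pop, flag):
                raise ValidationError(f"population {pop.population_id} missing flag {flag!r}")
        if pop.species_id in exclude_species:
            log.append((pop.population_id, "species on exclusion list"))
        elif len(pop.matrices) < 3:
            log.append((pop.population_id, "fewer than 3 matrices"))
        elif pop.manipulated:
            log.append((pop.population_id, "experimentally manipulated"))
        elif pop.is_mean_matrix:
            log.append((pop.population_id, "mean of multiple matrices"))
        else:
            kept.append(pop)
    return kept, log


def write_matrix_csv(db, path) -> None:
    """Write a database in the long exchange format (1-based row/col, dense)."""
    populations = list(db.populations) if isinstance(db, SyntheticDatabase) else list(db)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for pop in populations:
            for m, A in enumerate(pop.matrices):
                matrix_id = f"{pop.population_id}_m{m:03d}"
                s = A.shape[0]
                for r in range(s):
                    for c in range(s):
                        writer.writerow(
                            [
                                pop.population_id,
                                pop.species_id,
                                pop.growth_form,
                                matrix_id,
                                r + 1,
                                c + 1,
                                repr(float(A[r, c])),
                                pop.manipulated,
                                pop.is_mean_matrix,
                            ]
                        )


def _parse_bool(text, line_no):
    if text in ("True", "true", "1"):
        return True
    if text in ("False", "false", "0"):
        return False
    raise FormatError(f"line {line_no}: invalid boolean {text!r}")


def read_matrix_csv(path) -> SyntheticDatabase:
    """Read the long exchange format back into a database.

    Raises :class:`FormatError` (citing the 1-based file line) on negative
    values, duplicate (matrix_id, row, col) cells, or ragged/incomplete
    matrices; :class:`ValidationError` on missing columns.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty file") from None
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        col_of = {c: header.index(c) for c in CSV_COLUMNS}

        cells = {}  # (pop_id, matrix_id) -> {(row, col): value}
        meta = {}  # pop_id -> metadata
        order = []  # first-appearance order of (pop_id, matrix_id)
        for line_no, rec in enumerate(reader, start=2):
            if not rec:
                continue
            pop_id = rec[col_of["population_id"]]
            matrix_id = rec[col_of["matrix_id"]]
            try:
                r = int(rec[col_of["row"]])
                c = int(rec[col_of["col"]])
                v = float(rec[col_of["value"]])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from None
            if r < 1 or c < 1:
                raise FormatError(f"line {line_no}: row/col indices are 1-based, got ({r}, {c})")
            if v < 0:
                raise FormatError(f"line {line_no}: negative value {v}")
            key = (pop_id, matrix_id)
            if key not in cells:
                cells[key] = {}
                order.append(key)
            if (r, c) in cells[key]:
                raise FormatError(
                    f"line {line_no}: duplicate cell ({r}, {c}) for matrix {matrix_id!r}"
                )
            cells[key][(r, c)] = v
            rec_meta = (
                rec[col_of["species_id"]],
                rec[col_of["growth_form"]],
                _parse_bool(rec[col_of["manipulated"]], line_no),
                _parse_bool(rec[col_of["is_mean_matrix"]], line_no),
            )
            if pop_id in meta and meta[pop_id] != rec_meta:
                raise FormatError(f"line {line_no}: inconsistent metadata for {pop_id!r}")
            meta[pop_id] = rec_meta

    pop_matrices: dict[str, list] = {}
    for pop_id, matrix_id in order:
        entries = cells[(pop_id, matrix_id)]
        s = max(max(r for r, _ in entries), max(c for _, c in entries))
        if len(entries) != s * s:
            raise FormatError(
                f"matrix {matrix_id!r} is ragged: expected {s * s} cells for "
                f"dimension {s}, found {len(entries)}"
            )
        A = np.zeros((s, s))
        for (r, c), v in entries.items():
            A[r - 1, c - 1] = v
        pop_matrices.setdefault(pop_id, []).append(A)

    populations = []
    for pop_id, mats in pop_matrices.items():
        species_id, form, manipulated, is_mean = meta[pop_id]
        populations.append(
            PopulationModel(
                population_id=pop_id,
                species_id=species_id,
                growth_form=form,
                matrices=mats,
                manipulated=manipulated,
                is_mean_matrix=is_mean,
            )
        )
    return SyntheticDatabase(populations=populations)


def null_summaries(
    n_species: int = 40,
    populations_per_species: int = 2,
    intercept: float = 0.0,
    species_sd: float = 0.01,
    residual_sd: float = 0.01,
    seed: int = 0,
):
    """Summary-level generator for calibration studies of the null models.

    Draws ``mean_log_reactivity`` (and correlated growth responses) directly
    at the population level: species intercepts N(0, species_sd), population
    residuals N(0, residual_sd), around a global ``intercept``.  Dimensions
    and growth forms are drawn as in the full generator.  Returns a summary
    frame compatible with the comparative models.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA1B]))
    rows = []
    for i in range(n_species):
        species_id = f"sp{i:03d}"
        form = GROWTH_FORMS[rng.choice(len(GROWTH_FORMS))]
        dim = int(np.clip(2 + rng.poisson(3.3), 2, 15))
        sp_eff = rng.normal(0.0, species_sd)
        for p in range(populations_per_species):
            react = intercept + sp_eff + rng.normal(0.0, residual_sd)
            lam_max = rng.normal(0.0, 0.1)
            rows.append(
                {
                    "population_id": f"{species_id}_pop{p:02d}",
                    "species_id": species_id,
                    "growth_form": form,
                    "matrix_dimension": dim,
                    "n_replicates_used": 1000,
                    "r2_asym": 0.5,
                    "r2_trans": 0.5,
                    "prop_abs_trans": 0.5,
                    "mean_log_lambda_obs": lam_max + react,
                    "mean_log_lambda_max": lam_max,
                    "mean_log_reactivity": react,
                }
            )
    return pd.DataFrame(rows)
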