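"""End-to-end orchestration: generate/ingest -> filter -> simulate ->
partition -> fit -> report.

All stage outputs are pure functions of (config, global seed).  Module seeds
are derived deterministically from the global seed, and per-population
simulation streams are keyed by population id, so results do not depend on
execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import dominant_eigenvalue, mean_matrix
from .exceptions import ValidationError
from .partition import summarize_database
from .simulate import SimulationConfig, simulate_database
from .stats import (
    McmcConfig,
    association_test,
    boom_test,
    fit_contribution_model,
)
from .synthetic import (
    GeneratorConfig,
    apply_inclusion_filters,
    generate_database,
    read_matrix_csv,
    write_matrix_csv,
)

logger = logging.getLogger(__name__)

_MOD = 2**31


def derive_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds from one global seed (all < 2**31)."""
    return {
        "generator": (global_seed * 2654435761 + 1) % _MOD,
        "simulation": (global_seed * 2654435761 + 2) % _MOD,
        "mcmc": (global_seed * 2654435761 + 3) % _MOD,
    }


@dataclass
class PipelineConfig:
    """Pipeline settings: exactly one input mode (synthetic or csv)."""

    input_mode: str = "synthetic"
    csv_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "csv"):
            raise ValidationError(f"input_mode must be 'synthetic' or 'csv', got {self.input_mode!r}")
        if self.input_mode == "csv" and not self.csv_path:
            raise ValidationError("csv input mode requires csv_path")
        if self.input_mode == "synthetic" and self.csv_path:
            raise ValidationError("exactly one input mode: csv_path set in synthetic mode")
        seeds = derive_seeds(self.seed)
        self.generator = dataclasses.replace(self.generator, seed=seeds["generator"])
        self.simulation = dataclasses.replace(self.simulation, seed=seeds["simulation"])
        self.mcmc = dataclasses.replace(self.mcmc, seed=seeds["mcmc"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("input_mode", "csv_path", "out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**_tuplify(raw["generator"]))
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "mcmc" in raw:
            kwargs["mcmc"] = McmcConfig(**raw["mcmc"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "input_mode": self.input_mode,
            "csv_path": self.csv_path,
            "generator": dataclasses.asdict(self.generator),
            "simulation": dataclasses.asdict(self.simulation),
            "mcmc": dataclasses.asdict(self.mcmc),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
        }


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def mean_matrix_growth(populations) -> pd.DataFrame:
    """Per population: log dominant eigenvalue of the element-wise mean matrix."""
    rows = [
        {
            "population_id": pop.population_id,
            "log_lambda_max_mean_matrix": math.log(
                dominant_eigenvalue(mean_matrix(pop.matrices))
            ),
        }
        for pop in populations
    ]
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``cfg.out_dir``.

    Returns a dict with the in-memory artefacts: populations, exclusions,
    metrics table, summary frame, and the five fitted models.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.input_mode == "synthetic":
        db = generate_database(cfg.generator)
        write_matrix_csv(db, out / "database.csv")
    else:
        db = read_matrix_csv(cfg.csv_path)

    kept, exclusions = apply_inclusion_filters(db)
    with open(out / "exclusions.txt", "w") as fh:
        for pop_id, reason in exclusions:
            fh.write(f"{pop_id}\t{reason}\n")
    if not kept:
        raise ValidationError("no population passes the inclusion filters")
    logger.info("retained %d/%d populations", len(kept), len(db.populations))

    metrics = simulate_database(kept, cfg.simulation)
    metrics.to_csv(out / "metrics.csv")

    summaries = summarize_database(kept, metrics)
    summaries = summaries.merge(mean_matrix_growth(kept), on="population_id")
    summaries.to_csv(out / "summaries.csv", index=False)

    fits = {}
    for response in ("r2_asym", "r2_trans", "prop_abs_trans"):
        fits[response] = fit_contribution_model(summaries, response, cfg.mcmc)
        fits[response].to_csv(out / f"fit_{response}.csv")
    fits["boom"] = boom_test(summaries, cfg=cfg.mcmc)
    fits["boom"].to_csv(out / "fit_boom.csv")
    fits["assoc_stochastic"] = association_test(
        summaries, response="mean_log_lambda_obs", cfg=cfg.mcmc
    )
    fits["assoc_stochastic"].to_csv(out / "fit_assoc_stochastic.csv")
    fits["assoc_stable"] = association_test(
        summaries, response="log_lambda_max_mean_matrix", cfg=cfg.mcmc
    )
    fits["assoc_stable"].to_csv(out / "fit_assoc_stable.csv")

    diagnostics = {
        name: {
            "variance_components": fit.variance_components,
            "diagnostics": fit.diagnostics,
            "pmcmc": fit.pmcmc,
            "lrt_stat": fit.lrt_stat,
            "lrt_p": fit.lrt_p,
        }
        for name, fit in fits.items()
    }
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2, sort_keys=True)

    manifest = {
        "config": cfg.to_dict(),
        "seeds": derive_seeds(cfg.seed),
        "n_populations_input": len(db.populations),
        "n_populations_retained": len(kept),
        "n_replicates_total": int(len(metrics)),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    from . import __version__

    manifest["versions"]["transientmpm"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "populations": kept,
        "exclusions": exclusions,
        "metrics": metrics,
        "summaries": summaries,
        "fits": fits,
        "out_dir": out,
    }
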