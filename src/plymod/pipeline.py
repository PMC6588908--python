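"""End-to-end scenario runner.

Composes the full static microsimulation: synthesize the base survey file
and economic donor pool, impute weekly income/welfare/tax by synthetic
matching, age the file to each projection year (disease trends, GREGWT
calibration, uprating), classify the analysis groups, run the matched
counterfactual Monte Carlo, and aggregate national costs and lost GDP.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import published
from .ageing import default_disease_trends, default_uprating_rules, make_benchmarks, project_to_year
from .cohorts import assign_groups, group_summaries
from .costs import load_gdp_inputs, summaries_to_frame, summarize_national_costs
from .counterfactual import (
    DONOR_POOLS,
    CounterfactualSpec,
    estimate_all,
    select_donor_pool,
)
from .imputation import imputation_diagnostics, match_economic_data
from .population import PopulationConfig, generate_base_population, generate_donor_pool

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Run settings for one projection scenario."""

    n_records: int = published.SURVEY_RECORDS_TOTAL
    n_donors: int = 25_000
    years: tuple[int, ...] = published.PROJECTION_YEARS
    n_sims: int = 1000
    ci_level: float = 0.95
    tolerance: float = 1e-6
    bounds: tuple[float, float] = (0.1, 10.0)
    weeks_per_year: float = 52.0
    weight_proportional: bool = True
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario settings: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.years = tuple(int(y) for y in cfg.years)
        cfg.bounds = tuple(cfg.bounds)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


@dataclass
class ScenarioResult:
    table1: pd.DataFrame
    table2: pd.DataFrame
    national_costs: pd.DataFrame
    gdp: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


def _stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage integer seeds derived from the master seed."""
    rng = np.random.default_rng(master_seed)
    names = ["base", "donors", "imputation", "counterfactual"]
    return {name: int(rng.integers(2**31)) for name in names}


def run_scenario(config: ScenarioConfig, seed: int | None = None) -> ScenarioResult:
    """Run the whole pipeline for every configured projection year."""
    master = config.master_seed if seed is None else seed
    seeds = _stage_seeds(master)
    logger.info("scenario %s: master seed %d, stage seeds %s", config.digest(), master, seeds)

    pop_config = PopulationConfig(n_records=config.n_records, n_donors=config.n_donors)
    base = generate_base_population(pop_config, seeds["base"])
    donors = generate_donor_pool(pop_config, seeds["donors"])
    imputed = match_economic_data(base, donors, seeds["imputation"])
    diag = imputation_diagnostics(imputed)
    logger.info(
        "imputation: match rate %.4f, mean fallback depth %.2f",
        diag["match_rate"], diag["mean_fallback_depth"],
    )

    gdp_inputs = load_gdp_inputs()
    trends = default_disease_trends()
    rules = default_uprating_rules()

    table1_rows, table2_rows, cost_summaries, gdp_rows = [], [], [], []
    cf_rng = np.random.default_rng(seeds["counterfactual"])
    calibration_diag = {}
    for year in config.years:
        benchmarks = make_benchmarks(imputed, year)
        projected, cal = project_to_year(
            imputed, benchmarks, trends, rules, year,
            tolerance=config.tolerance, bounds=config.bounds,
        )
        calibration_diag[year] = {
            "iterations": cal.iterations,
            "max_rel_error": cal.max_rel_error,
            "converged": cal.converged,
            "n_bound_hits": cal.n_bound_hits,
        }

        summary = group_summaries(projected).reset_index()
        summary.insert(0, "year", year)
        table1_rows.append(summary)

        groups = assign_groups(projected)
        cases = projected[groups == "nilf_ihd"]
        n_lost_ply = float(cases["weight"].sum())

        year_estimates = {}
        for pool in DONOR_POOLS:
            spec = CounterfactualSpec(
                donor_pool=pool,
                n_sims=config.n_sims,
                ci_level=config.ci_level,
                master_seed=int(cf_rng.integers(2**31)),
                weight_proportional=config.weight_proportional,
            )
            pool_donors = select_donor_pool(projected, pool)
            year_estimates[pool] = estimate_all(spec, cases, pool_donors)

        for pool in ("ft_no_ihd", "pt_no_ihd"):
            for outcome, est in year_estimates[pool].items():
                table2_rows.append(
                    {
                        "year": year,
                        "comparison_pool": pool,
                        "outcome": outcome,
                        "difference": est.point,
                        "ci_lower": est.lower,
                        "ci_upper": est.upper,
                        "n_sims": est.n_sims,
                    }
                )

        cost_summaries.append(
            summarize_national_costs(
                year,
                year_estimates["labour_force_no_ihd"],
                n_lost_ply,
                gdp_inputs[year],
                weeks_per_year=config.weeks_per_year,
            )
        )
        gdp_rows.append(
            {
                "year": year,
                "projected_gdp": gdp_inputs[year].gdp_millions,
                "reference_workforce": gdp_inputs[year].workforce,
                "n_lost_ply": n_lost_ply,
                "lost_gdp": cost_summaries[-1].lost_gdp,
                "potential_gdp_gain_pct": cost_summaries[-1].potential_gdp_gain_pct,
            }
        )

    return ScenarioResult(
        table1=pd.concat(table1_rows, ignore_index=True),
        table2=pd.DataFrame(table2_rows),
        national_costs=summaries_to_frame(cost_summaries),
        gdp=pd.DataFrame(gdp_rows),
        diagnostics={
            "imputation": diag,
            "calibration": calibration_diag,
            "seeds": seeds,
            "config_digest": config.digest(),
        },
    )


def write_outputs(result: ScenarioResult, outdir) -> dict[str, Path]:
    """Write the four output tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("table1", result.table1),
        ("table2", result.table2),
        ("national_costs", result.national_costs),
        ("gdp", result.gdp),
    ):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
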