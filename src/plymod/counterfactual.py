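"""Matched counterfactual Monte Carlo for lost-PLY cost differences.

For every person out of the labour force due to IHD, a counterfactual is
drawn at random with replacement from a donor pool of people without IHD
(full-time employed, part-time employed, or the whole labour force), matched
on sex, age group and highest educational attainment. Each replicate yields
one survey-weighted mean difference (case minus counterfactual) per outcome;
the point estimate is the mean over replicates and the confidence interval
is taken from the replicate percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import _ihd_mask

logger = logging.getLogger(__name__)

OUTCOMES = ("income", "welfare", "tax")
_OUTCOME_COLS = {
    "income": "weekly_income",
    "welfare": "weekly_welfare",
    "tax": "weekly_tax",
}
DONOR_POOLS = ("ft_no_ihd", "pt_no_ihd", "labour_force_no_ihd")
DEFAULT_MATCH_VARS = ("sex", "age_group", "education")


@dataclass
class CounterfactualSpec:
    donor_pool: str = "labour_force_no_ihd"
    match_vars: tuple[str, ...] = DEFAULT_MATCH_VARS
    n_sims: int = 1000
    ci_level: float = 0.95
    master_seed: int = 0
    weight_proportional: bool = True
    case_group: str = "nilf_ihd"

    def validate(self) -> None:
        if self.donor_pool not in DONOR_POOLS:
            raise ValueError(f"unknown donor pool {self.donor_pool!r}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie strictly inside (0, 1)")
        if not self.match_vars:
            raise ValueError("at least one matching variable is required")


@dataclass
class SimulationDraws:
    """Per-replicate weighted mean differences, one column per outcome."""

    draws: pd.DataFrame  # index: replicate, columns: OUTCOMES
    n_sims: int


@dataclass(frozen=True)
class CounterfactualEstimate:
    outcome: str
    donor_pool: str
    point: float
    lower: float
    upper: float
    n_sims: int


def select_donor_pool(df: pd.DataFrame, pool: str) -> pd.DataFrame:
    """Subset an imputed frame to one counterfactual donor pool (no IHD)."""
    no_ihd = ~_ihd_mask(df)
    lfs = df["labour_force_status"]
    if pool == "ft_no_ihd":
        mask = (lfs == "employed_ft") & no_ihd
    elif pool == "pt_no_ihd":
        mask = (lfs == "employed_pt") & no_ihd
    elif pool == "labour_force_no_ihd":
        # Whole labour force: full-time, part-time, and unemployed job seekers.
        in_lf = lfs.isin(
            ["employed_ft", "employed_pt", "unemployed_seeking_ft", "unemployed_seeking_pt"]
        )
        mask = in_lf & no_ihd
    else:
        raise ValueError(f"unknown donor pool {pool!r}")
    return df[mask]


class _MatchCells:
    """Case-to-donor-cell resolution with drop-last-variable fallback."""

    def __init__(
        self,
        cases: pd.DataFrame,
        donors: pd.DataFrame,
        match_vars: tuple[str, ...],
        weight_proportional: bool,
    ):
        if len(cases) == 0:
            raise ValueError("no case records")
        if len(donors) == 0:
            raise ValueError("donor pool is empty")
        donor_keys = {
            k: [tuple(t) for t in zip(*(donors[v].to_numpy() for v in match_vars[:k]))]
            for k in range(len(match_vars), 0, -1)
        }
        donor_index: dict[int, dict] = {}
        self.cells: dict[tuple, dict] = {}
        self.case_cell: list[tuple] = []
        unmatched = []
        for i in range(len(cases)):
            cell = None
            for k in range(len(match_vars), 0, -1):
                key = tuple(cases.iloc[i][v] for v in match_vars[:k])
                if k not in donor_index:
                    idx: dict[tuple, list[int]] = {}
                    for j, dk in enumerate(donor_keys[k]):
                        idx.setdefault(dk, []).append(j)
                    donor_index[k] = idx
                if key in donor_index[k]:
                    cell = (k, key)
                    break
            if cell is None:
                unmatched.append(tuple(cases.iloc[i][v] for v in match_vars))
                continue
            self.case_cell.append(cell)
            if cell not in self.cells:
                pos = np.asarray(donor_index[cell[0]][cell[1]])
                w = donors["weight"].to_numpy()[pos].astype(float)
                p = w / w.sum() if weight_proportional else np.full(len(pos), 1 / len(pos))
                self.cells[cell] = {"pos": pos, "cum": np.cumsum(p)}
        if unmatched:
            raise ValueError(
                f"no donors found for case cells (even at sex level): {sorted(set(unmatched))}"
            )
        # Group case positions by cell for vectorised sampling.
        self.cell_members: dict[tuple, np.ndarray] = {}
        for cell in self.cells:
            members = [i for i, c in enumerate(self.case_cell) if c == cell]
            self.cell_members[cell] = np.asarray(members)

    def assign(self, u: np.ndarray) -> np.ndarray:
        """Map uniforms (one per case) to donor positional indices."""
        out = np.empty(len(u), dtype=int)
        for cell, members in self.cell_members.items():
            c = self.cells[cell]
            j = np.searchsorted(c["cum"], u[members], side="left")
            out[members] = c["pos"][np.clip(j, 0, len(c["pos"]) - 1)]
        return out


def draw_counterfactual_set(
    cases: pd.DataFrame,
    donors: pd.DataFrame,
    match_vars: tuple[str, ...] = DEFAULT_MATCH_VARS,
    seed: int = 0,
    weight_proportional: bool = True,
) -> np.ndarray:
    """One counterfactual assignment: donor positional index per case.

    Donors are sampled with replacement within each case's most specific
    non-empty match cell, with probability proportional to donor survey
    weight (or uniformly). Deterministic given ``seed``.
    """
    cells = _MatchCells(cases, donors, tuple(match_vars), weight_proportional)
    rng = np.random.default_rng(seed)
    return cells.assign(rng.random(len(cases)))


def replicate_difference(
    cases: pd.DataFrame,
    donors: pd.DataFrame,
    assignment: np.ndarray,
    outcome: str,
) -> float:
    """Case-weighted mean of (case value - assigned donor value)."""
    col = _OUTCOME_COLS[outcome]
    w = cases["weight"].to_numpy(dtype=float)
    diff = cases[col].to_numpy(dtype=float) - donors[col].to_numpy(dtype=float)[assignment]
    return float((w * diff).sum() / w.sum())


def run_simulations(
    spec: CounterfactualSpec, cases: pd.DataFrame, donors: pd.DataFrame
) -> SimulationDraws:
    """Run the replicate Monte Carlo; one weighted difference per outcome
    per replicate.

    Replicate ``k`` uses a sub-seed spawned deterministically from the
    master seed, so results are reproducible and independent of execution
    order.
    """
    spec.validate()
    cells = _MatchCells(cases, donors, tuple(spec.match_vars), spec.weight_proportional)
    w = cases["weight"].to_numpy(dtype=float)
    wsum = w.sum()
    case_vals = {o: cases[_OUTCOME_COLS[o]].to_numpy(dtype=float) for o in OUTCOMES}
    donor_vals = {o: donors[_OUTCOME_COLS[o]].to_numpy(dtype=float) for o in OUTCOMES}
    case_part = {o: float((w * case_vals[o]).sum() / wsum) for o in OUTCOMES}

    seeds = np.random.SeedSequence(spec.master_seed).spawn(spec.n_sims)
    rows = np.empty((spec.n_sims, len(OUTCOMES)))
    for k in range(spec.n_sims):
        rng = np.random.default_rng(seeds[k])
        assignment = cells.assign(rng.random(len(cases)))
        for j, o in enumerate(OUTCOMES):
            rows[k, j] = case_part[o] - float((w * donor_vals[o][assignment]).sum() / wsum)
    draws = pd.DataFrame(rows, columns=list(OUTCOMES))
    draws.index.name = "replicate"
    return SimulationDraws(draws=draws, n_sims=spec.n_sims)


def percentile_ci(draws, level: float = 0.95) -> tuple[float, float]:
    """Nearest-rank percentile interval of the replicate draws.

    With 1000 draws at the 95% level this is the 25th and 975th order
    statistic.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie strictly inside (0, 1)")
    values = np.sort(np.asarray(draws, dtype=float))
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 draws for a percentile interval")
    alpha = 1.0 - level
    # tiny slack so e.g. 0.025 * 1000 = 25.000000000000004 still ranks 25
    lo_rank = max(math.ceil(alpha / 2 * n - 1e-9), 1)
    hi_rank = max(math.ceil((1 - alpha / 2) * n - 1e-9), 1)
    return float(values[lo_rank - 1]), float(values[hi_rank - 1])


def estimate(
    sims: SimulationDraws, outcome: str, donor_pool: str, level: float = 0.95
) -> CounterfactualEstimate:
    """Point estimate (mean of draws) and percentile CI for one outcome."""
    values = sims.draws[outcome].to_numpy()
    lower, upper = percentile_ci(values, level)
    return CounterfactualEstimate(
        outcome=outcome,
        donor_pool=donor_pool,
        point=float(values.mean()),
        lower=lower,
        upper=upper,
        n_sims=sims.n_sims,
    )


def estimate_all(
    spec: CounterfactualSpec, cases: pd.DataFrame, donors: pd.DataFrame
) -> dict[str, CounterfactualEstimate]:
    """Run the Monte Carlo and summarise every outcome."""
    sims = run_simulations(spec, cases, donors)
    return {
        o: estimate(sims, o, spec.donor_pool, spec.ci_level) for o in OUTCOMES
    }
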