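"""National cost aggregation: annual dollar totals, lost GDP, derived ratios.

Weekly counterfactual differences become annual national totals by scaling
with the weighted number of people with lost PLYs and a 52-week year;
lost GDP uses a proportional-labour decomposition (GDP times lost workers
over the reference workforce); small helpers compute the percent-change and
share statistics used throughout the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from .counterfactual import CounterfactualEstimate

WEEKS_PER_YEAR = 52.0
NATIONAL_POOL = "labour_force_no_ihd"


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, applied only at display/report time."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GDPInputs:
    """Projected GDP (AU$ millions, 2013 dollars) and the reference workforce
    (employed persons) for one projection year."""

    year: int
    gdp_millions: float
    workforce: float

    def __post_init__(self):
        if self.gdp_millions <= 0 or self.workforce <= 0:
            raise ValueError("GDP and workforce must be positive")


def load_gdp_inputs(path=None) -> dict[int, GDPInputs]:
    """Load the packaged (or user-supplied) GDP/workforce table."""
    if path is None:
        path = resources.files("plymod").joinpath("data/gdp_inputs.csv")
    df = pd.read_csv(path)
    return {
        int(r.year): GDPInputs(int(r.year), float(r.gdp_millions), float(r.workforce))
        for r in df.itertuples()
    }


@dataclass(frozen=True)
class CostEstimate:
    """Annual national cost magnitude in AU$ millions with percentile CI."""

    point: float
    lower: float
    upper: float


def national_cost(
    estimate: CounterfactualEstimate,
    n_lost_ply: float,
    weeks_per_year: float = WEEKS_PER_YEAR,
) -> CostEstimate:
    """Annual national cost from a weekly per-person difference.

    ``|weekly difference| x n_lost_ply x weeks_per_year / 1e6``; the CI
    endpoints pass through the same monotone map (and are reordered when the
    map is decreasing). Requires the whole-labour-force donor pool, which is
    what the national totals are defined against.
    """
    if estimate.donor_pool != NATIONAL_POOL:
        raise ValueError(
            f"national costs require the {NATIONAL_POOL!r} pool, got {estimate.donor_pool!r}"
        )
    if n_lost_ply < 0:
        raise ValueError("n_lost_ply must be non-negative")
    scale = n_lost_ply * weeks_per_year / 1e6
    sign = -1.0 if estimate.point < 0 else 1.0
    lo, hi = sorted((estimate.lower * sign * scale, estimate.upper * sign * scale))
    return CostEstimate(point=estimate.point * sign * scale, lower=lo, upper=hi)


def lost_gdp(n_lost_ply: float, gdp_inputs: GDPInputs) -> float:
    """Lost GDP (AU$ millions): proportional-labour share of projected GDP."""
    if n_lost_ply < 0:
        raise ValueError("n_lost_ply must be non-negative")
    return gdp_inputs.gdp_millions * n_lost_ply / gdp_inputs.workforce


def potential_gdp_gain_pct(lost: float, gdp: float) -> float:
    """Percent of GDP recovered if the lost workers re-entered the labour force."""
    if gdp <= 0:
        raise ValueError("gdp must be positive")
    return 100.0 * lost / gdp


def percent_change(earlier: float, later: float) -> float:
    """100 x (later - earlier) / earlier."""
    if earlier == 0:
        raise ValueError("earlier value must be non-zero")
    return 100.0 * (later - earlier) / earlier


def share_pct(part: float, whole: float) -> float:
    """100 x part / whole."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


@dataclass(frozen=True)
class NationalCostSummary:
    year: int
    n_lost_ply: float
    lost_income: CostEstimate
    extra_welfare: CostEstimate
    lost_tax: CostEstimate
    lost_gdp: float
    potential_gdp_gain_pct: float


def summarize_national_costs(
    year: int,
    estimates: dict[str, CounterfactualEstimate],
    n_lost_ply: float,
    gdp_inputs: GDPInputs,
    weeks_per_year: float = WEEKS_PER_YEAR,
) -> NationalCostSummary:
    """Assemble one year's national cost summary from whole-labour-force
    counterfactual estimates keyed by outcome (income/welfare/tax)."""
    gdp_loss = lost_gdp(n_lost_ply, gdp_inputs)
    return NationalCostSummary(
        year=year,
        n_lost_ply=n_lost_ply,
        lost_income=national_cost(estimates["income"], n_lost_ply, weeks_per_year),
        extra_welfare=national_cost(estimates["welfare"], n_lost_ply, weeks_per_year),
        lost_tax=national_cost(estimates["tax"], n_lost_ply, weeks_per_year),
        lost_gdp=gdp_loss,
        potential_gdp_gain_pct=potential_gdp_gain_pct(gdp_loss, gdp_inputs.gdp_millions),
    )


def summaries_to_frame(summaries: list[NationalCostSummary]) -> pd.DataFrame:
    """Flatten national cost summaries to one row per year."""
    rows = []
    for s in summaries:
        row = {"year": s.year, "n_lost_ply": s.n_lost_ply}
        for name in ("lost_income", "extra_welfare", "lost_tax"):
            est: CostEstimate = getattr(s, name)
            row[name] = est.point
            row[f"{name}_lower"] = est.lower
            row[f"{name}_upper"] = est.upper
        row["lost_gdp"] = s.lost_gdp
        row["potential_gdp_gain_pct"] = s.potential_gdp_gain_pct
        rows.append(row)
    return pd.DataFrame(rows)
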