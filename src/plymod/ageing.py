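"""Static ageing: survey-weight calibration, disease trends, uprating.

The base file is "aged" to a projection year in three steps:

1. reweight the file so age-group x sex population totals and full/part-time
   employment counts hit the year's benchmarks (GREGWT-style chi-square
   calibration with weight-ratio bounds and iterative re-restriction);
2. scale weights within each sex x age-group stratum so chronic-disease
   prevalence follows its proportional annual trend, frozen after 2023;
3. uprate weekly dollar amounts from 2013: income and tax at 1%/yr real,
   welfare at zero real growth.

Trend adjustment runs before calibration so the reweighting sees the target
year's disease mix; uprating is a pure multiplicative rescale of dollar
columns and commutes with both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published
from .population import AGE_GROUPS, IHD_CONDITIONS, SEXES

logger = logging.getLogger(__name__)

TREND_DISEASES = ("stroke", "cancer", "ihd", "type2_diabetes", "copd")
#: Prevalence trends stabilise after this calendar year.
TREND_STABILISATION_YEAR = 2023
BASE_POPULATION_YEAR = 2009
ECONOMIC_BASE_YEAR = 2013

_CONDITION_TO_TREND = {c: "ihd" for c in IHD_CONDITIONS}
_CONDITION_TO_TREND.update(
    {"stroke": "stroke", "cancer": "cancer", "type2_diabetes": "type2_diabetes", "copd": "copd"}
)


# ---------------------------------------------------------------------------
# Benchmarks


@dataclass
class BenchmarkSet:
    """Calibration targets for one projection year.

    ``cells`` has one row per (age_group, sex) with the target population
    total and the target full-time / part-time employment rates.
    """

    year: int
    cells: pd.DataFrame  # columns: age_group, sex, population, ft_rate, pt_rate

    def validate(self) -> None:
        required = {"age_group", "sex", "population", "ft_rate", "pt_rate"}
        if not required <= set(self.cells.columns):
            raise ValueError(f"benchmark cells need columns {sorted(required)}")
        c = self.cells
        if (c["population"] <= 0).any():
            raise ValueError("benchmark population totals must be positive")
        if ((c[["ft_rate", "pt_rate"]] < 0) | (c[["ft_rate", "pt_rate"]] > 1)).any().any():
            raise ValueError("employment rates must lie in [0, 1]")
        if ((c["ft_rate"] + c["pt_rate"]) > 1 + 1e-12).any():
            raise ValueError("ft_rate + pt_rate must not exceed 1")

    def to_csv(self, path) -> None:
        self.cells.assign(year=self.year).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BenchmarkSet":
        df = pd.read_csv(path)
        year = int(df["year"].iloc[0])
        bm = cls(year=year, cells=df.drop(columns="year"))
        bm.validate()
        return bm


def make_benchmarks(records: pd.DataFrame, year: int) -> BenchmarkSet:
    """Default benchmarks: the base file's own margins grown to ``year``.

    Population totals per (age_group, sex) cell grow with the published
    45-64 population series; full-time and part-time employment rates drift
    with the published aggregate employment shares. This emulates an external
    population/labour-force projection on the synthetic file's scale.
    """
    if year not in published.PROJECTION_YEARS:
        raise ValueError(f"no projection benchmarks for year {year}")
    pop_factor = published.population_growth_factor(year)
    ft_factor = published.full_time_share(year) / published.full_time_share(2015)
    pt_factor = published.part_time_share(year) / published.part_time_share(2015)

    rows = []
    for ag in AGE_GROUPS:
        for sex in SEXES:
            sub = records[(records["age_group"] == ag) & (records["sex"] == sex)]
            total = sub["weight"].sum()
            if total == 0:
                raise ValueError(f"base file has no records in cell ({ag}, {sex})")
            ft_rate = sub.loc[sub["labour_force_status"] == "employed_ft", "weight"].sum() / total
            pt_rate = sub.loc[sub["labour_force_status"] == "employed_pt", "weight"].sum() / total
            rows.append(
                {
                    "age_group": ag,
                    "sex": sex,
                    "population": total * pop_factor,
                    "ft_rate": min(ft_rate * ft_factor, 0.98),
                    "pt_rate": min(pt_rate * pt_factor, 1.0 - min(ft_rate * ft_factor, 0.98)),
                }
            )
    bm = BenchmarkSet(year=year, cells=pd.DataFrame(rows))
    bm.validate()
    return bm


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationResult:
    weights: np.ndarray
    iterations: int
    max_rel_error: float
    converged: bool
    n_bound_hits: int
    margins: pd.DataFrame = field(repr=False, default=None)


def _max_rel_error(achieved: np.ndarray, targets: np.ndarray) -> float:
    if targets.size == 0:
        return 0.0
    scale = np.where(np.abs(targets) > 0, np.abs(targets), 1.0)
    return float(np.max(np.abs(achieved - targets) / scale))


def calibrate_weights(
    d: np.ndarray,
    X: np.ndarray,
    targets: np.ndarray,
    bounds: tuple[float, float] = (0.1, 10.0),
    tolerance: float = 1e-6,
    max_iter: int = 50,
) -> CalibrationResult:
    """Chi-square (generalised regression) calibration with bounded ratios.

    Finds weights ``w`` minimising ``sum (w-d)^2 / d`` subject to
    ``X' w = targets``; the unrestricted solution is the linear form
    ``w = d * (1 + X @ lam)``. Weights pushed outside
    ``[lo*d, hi*d]`` are truncated to the bound and frozen, and the linear
    system is re-solved on the free records against the residual targets
    until no new truncations occur (the iterative restricted loop of
    GREGWT-family calibration).
    """
    d = np.asarray(d, dtype=float)
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    lo, hi = bounds
    if not lo < 1 < hi:
        raise ValueError("bounds must bracket 1 (lo < 1 < hi)")
    w = d.copy()
    fixed = np.zeros(len(d), dtype=bool)
    iterations = 0
    for _ in range(max_iter):
        err = _max_rel_error(X.T @ w, targets)
        if err <= tolerance:
            break
        iterations += 1
        free = ~fixed
        Xf, df_ = X[free], d[free]
        A = Xf.T @ (Xf * df_[:, None])
        resid = targets - X[fixed].T @ w[fixed] - Xf.T @ df_
        lam, *_ = np.linalg.lstsq(A, resid, rcond=None)
        w_free = df_ * (1.0 + Xf @ lam)
        lo_b, hi_b = lo * df_, hi * df_
        hit = (w_free < lo_b) | (w_free > hi_b)
        w[free] = np.clip(w_free, lo_b, hi_b)
        if not hit.any():
            continue  # re-check error; loop exits when within tolerance
        fixed_idx = np.flatnonzero(free)[hit]
        fixed[fixed_idx] = True
        logger.debug("calibration: froze %d weights at bounds", hit.sum())
    err = _max_rel_error(X.T @ w, targets)
    converged = err <= tolerance
    if not converged:
        logger.warning("calibration did not converge: max rel error %.3e", err)
    return CalibrationResult(
        weights=w,
        iterations=iterations,
        max_rel_error=err,
        converged=converged,
        n_bound_hits=int(fixed.sum()),
    )


def _benchmark_design(records: pd.DataFrame, benchmarks: BenchmarkSet):
    """Design matrix and target vector: population totals plus full-time and
    part-time employment counts per (age_group, sex) cell."""
    cells = benchmarks.cells
    n = len(records)
    cols, targets, names = [], [], []
    ag = records["age_group"].to_numpy()
    sex = records["sex"].to_numpy()
    lfs = records["labour_force_status"].to_numpy()
    for _, cell in cells.iterrows():
        in_cell = (ag == cell["age_group"]) & (sex == cell["sex"])
        specs = [
            ("population", in_cell.astype(float), cell["population"]),
            ("ft_count", (in_cell & (lfs == "employed_ft")).astype(float),
             cell["ft_rate"] * cell["population"]),
            ("pt_count", (in_cell & (lfs == "employed_pt")).astype(float),
             cell["pt_rate"] * cell["population"]),
        ]
        for kind, col, target in specs:
            if target > 0 and not col.any():
                raise ValueError(
                    f"infeasible margin: no records for {kind} in cell "
                    f"({cell['age_group']}, {cell['sex']}) with positive target"
                )
            if target == 0 and not col.any():
                continue  # vacuous margin
            cols.append(col)
            targets.append(target)
            names.append(f"{kind}[{cell['age_group']},{cell['sex']}]")
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    return X, np.asarray(targets, dtype=float), names


def gregwt_calibrate(
    records: pd.DataFrame,
    benchmarks: BenchmarkSet,
    tolerance: float = 1e-6,
    max_iter: int = 50,
    bounds: tuple[float, float] = (0.1, 10.0),
) -> CalibrationResult:
    """Calibrate survey weights to a year's population/employment benchmarks."""
    benchmarks.validate()
    X, targets, names = _benchmark_design(records, benchmarks)
    result = calibrate_weights(
        records["weight"].to_numpy(), X, targets, bounds=bounds,
        tolerance=tolerance, max_iter=max_iter,
    )
    achieved = X.T @ result.weights
    result.margins = pd.DataFrame(
        {"margin": names, "target": targets, "achieved": achieved}
    )
    logger.info(
        "calibration year %s: %d iterations, max rel error %.3e, converged=%s",
        benchmarks.year, result.iterations, result.max_rel_error, result.converged,
    )
    return result


# ---------------------------------------------------------------------------
# Disease trends


def default_disease_trends() -> pd.DataFrame:
    """Annual proportional prevalence multipliers by disease, sex, age group.

    Directions follow the national burden-of-disease trend study the model
    draws on: IHD declining in both sexes, cancer near-stable, type 2
    diabetes rising, COPD stable in men and rising in women, stroke slowly
    declining. Magnitudes are scenario defaults.
    """
    annual = {
        "ihd": {"male": 0.99, "female": 0.99},
        "cancer": {"male": 1.0, "female": 1.0},
        "stroke": {"male": 0.995, "female": 0.995},
        "type2_diabetes": {"male": 1.02, "female": 1.02},
        "copd": {"male": 1.0, "female": 1.01},
    }
    rows = [
        {"disease": disease, "sex": sex, "age_group": ag, "annual_multiplier": m}
        for disease, by_sex in annual.items()
        for sex, m in by_sex.items()
        for ag in AGE_GROUPS
    ]
    return pd.DataFrame(rows)


def trend_exponent(base_year: int, target_year: int) -> int:
    """Years of trend applied: frozen at the stabilisation year."""
    return max(min(target_year, TREND_STABILISATION_YEAR) - base_year, 0)


def apply_disease_trend(
    records: pd.DataFrame,
    trends: pd.DataFrame,
    base_year: int = BASE_POPULATION_YEAR,
    target_year: int | None = None,
) -> pd.DataFrame:
    """Adjust weights so disease prevalence follows its trend within strata.

    Within each sex x age-group stratum, the weight of records whose main
    condition maps to a trended disease is scaled by
    ``multiplier ** (min(target_year, 2023) - base_year)``; all remaining
    records are rescaled so the stratum's total weight is conserved.
    """
    if target_year is None:
        raise ValueError("target_year is required")
    if target_year < base_year:
        raise ValueError("target_year must be >= base_year")
    out = records.copy()
    years = trend_exponent(base_year, target_year)
    trend_map = {
        (r.disease, r.sex, r.age_group): r.annual_multiplier
        for r in trends.itertuples()
    }
    disease_class = out["main_condition"].map(_CONDITION_TO_TREND)
    w = out["weight"].to_numpy(dtype=float).copy()
    for (sex, ag), idx in out.groupby(["sex", "age_group"], observed=True).groups.items():
        pos = out.index.get_indexer(idx)
        stratum_total = w[pos].sum()
        trended = np.zeros(len(pos), dtype=bool)
        old_trend_weight = new_trend_weight = 0.0
        dc = disease_class.iloc[pos]
        for disease in TREND_DISEASES:
            mult = trend_map.get((disease, sex, ag))
            if mult is None:
                continue
            if mult <= 0:
                raise ValueError(f"non-positive multiplier for {disease}")
            mask = (dc == disease).to_numpy()
            if not mask.any():
                continue
            ratio = mult**years
            old = w[pos][mask].sum()
            old_trend_weight += old
            new_trend_weight += old * ratio
            w[pos[mask]] *= ratio
            trended |= mask
        if new_trend_weight > stratum_total + 1e-9:
            raise ValueError(
                f"trend implies prevalence > 1 in stratum ({sex}, {ag})"
            )
        rest = pos[~trended]
        old_rest = stratum_total - old_trend_weight
        new_rest = stratum_total - new_trend_weight
        if old_rest <= 0:
            if abs(new_rest) > 1e-9 * stratum_total:
                raise ValueError(
                    f"cannot conserve stratum ({sex}, {ag}): no untrended records"
                )
            continue
        w[rest] *= new_rest / old_rest
    out["weight"] = w
    return out


# ---------------------------------------------------------------------------
# Uprating


VALID_COMPONENTS = ("income", "welfare", "tax")
_COMPONENT_COLS = {
    "income": "weekly_income",
    "welfare": "weekly_welfare",
    "tax": "weekly_tax",
}


@dataclass(frozen=True)
class UpratingRule:
    """Real annual growth applied to one dollar component from 2013."""

    component: str
    annual_rate: float
    base_year: int = ECONOMIC_BASE_YEAR

    def __post_init__(self):
        if self.component not in VALID_COMPONENTS:
            raise ValueError(f"unknown uprating component {self.component!r}")
        if self.annual_rate < 0:
            raise ValueError("uprating rate must be non-negative")

    def factor(self, target_year: int) -> float:
        return (1.0 + self.annual_rate) ** (target_year - self.base_year)


def default_uprating_rules() -> tuple[UpratingRule, ...]:
    """Income and tax grow 1%/yr in real terms; welfare has zero real growth."""
    return (
        UpratingRule("income", 0.01),
        UpratingRule("tax", 0.01),
        UpratingRule("welfare", 0.0),
    )


def uprate_economics(
    records: pd.DataFrame,
    rules: tuple[UpratingRule, ...] | None = None,
    target_year: int | None = None,
) -> pd.DataFrame:
    """Index dollar amounts from the 2013 economic base to ``target_year``."""
    if target_year is None:
        raise ValueError("target_year is required")
    rules = default_uprating_rules() if rules is None else rules
    out = records.copy()
    for rule in rules:
        if target_year < rule.base_year:
            raise ValueError("target_year must be >= the economic base year")
        col = _COMPONENT_COLS[rule.component]
        if col in out.columns:
            out[col] = out[col] * rule.factor(target_year)
    return out


# ---------------------------------------------------------------------------
# Composition


def project_to_year(
    records: pd.DataFrame,
    benchmarks: BenchmarkSet,
    trends: pd.DataFrame | None = None,
    rules: tuple[UpratingRule, ...] | None = None,
    year: int | None = None,
    tolerance: float = 1e-6,
    bounds: tuple[float, float] = (0.1, 10.0),
    max_iter: int = 50,
) -> tuple[pd.DataFrame, CalibrationResult]:
    """Age the imputed base file to one projection year.

    Composition: disease-trend adjustment, then benchmark calibration, then
    economic uprating. Returns the projected frame (``attrs["year"]`` set)
    and the calibration diagnostics.
    """
    year = benchmarks.year if year is None else year
    if year != benchmarks.year:
        raise ValueError("year does not match the benchmark set")
    trends = default_disease_trends() if trends is None else trends
    staged = apply_disease_trend(records, trends, target_year=year)
    cal = gregwt_calibrate(
        staged, benchmarks, tolerance=tolerance, max_iter=max_iter, bounds=bounds
    )
    staged = staged.copy()
    staged["weight"] = cal.weights
    staged = uprate_economics(staged, rules, target_year=year)
    staged.attrs["year"] = year
    return staged, cal
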