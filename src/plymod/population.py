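"""Synthetic survey base population and economic donor pool.

The base file emulates a pooled national disability survey of 45-64 year
olds: demographics, a six-state labour-force status with the "own ill-health
or disability" not-in-labour-force reason, a main chronic condition code, and
positive survey weights. The donor pool emulates a static tax/transfer
microsimulation output: the ten matching variables plus weekly income,
welfare and tax in 2013 dollars.

Group shares and the income/welfare/tax laws are anchored to the published
2015 weighted table: each analysis group's share defaults to its printed
population share, employed incomes are log-normal with the printed median,
and the out-of-labour-force-due-to-ill-health segment receives a disability
pension style payment making up ~77% of its income.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import published

logger = logging.getLogger(__name__)

AGE_GROUPS = ("45-49", "50-54", "55-59", "60-64")
SEXES = ("male", "female")
LABOUR_FORCE_STATUSES = (
    "employed_ft",
    "employed_pt",
    "unemployed_seeking_ft",
    "unemployed_seeking_pt",
    "nilf",
    "not_applicable",
)
NILF_REASONS = ("own_ill_health", "other", "not_applicable")
CONDITIONS = (
    "heart_disease",
    "angina",
    "myocardial_infarction",
    "stroke",
    "cancer",
    "type2_diabetes",
    "copd",
    "other",
    "none",
)
IHD_CONDITIONS = ("heart_disease", "angina", "myocardial_infarction")
NON_IHD_CONDITIONS = ("stroke", "cancer", "type2_diabetes", "copd", "other")
EDUCATION_LEVELS = ("no_qualification", "certificate", "diploma", "bachelor_plus")
INCOME_UNIT_TYPES = ("single", "couple_no_children", "couple_with_children")
HOURS_BANDS = ("0", "1-34", "35+")
ANALYSIS_GROUPS = ("ft_no_ihd", "ft_ihd", "pt_no_ihd", "pt_ihd", "nilf_ihd", "other")

PERSON_COLUMNS = (
    "person_id", "age", "age_group", "sex", "income_unit_type", "education",
    "labour_force_status", "nilf_reason", "main_condition", "hours_per_week",
    "home_owner", "receives_age_pension", "receives_dsp", "income_quintile",
    "weight",
)
DONOR_COLUMNS = (
    "donor_id", "sex", "age_group", "income_unit_type", "income_quintile",
    "receives_age_pension", "receives_dsp", "labour_force_status",
    "hours_band", "education", "home_owner", "weekly_income",
    "weekly_welfare", "weekly_tax",
)

# Welfare as a fraction of total income for the ill-health NILF segment:
# 321.87 / 415.83 of the published 2015 medians.
NILF_WELFARE_INCOME_RATIO = (
    published.MEDIAN_WELFARE_NILF_IHD_2015 / published.MEDIAN_INCOME_2015["nilf_ihd"]
)

# Stylised two-bracket weekly tax scale anchored so the full-time and
# part-time median incomes map exactly onto the published median taxes.
_T1 = published.MEDIAN_INCOME_2015["pt_no_ihd"] - published.MEDIAN_TAX_2015["pt_no_ihd"] / 0.19
_T2 = 700.0
_R2 = (
    published.MEDIAN_TAX_2015["ft_no_ihd"] - 0.19 * (_T2 - _T1)
) / (published.MEDIAN_INCOME_2015["ft_no_ihd"] - _T2)
DEFAULT_TAX_BRACKETS = ((_T1, 0.19), (_T2, _R2))


class ConfigurationError(ValueError):
    """Raised when a population configuration violates its invariants."""


class SchemaError(ValueError):
    """Raised when a record file violates the person/donor schema."""


@dataclass(frozen=True)
class IncomeLaw:
    """Right-skewed weekly income law anchored on its median.

    ``lognormal`` uses ``exp(N(log(median), shape))``; ``normal`` uses
    ``N(median, shape)`` clipped at zero (median == mean up to truncation).
    """

    dist: str
    median: float
    shape: float

    def validate(self) -> None:
        if self.dist not in ("lognormal", "normal"):
            raise ConfigurationError(f"unknown income law {self.dist!r}")
        if self.median < 0 or self.shape <= 0:
            raise ConfigurationError("income law requires median >= 0 and shape > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "lognormal":
            return np.exp(rng.normal(np.log(self.median), self.shape, n))
        return np.clip(rng.normal(self.median, self.shape, n), 0.0, None)


def _default_group_shares() -> dict[str, float]:
    total = published.POPULATION_TOTALS[2015]
    shares = {g: published.GROUP_COUNTS[g][2015] / total for g in published.GROUP_COUNTS}
    shares["other"] = 1.0 - sum(shares.values())
    return shares


def _default_income_laws() -> dict[str, IncomeLaw]:
    # Log-sigma for employed segments chosen so the mean/median ratio matches
    # the published 2015 full-time and part-time moments.
    m = published.MEDIAN_INCOME_2015
    mu = published.MEAN_INCOME_2015
    sig_ft = float(np.sqrt(2 * np.log(mu["ft_no_ihd"] / m["ft_no_ihd"])))
    sig_pt = float(np.sqrt(2 * np.log(mu["pt_no_ihd"] / m["pt_no_ihd"])))
    return {
        "ft": IncomeLaw("lognormal", m["ft_no_ihd"], sig_ft),
        "pt": IncomeLaw("lognormal", m["pt_no_ihd"], sig_pt),
        # NILF income is welfare-led: the welfare law below implies income.
        "nilf": IncomeLaw("normal", published.MEDIAN_WELFARE_NILF_IHD_2015, 117.62),
        "unemployed": IncomeLaw("normal", 260.0, 90.0),
    }


@dataclass
class PopulationConfig:
    """Generator settings for the base population and donor pool.

    Group shares default to the published 2015 weighted shares; income laws
    are keyed by labour-force segment because the economic donor pool (a
    tax/transfer model output) carries no disease information.
    """

    n_records: int = published.SURVEY_RECORDS_TOTAL
    n_donors: int = 25_000
    group_shares: dict[str, float] = field(default_factory=_default_group_shares)
    income_laws: dict[str, IncomeLaw] = field(default_factory=_default_income_laws)
    nilf_welfare_income_ratio: float = NILF_WELFARE_INCOME_RATIO
    tax_brackets: tuple = DEFAULT_TAX_BRACKETS
    weight_range: tuple[float, float] = (50.0, 150.0)
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_records < 0 or self.n_donors < 0:
            raise ConfigurationError("record counts must be non-negative")
        if set(self.group_shares) != set(ANALYSIS_GROUPS):
            raise ConfigurationError(
                f"group_shares must cover exactly {sorted(ANALYSIS_GROUPS)}"
            )
        total = sum(self.group_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"group shares sum to {total!r}, expected 1")
        if any(s < 0 for s in self.group_shares.values()):
            raise ConfigurationError("group shares must be non-negative")
        for law in self.income_laws.values():
            law.validate()
        if not 0 < self.nilf_welfare_income_ratio <= 1:
            raise ConfigurationError("nilf welfare/income ratio must be in (0, 1]")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ConfigurationError("weight range must be positive and ordered")


def tax_from_income(income: np.ndarray, brackets=DEFAULT_TAX_BRACKETS) -> np.ndarray:
    """Weekly tax (incl. Medicare-levy style component) from weekly income."""
    income = np.asarray(income, dtype=float)
    tax = np.zeros_like(income)
    edges = [b[0] for b in brackets] + [np.inf]
    for (lo, rate), hi in zip(brackets, edges[1:]):
        tax += rate * np.clip(income - lo, 0.0, hi - lo)
    return tax


def hours_band(hours) -> np.ndarray:
    """Map weekly hours to the matching bands 0 / 1-34 / 35+."""
    h = np.asarray(hours, dtype=float)
    return np.select([h <= 0, h < 35], ["0", "1-34"], default="35+")


def _age_group_of(age: np.ndarray) -> np.ndarray:
    idx = np.clip((np.asarray(age) - 45) // 5, 0, 3).astype(int)
    return np.asarray(AGE_GROUPS, dtype=object)[idx]


def generate_base_population(config: PopulationConfig, seed: int) -> pd.DataFrame:
    """Generate a synthetic survey base file of 45-64 year olds.

    Deterministic given ``(config, seed)``. Empirical analysis-group shares
    converge to ``config.group_shares`` as ``n_records`` grows.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_records
    groups = np.asarray(ANALYSIS_GROUPS, dtype=object)
    shares = np.array([config.group_shares[g] for g in ANALYSIS_GROUPS])
    group = rng.choice(groups, size=n, p=shares / shares.sum())

    age = rng.integers(45, 65, n)
    sex = rng.choice(np.asarray(SEXES, dtype=object), size=n)
    education = rng.choice(
        np.asarray(EDUCATION_LEVELS, dtype=object), size=n, p=[0.30, 0.35, 0.20, 0.15]
    )
    income_unit = rng.choice(
        np.asarray(INCOME_UNIT_TYPES, dtype=object), size=n, p=[0.25, 0.45, 0.30]
    )
    home_owner = rng.random(n) < 0.70

    # Residual ("other") group mixes unemployment, NILF for non-health
    # reasons, NILF for ill-health with a non-IHD condition, and a small
    # not-applicable slice.
    other_kind = rng.choice(
        np.asarray(
            ["unemployed_ft", "unemployed_pt", "nilf_ill_other", "nilf_other", "not_applicable"],
            dtype=object,
        ),
        size=n,
        p=[0.22, 0.08, 0.18, 0.49, 0.03],
    )

    lfs = np.empty(n, dtype=object)
    lfs[np.isin(group, ["ft_no_ihd", "ft_ihd"])] = "employed_ft"
    lfs[np.isin(group, ["pt_no_ihd", "pt_ihd"])] = "employed_pt"
    lfs[group == "nilf_ihd"] = "nilf"
    is_other = group == "other"
    lfs[is_other & (other_kind == "unemployed_ft")] = "unemployed_seeking_ft"
    lfs[is_other & (other_kind == "unemployed_pt")] = "unemployed_seeking_pt"
    lfs[is_other & np.isin(other_kind, ["nilf_ill_other", "nilf_other"])] = "nilf"
    lfs[is_other & (other_kind == "not_applicable")] = "not_applicable"

    nilf_reason = np.full(n, "not_applicable", dtype=object)
    nilf_reason[group == "nilf_ihd"] = "own_ill_health"
    nilf_reason[is_other & (other_kind == "nilf_ill_other")] = "own_ill_health"
    nilf_reason[is_other & (other_kind == "nilf_other")] = "other"

    condition = np.empty(n, dtype=object)
    ihd_mask = np.isin(group, ["ft_ihd", "pt_ihd", "nilf_ihd"])
    condition[ihd_mask] = rng.choice(
        np.asarray(IHD_CONDITIONS, dtype=object), size=int(ihd_mask.sum()), p=[0.5, 0.25, 0.25]
    )
    ill_other = is_other & (other_kind == "nilf_ill_other")
    condition[ill_other] = rng.choice(
        np.asarray(NON_IHD_CONDITIONS, dtype=object),
        size=int(ill_other.sum()),
        p=[0.15, 0.20, 0.30, 0.15, 0.20],
    )
    rest = ~(ihd_mask | ill_other)
    condition[rest] = rng.choice(
        np.asarray(("none",) + NON_IHD_CONDITIONS, dtype=object),
        size=int(rest.sum()),
        p=[0.60, 0.04, 0.08, 0.12, 0.06, 0.10],
    )

    hours = np.zeros(n, dtype=float)
    ft = lfs == "employed_ft"
    pt = lfs == "employed_pt"
    hours[ft] = rng.integers(35, 51, int(ft.sum()))
    hours[pt] = rng.integers(4, 35, int(pt.sum()))

    quintile_probs = {
        "employed_ft": [0.05, 0.10, 0.20, 0.30, 0.35],
        "employed_pt": [0.15, 0.25, 0.25, 0.20, 0.15],
    }
    quintile = np.empty(n, dtype=int)
    for status, probs in quintile_probs.items():
        m = lfs == status
        quintile[m] = rng.choice(np.arange(1, 6), size=int(m.sum()), p=probs)
    m = ~np.isin(lfs, list(quintile_probs))
    quintile[m] = rng.choice(np.arange(1, 6), size=int(m.sum()), p=[0.45, 0.30, 0.15, 0.07, 0.03])

    nilf_ill = (lfs == "nilf") & (nilf_reason == "own_ill_health")
    dsp = np.where(
        nilf_ill, rng.random(n) < 0.80,
        np.where(lfs == "nilf", rng.random(n) < 0.05, rng.random(n) < 0.01),
    )
    age_pension = np.where(
        (age >= 60) & (lfs != "employed_ft"), rng.random(n) < 0.20, rng.random(n) < 0.01
    )

    lo, hi = config.weight_range
    weight = rng.uniform(lo, hi, n)

    df = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "age": age.astype(int),
            "age_group": _age_group_of(age),
            "sex": sex,
            "income_unit_type": income_unit,
            "education": education,
            "labour_force_status": lfs,
            "nilf_reason": nilf_reason,
            "main_condition": condition,
            "hours_per_week": hours,
            "home_owner": home_owner,
            "receives_age_pension": age_pension,
            "receives_dsp": dsp,
            "income_quintile": quintile,
            "weight": weight,
        }
    )
    validate_population(df)
    return df


def _donor_economics(
    rng: np.random.Generator, lfs: np.ndarray, config: PopulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(lfs)
    income = np.zeros(n)
    welfare = np.zeros(n)
    tax = np.zeros(n)

    ft = lfs == "employed_ft"
    pt = lfs == "employed_pt"
    unemployed = np.isin(lfs, ["unemployed_seeking_ft", "unemployed_seeking_pt"])
    nilf_like = ~(ft | pt | unemployed)

    income[ft] = config.income_laws["ft"].draw(rng, int(ft.sum()))
    income[pt] = config.income_laws["pt"].draw(rng, int(pt.sum()))
    # Welfare for employed donors: mostly zero, occasional supplements, so
    # the cell medians are zero while means stay positive.
    wf_ft = np.where(rng.random(n) < 0.10, rng.exponential(187.0, n), 0.0)
    wf_pt = np.where(rng.random(n) < 0.30, rng.exponential(258.0, n), 0.0)
    welfare[ft] = np.minimum(wf_ft[ft], income[ft])
    welfare[pt] = np.minimum(wf_pt[pt], income[pt])
    tax[ft | pt] = tax_from_income(income[ft | pt], config.tax_brackets)

    # Out-of-labour-force donors: welfare-led income, zero tax.
    w_nilf = config.income_laws["nilf"].draw(rng, int(nilf_like.sum()))
    welfare[nilf_like] = w_nilf
    income[nilf_like] = w_nilf / config.nilf_welfare_income_ratio
    w_un = config.income_laws["unemployed"].draw(rng, int(unemployed.sum()))
    welfare[unemployed] = w_un
    income[unemployed] = w_un / 0.85

    return income, welfare, tax


def generate_donor_pool(config: PopulationConfig, seed: int) -> pd.DataFrame:
    """Generate a synthetic tax/transfer donor pool (2013 dollars).

    Donors carry the ten matching variables and weekly income / welfare /
    tax; they are disease-blind, as the economic source model is.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_donors

    gs = config.group_shares
    p_ft = gs["ft_no_ihd"] + gs["ft_ihd"]
    p_pt = gs["pt_no_ihd"] + gs["pt_ihd"]
    p_rest = max(1.0 - p_ft - p_pt, 0.0)
    lfs_probs = np.array(
        [p_ft, p_pt, 0.15 * p_rest, 0.05 * p_rest, 0.78 * p_rest, 0.02 * p_rest]
    )
    lfs = rng.choice(
        np.asarray(LABOUR_FORCE_STATUSES, dtype=object), size=n, p=lfs_probs / lfs_probs.sum()
    )

    age_group = rng.choice(np.asarray(AGE_GROUPS, dtype=object), size=n)
    sex = rng.choice(np.asarray(SEXES, dtype=object), size=n)
    education = rng.choice(
        np.asarray(EDUCATION_LEVELS, dtype=object), size=n, p=[0.30, 0.35, 0.20, 0.15]
    )
    income_unit = rng.choice(
        np.asarray(INCOME_UNIT_TYPES, dtype=object), size=n, p=[0.25, 0.45, 0.30]
    )
    home_owner = rng.random(n) < 0.70
    nilf_like = ~np.isin(lfs, ["employed_ft", "employed_pt"])
    dsp = np.where(nilf_like, rng.random(n) < 0.55, rng.random(n) < 0.01)
    age_pension = np.where(
        (age_group == "60-64") & (lfs != "employed_ft"), rng.random(n) < 0.20,
        rng.random(n) < 0.01,
    )
    quintile = np.empty(n, dtype=int)
    ft = lfs == "employed_ft"
    pt = lfs == "employed_pt"
    quintile[ft] = rng.choice(np.arange(1, 6), size=int(ft.sum()), p=[0.05, 0.10, 0.20, 0.30, 0.35])
    quintile[pt] = rng.choice(np.arange(1, 6), size=int(pt.sum()), p=[0.15, 0.25, 0.25, 0.20, 0.15])
    rest = ~(ft | pt)
    quintile[rest] = rng.choice(
        np.arange(1, 6), size=int(rest.sum()), p=[0.45, 0.30, 0.15, 0.07, 0.03]
    )
    band = np.full(n, "0", dtype=object)
    band[ft] = "35+"
    band[pt] = "1-34"

    income, welfare, tax = _donor_economics(rng, lfs, config)

    df = pd.DataFrame(
        {
            "donor_id": [f"D{i:07d}" for i in range(n)],
            "sex": sex,
            "age_group": age_group,
            "income_unit_type": income_unit,
            "income_quintile": quintile,
            "receives_age_pension": age_pension,
            "receives_dsp": dsp,
            "labour_force_status": lfs,
            "hours_band": band,
            "education": education,
            "home_owner": home_owner,
            "weekly_income": income,
            "weekly_welfare": welfare,
            "weekly_tax": tax,
        }
    )
    validate_donor_pool(df)
    return df


def validate_population(df: pd.DataFrame) -> None:
    """Check the person-record schema invariants; raise SchemaError on failure."""
    missing = set(PERSON_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"person file missing columns: {sorted(missing)}")
    if len(df) == 0:
        return
    checks = [
        (df["age"].between(45, 64).all(), "age outside [45, 64]"),
        ((_age_group_of(df["age"].to_numpy()) == df["age_group"].to_numpy()).all(),
         "age_group inconsistent with age"),
        (df["sex"].isin(SEXES).all(), "unknown sex"),
        (df["labour_force_status"].isin(LABOUR_FORCE_STATUSES).all(),
         "unknown labour_force_status"),
        (df["nilf_reason"].isin(NILF_REASONS).all(), "unknown nilf_reason"),
        (df["main_condition"].isin(CONDITIONS).all(), "unknown main_condition"),
        (df["education"].isin(EDUCATION_LEVELS).all(), "unknown education"),
        (df["income_unit_type"].isin(INCOME_UNIT_TYPES).all(), "unknown income_unit_type"),
        (df["income_quintile"].isin(range(1, 6)).all(), "income_quintile outside 1-5"),
        ((df["weight"] > 0).all(), "non-positive weight"),
        ((df["hours_per_week"] >= 0).all(), "negative hours"),
    ]
    nilf = df["labour_force_status"] == "nilf"
    checks.append(
        (((df["nilf_reason"] != "not_applicable") == nilf).all(),
         "nilf_reason set iff labour_force_status == nilf"),
    )
    employed = df["labour_force_status"].isin(["employed_ft", "employed_pt"])
    checks.append(((df.loc[~employed, "hours_per_week"] == 0).all(), "hours > 0 while not employed"))
    for ok, message in checks:
        if not ok:
            raise SchemaError(message)


def validate_donor_pool(df: pd.DataFrame) -> None:
    """Check the donor-record schema invariants; raise SchemaError on failure."""
    missing = set(DONOR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"donor file missing columns: {sorted(missing)}")
    if len(df) == 0:
        return
    checks = [
        ((df["weekly_income"] >= 0).all(), "negative weekly_income"),
        ((df["weekly_welfare"] >= 0).all(), "negative weekly_welfare"),
        ((df["weekly_tax"] >= 0).all(), "negative weekly_tax"),
        ((df["weekly_welfare"] <= df["weekly_income"] + 1e-9).all(),
         "weekly_welfare exceeds weekly_income"),
        (df["hours_band"].isin(HOURS_BANDS).all(), "unknown hours_band"),
        (df["labour_force_status"].isin(LABOUR_FORCE_STATUSES).all(),
         "unknown labour_force_status"),
        (df["age_group"].isin(AGE_GROUPS).all(), "unknown age_group"),
        (df["sex"].isin(SEXES).all(), "unknown sex"),
    ]
    for ok, message in checks:
        if not ok:
            raise SchemaError(message)


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a person or donor file as UTF-8 CSV with header."""
    df.to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_population(df)
    return df


def read_donor_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_donor_pool(df)
    return df


def _truncated_normal_mean(mu: float, sigma: float) -> float:
    """Mean of max(0, N(mu, sigma)) -- exact correction for clipping at zero."""
    z = mu / sigma
    return mu * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def make_recovery_study(
    n_cases: int = 500,
    n_donors: int = 3000,
    income_gap: float = 950.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Designed validation study with a known case-vs-full-time gap.

    Builds a case frame (out of the labour force due to ill-health, income
    centred on the published 415.83 median) and a full-time donor frame whose
    income is centred exactly ``income_gap`` dollars higher, independent of
    the matching cells, so the true weekly mean difference (case - donor) is
    known in closed form. Returns ``(cases, donors, truth)`` with truth keyed
    by outcome on the case-minus-donor sign convention.
    """
    rng = np.random.default_rng(seed)
    case_mu, case_sd = 415.83, 86.41
    donor_mu, donor_sd = case_mu + income_gap, 500.0
    welfare_mu, welfare_sd = 321.87, 117.62
    tax_mu, tax_sd = 256.10, 80.0

    def frame(n, prefix, income_mu, income_sd):
        return pd.DataFrame(
            {
                f"{prefix}_id": [f"{prefix[0].upper()}{i:06d}" for i in range(n)],
                "sex": rng.choice(np.asarray(SEXES, dtype=object), size=n),
                "age_group": rng.choice(np.asarray(AGE_GROUPS, dtype=object), size=n),
                "education": rng.choice(np.asarray(EDUCATION_LEVELS, dtype=object), size=n),
                "weight": rng.uniform(50.0, 150.0, n),
                "weekly_income": np.clip(rng.normal(income_mu, income_sd, n), 0.0, None),
            }
        )

    cases = frame(n_cases, "case", case_mu, case_sd)
    cases["weekly_welfare"] = np.clip(rng.normal(welfare_mu, welfare_sd, n_cases), 0.0, None)
    cases["weekly_tax"] = 0.0
    donors = frame(n_donors, "donor", donor_mu, donor_sd)
    donors["weekly_welfare"] = 0.0
    donors["weekly_tax"] = np.clip(rng.normal(tax_mu, tax_sd, n_donors), 0.0, None)

    truth = {
        "income": _truncated_normal_mean(case_mu, case_sd)
        - _truncated_normal_mean(donor_mu, donor_sd),
        "welfare": _truncated_normal_mean(welfare_mu, welfare_sd),
        "tax": -_truncated_normal_mean(tax_mu, tax_sd),
        "design_sd": {
            "case_income": case_sd,
            "donor_income": donor_sd,
            "case_welfare": welfare_sd,
            "donor_tax": tax_sd,
        },
    }
    return cases, donors, truth
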