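"""Lost-PLY identification, analysis-group classification, weighted summaries.

A lost productive life year (PLY) due to IHD is a person not in the labour
force whose stated reason is their own ill-health or disability and whose
main chronic condition is in the ischemic heart disease group (heart
disease, angina, myocardial infarction). Every record falls in exactly one
of six analysis groups: employed full/part-time with/without IHD, out of the
labour force due to IHD, and a residual "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import ANALYSIS_GROUPS, CONDITIONS, IHD_CONDITIONS

IHD_SET = frozenset(IHD_CONDITIONS)
_CONDITION_SET = frozenset(CONDITIONS)


def is_ihd(main_condition: str) -> bool:
    """True iff the condition code belongs to the ischemic heart disease group."""
    if main_condition not in _CONDITION_SET:
        raise ValueError(f"unknown condition code {main_condition!r}")
    return main_condition in IHD_SET


def _ihd_mask(df: pd.DataFrame) -> pd.Series:
    unknown = ~df["main_condition"].isin(_CONDITION_SET)
    if unknown.any():
        bad = sorted(df.loc[unknown, "main_condition"].unique())
        raise ValueError(f"unknown condition codes {bad}")
    return df["main_condition"].isin(IHD_SET)


def identify_lost_ply(record) -> bool:
    """True iff the record represents a lost PLY due to IHD.

    Accepts anything mapping-like with the person fields (a dict, a
    DataFrame row).
    """
    return (
        record["labour_force_status"] == "nilf"
        and record["nilf_reason"] == "own_ill_health"
        and is_ihd(record["main_condition"])
    )


def lost_ply_mask(df: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`identify_lost_ply` over a person frame."""
    return (
        (df["labour_force_status"] == "nilf")
        & (df["nilf_reason"] == "own_ill_health")
        & _ihd_mask(df)
    )


def classify_group(record) -> str:
    """Analysis group of one record."""
    lfs = record["labour_force_status"]
    ihd = is_ihd(record["main_condition"])
    if lfs == "employed_ft":
        return "ft_ihd" if ihd else "ft_no_ihd"
    if lfs == "employed_pt":
        return "pt_ihd" if ihd else "pt_no_ihd"
    if identify_lost_ply(record):
        return "nilf_ihd"
    return "other"


def assign_groups(df: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_group`: one analysis group per record."""
    ihd = _ihd_mask(df)
    lfs = df["labour_force_status"]
    out = np.select(
        [
            (lfs == "employed_ft") & ~ihd,
            (lfs == "employed_ft") & ihd,
            (lfs == "employed_pt") & ~ihd,
            (lfs == "employed_pt") & ihd,
            lost_ply_mask(df),
        ],
        ["ft_no_ihd", "ft_ihd", "pt_no_ihd", "pt_ihd", "nilf_ihd"],
        default="other",
    )
    return pd.Series(out, index=df.index, name="group")


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.average(values, weights=weights))


def weighted_sd(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    m = np.average(values, weights=weights)
    return float(np.sqrt(np.average((values - m) ** 2, weights=weights)))


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1], side="left"))
    return float(values[order][idx])


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_records: int
    weighted_count: float
    share: float
    stats: dict  # outcome -> {"mean": ..., "sd": ..., "median": ...}


def group_summaries(
    df: pd.DataFrame,
    value_cols: tuple[str, ...] = ("weekly_income", "weekly_welfare", "weekly_tax"),
) -> pd.DataFrame:
    """Weighted count, population share, and weighted mean/SD/median per group.

    Output mirrors the published income/welfare/tax table: one row per
    analysis group, empty groups carried with zero count and NaN moments.
    Shares sum to one over the six groups.
    """
    if (df["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    work = df.assign(group=assign_groups(df))
    total = work["weight"].sum()
    rows = []
    for group in ANALYSIS_GROUPS:
        sub = work[work["group"] == group]
        row = {
            "group": group,
            "n_records": len(sub),
            "weighted_count": sub["weight"].sum(),
            "share": sub["weight"].sum() / total if total else np.nan,
        }
        for col in value_cols:
            if col not in work.columns:
                continue
            if len(sub) == 0:
                row[f"{col}_mean"] = row[f"{col}_sd"] = row[f"{col}_median"] = np.nan
            else:
                v, w = sub[col], sub["weight"]
                row[f"{col}_mean"] = weighted_mean(v, w)
                row[f"{col}_sd"] = weighted_sd(v, w)
                row[f"{col}_median"] = weighted_median(v, w)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
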