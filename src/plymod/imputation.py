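"""Hot-deck synthetic matching of economic data onto the base population.

Each person receives the weekly income, welfare and tax of one donor record
sharing the ten matching variables. When the exact ten-variable cell is
empty, variables are dropped one at a time from the end of the priority
order (home ownership first, then income-unit type, hours band, ...) until a
donor exists; the number of dropped variables is recorded as the fallback
depth. A record that finds no donor even in its (sex, age group) cell is
excluded and counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .population import hours_band

logger = logging.getLogger(__name__)

#: Matching variables in priority order: the head of the tuple is most
#: predictive of income and is dropped last.
MATCH_VARS = (
    "sex",
    "age_group",
    "labour_force_status",
    "receives_dsp",
    "receives_age_pension",
    "education",
    "income_quintile",
    "hours_band",
    "income_unit_type",
    "home_owner",
)
#: Never drop below (sex, age_group).
MIN_KEY_LEN = 2
MAX_FALLBACK_DEPTH = len(MATCH_VARS) - MIN_KEY_LEN
ECON_COLS = ("weekly_income", "weekly_welfare", "weekly_tax")


def _key_arrays(df: pd.DataFrame, n_vars: int) -> list[tuple]:
    cols = [df[v].to_numpy() for v in MATCH_VARS[:n_vars]]
    return list(zip(*cols)) if cols else [()] * len(df)


def _index_at(donors: pd.DataFrame, n_vars: int) -> dict[tuple, np.ndarray]:
    index: dict[tuple, list[int]] = {}
    for i, key in enumerate(_key_arrays(donors, n_vars)):
        index.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in index.items()}


def build_match_index(donors: pd.DataFrame) -> dict[tuple, np.ndarray]:
    """Exact-key index over the full ten-variable match key.

    Maps each distinct key to the positional indices of the donors carrying
    it; every donor is reachable under exactly its own key.
    """
    if len(donors) == 0:
        raise ValueError("donor pool is empty")
    return _index_at(donors, len(MATCH_VARS))


def match_economic_data(
    base: pd.DataFrame, donors: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Impute donor economics onto every base record by synthetic matching.

    The donor is chosen uniformly at random (with replacement across base
    records) among donors in the most specific non-empty cell. Donor cells
    are sorted by donor id, so the result depends only on ``(base, donor
    multiset, seed)``, not on donor file order. Unmatched records are dropped;
    their count is logged and stored in ``result.attrs["n_unmatched"]``.
    """
    if len(base) == 0:
        raise ValueError("base population is empty")
    donors = donors.sort_values("donor_id", kind="mergesort").reset_index(drop=True)
    base = base.copy()
    base["hours_band"] = hours_band(base["hours_per_week"])

    indexes = [
        _index_at(donors, len(MATCH_VARS) - depth)
        for depth in range(MAX_FALLBACK_DEPTH + 1)
    ]
    keys_by_depth = [
        _key_arrays(base, len(MATCH_VARS) - depth)
        for depth in range(MAX_FALLBACK_DEPTH + 1)
    ]

    rng = np.random.default_rng(seed)
    n = len(base)
    donor_pos = np.full(n, -1, dtype=int)
    depth_out = np.full(n, -1, dtype=int)
    for i in range(n):
        for depth in range(MAX_FALLBACK_DEPTH + 1):
            cand = indexes[depth].get(keys_by_depth[depth][i])
            if cand is not None:
                donor_pos[i] = cand[rng.integers(len(cand))]
                depth_out[i] = depth
                break

    matched = donor_pos >= 0
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        logger.warning("synthetic matching: %d of %d records unmatched", n_unmatched, n)

    result = base.loc[matched].reset_index(drop=True)
    chosen = donors.iloc[donor_pos[matched]].reset_index(drop=True)
    for col in ECON_COLS:
        result[col] = chosen[col].to_numpy()
    result["donor_id"] = chosen["donor_id"].to_numpy()
    result["fallback_depth"] = depth_out[matched]
    result.attrs["n_unmatched"] = n_unmatched
    result.attrs["n_base"] = n
    return result


def imputation_diagnostics(imputed: pd.DataFrame, n_base: int | None = None) -> dict:
    """Match rate, fallback-depth profile, and income medians by analysis group."""
    from .cohorts import assign_groups

    if n_base is None:
        n_base = imputed.attrs.get("n_base", len(imputed))
    depth = imputed["fallback_depth"]
    groups = assign_groups(imputed)
    medians = (
        imputed.assign(group=groups)
        .groupby("group", observed=True)["weekly_income"]
        .median()
        .to_dict()
    )
    return {
        "n_base": int(n_base),
        "n_matched": int(len(imputed)),
        "match_rate": len(imputed) / n_base if n_base else float("nan"),
        "mean_fallback_depth": float(depth.mean()) if len(imputed) else float("nan"),
        "max_fallback_depth": int(depth.max()) if len(imputed) else 0,
        "depth_counts": depth.value_counts().sort_index().to_dict(),
        "median_income_by_group": medians,
    }
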