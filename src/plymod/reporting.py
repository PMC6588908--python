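"""Reproduction of published derived statistics and cost-series figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import published
from .costs import percent_change, potential_gdp_gain_pct, round2, share_pct

_KIND_FUNCS = {
    "percent_change": percent_change,
    "share": share_pct,
    "gdp_gain": potential_gdp_gain_pct,
}


def reproduce_derived_statistics(fixture=None) -> pd.DataFrame:
    """Recompute every published derived ratio/percent change from its
    printed inputs.

    Returns one row per statistic with the recomputed value, the published
    value, and ``match`` (equality after half-up rounding to two decimals).
    ``exact_expected`` marks entries whose printed value is itself consistent
    with recomputation; the remaining entries are printed-rounding artifacts
    kept for the record.
    """
    fixture = published.DERIVED_STATISTICS if fixture is None else fixture
    rows = []
    for name, kind, a, b, pub, exact, source in fixture:
        if kind not in _KIND_FUNCS:
            raise KeyError(f"unknown statistic kind {kind!r} for {name}")
        recomputed = _KIND_FUNCS[kind](a, b)
        rows.append(
            {
                "statistic": name,
                "kind": kind,
                "recomputed": recomputed,
                "recomputed_2dp": round2(recomputed),
                "published": pub,
                "match": round2(recomputed) == round2(pub),
                "exact_expected": exact,
                "source": source,
            }
        )
    return pd.DataFrame(rows)


_COST_COMPONENTS = {
    "lost_income": "Lost income",
    "extra_welfare": "Extra welfare payments",
    "lost_tax": "Lost income tax revenue",
}


def render_cost_series(
    national_costs: pd.DataFrame, outdir, formats: tuple[str, ...] = ("png",)
) -> list[Path]:
    """One cost-vs-year chart per component, with the percentile CI band.

    ``national_costs`` is the frame written to ``national_costs.csv``; the
    plotted values are taken from it unchanged.
    """
    if len(national_costs) == 0:
        raise ValueError("no cost summaries to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = national_costs.sort_values("year")
    paths = []
    for component, label in _COST_COMPONENTS.items():
        data = df[["year", component, f"{component}_lower", f"{component}_upper"]]
        data.to_csv(outdir / f"{component}_data.csv", index=False)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["year"], df[component], marker="o", color="tab:blue")
        ax.fill_between(
            df["year"], df[f"{component}_lower"], df[f"{component}_upper"],
            alpha=0.25, color="tab:blue", label="95% CI",
        )
        ax.set_xlabel("Projection year")
        ax.set_ylabel(f"{label} (AU$ millions/year)")
        ax.set_title(f"{label} through lost productive life years")
        ax.set_xticks(df["year"])
        ax.legend()
        fig.tight_layout()
        for fmt in formats:
            path = outdir / f"{component}.{fmt}"
            fig.savefig(path)
            paths.append(path)
        plt.close(fig)
    return paths
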