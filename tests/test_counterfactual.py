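"""Matched counterfactual Monte Carlo: sampling law, differences, CIs."""

import numpy as np
import pandas as pd
import pytest

from plymod import (
    CounterfactualSpec,
    draw_counterfactual_set,
    make_recovery_study,
    percentile_ci,
    replicate_difference,
    run_simulations,
    select_donor_pool,
)
from plymod.counterfactual import estimate, estimate_all


def _cases(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("sex", "male"), ("age_group", "45-49"), ("education", "certificate"),
        ("weight", 1.0), ("weekly_income", 0.0), ("weekly_welfare", 0.0),
        ("weekly_tax", 0.0),
    ):
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    return df


def test_single_donor_always_assigned():
    cases = _cases([{"weekly_income": 400.0}] * 5)
    donors = _cases([{"weekly_income": 1350.0, "weight": 7.0}])
    for seed in range(10):
        assignment = draw_counterfactual_set(cases, donors, seed=seed)
        assert (assignment == 0).all()


def test_weight_proportional_sampling_frequencies():
    """Two donors with weights 3:1 are drawn ~0.75/0.25 (binomial 3-SD band)."""
    cases = _cases([{}])
    donors = _cases([{"weight": 3.0}, {"weight": 1.0}])
    n = 10_000
    picks = np.array(
        [draw_counterfactual_set(cases, donors, seed=s)[0] for s in range(n)]
    )
    p_hat = (picks == 0).mean()
    sd = np.sqrt(0.75 * 0.25 / n)
    assert abs(p_hat - 0.75) <= 3 * sd


def test_uniform_sampling_switch():
    cases = _cases([{}])
    donors = _cases([{"weight": 99.0}, {"weight": 1.0}])
    n = 10_000
    picks = np.array(
        [
            draw_counterfactual_set(cases, donors, seed=s, weight_proportional=False)[0]
            for s in range(n)
        ]
    )
    p_hat = (picks == 0).mean()
    sd = np.sqrt(0.25 / n)
    assert abs(p_hat - 0.5) <= 3 * sd


def test_no_cross_cell_assignment():
    """Exhaustive check on a 6-cell fixture: donors never cross match cells."""
    cells = [(s, a) for s in ("male", "female") for a in ("45-49", "50-54", "55-59")]
    cases = _cases([{"sex": s, "age_group": a} for s, a in cells])
    donors = _cases([{"sex": s, "age_group": a, "weekly_income": i} for i, (s, a) in enumerate(cells)])
    for seed in range(50):
        assignment = draw_counterfactual_set(
            cases, donors, match_vars=("sex", "age_group"), seed=seed
        )
        assert (assignment == np.arange(6)).all()


def test_education_fallback_then_error():
    cases = _cases([{"education": "diploma"}])
    donors = _cases([{"education": "bachelor_plus", "weekly_income": 50.0}])
    # full cell empty, dropping education finds the donor
    assignment = draw_counterfactual_set(cases, donors, seed=0)
    assert assignment[0] == 0
    # no donor even at the sex level -> error listing the cell
    lonely = _cases([{"sex": "female"}])
    with pytest.raises(ValueError, match="female"):
        draw_counterfactual_set(lonely, donors, seed=0)


def test_replicate_difference_arithmetic():
    cases = _cases([{"weight": 2.0, "weekly_income": 400.0}])
    donors = _cases([{"weekly_income": 1350.0}])
    assert replicate_difference(cases, donors, np.array([0]), "income") == pytest.approx(-950.0)

    # three-case fixture against hand-computed weighted mean
    cases3 = _cases(
        [
            {"weight": 1.0, "weekly_income": 100.0},
            {"weight": 2.0, "weekly_income": 200.0},
            {"weight": 3.0, "weekly_income": 300.0},
        ]
    )
    donors3 = _cases([{"weekly_income": 150.0}, {"weekly_income": 250.0}])
    assignment = np.array([0, 0, 1])
    # (1*(100-150) + 2*(200-150) + 3*(300-250)) / 6 = (-50 + 100 + 150)/6
    assert replicate_difference(cases3, donors3, assignment, "income") == pytest.approx(200.0 / 6.0)

    # donors identical to cases -> zero difference
    assert replicate_difference(cases3, cases3, np.arange(3), "income") == 0.0


def test_run_simulations_shapes_and_degenerate_pool():
    cases = _cases([{"weekly_income": 400.0}, {"weekly_income": 500.0, "weight": 2.0}])
    donors = _cases([{"weekly_income": 1000.0}])
    sims = run_simulations(CounterfactualSpec(n_sims=1, master_seed=4), cases, donors)
    assert len(sims.draws) == 1
    sims = run_simulations(CounterfactualSpec(n_sims=20, master_seed=4), cases, donors)
    assert sims.draws["income"].nunique() == 1  # single donor per cell: zero MC variance


def test_simulations_deterministic_under_master_seed():
    cases, donors, _ = make_recovery_study(n_cases=30, n_donors=100, seed=8)
    spec = CounterfactualSpec(n_sims=50, master_seed=123)
    a = run_simulations(spec, cases, donors)
    b = run_simulations(spec, cases, donors)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    c = run_simulations(CounterfactualSpec(n_sims=50, master_seed=124), cases, donors)
    assert not a.draws.equals(c.draws)


def test_percentile_ci_nearest_rank():
    draws = np.arange(1.0, 1001.0)
    assert percentile_ci(draws, 0.95) == (25.0, 975.0)
    assert percentile_ci(np.full(10, 3.3), 0.95) == (3.3, 3.3)
    with pytest.raises(ValueError):
        percentile_ci(draws, 1.0)
    with pytest.raises(ValueError):
        percentile_ci(np.array([1.0]), 0.95)


def test_estimate_orders_interval():
    cases, donors, _ = make_recovery_study(n_cases=40, n_donors=200, seed=9)
    sims = run_simulations(CounterfactualSpec(n_sims=100, master_seed=5), cases, donors)
    est = estimate(sims, "income", "ft_no_ihd")
    assert est.lower <= est.point <= est.upper
    assert est.n_sims == 100


def test_gap_recovery_within_monte_carlo_error():
    """The designed case-vs-full-time income gap is recovered within 3 MC SEs."""
    from conftest import recovery_se

    cases, donors, truth = make_recovery_study(n_cases=400, n_donors=2000, seed=10)
    spec = CounterfactualSpec(n_sims=500, master_seed=11)
    ests = estimate_all(spec, cases, donors)
    se = recovery_se(cases, donors, truth["design_sd"], spec.n_sims)
    assert abs(ests["income"].point - truth["income"]) <= 3 * se["income"]
    assert abs(ests["welfare"].point - truth["welfare"]) <= 3 * se["welfare"]
    assert abs(ests["tax"].point - truth["tax"]) <= 3 * se["tax"]


def test_wider_donor_dispersion_never_shrinks_ci():
    """CI width is statistically monotone in donor income dispersion."""
    widths = {}
    for scale, label in ((1.0, "narrow"), (4.0, "wide")):
        deltas = []
        for seed in range(10):
            cases, donors, _ = make_recovery_study(n_cases=80, n_donors=300, seed=seed)
            donors = donors.copy()
            mean = donors["weekly_income"].mean()
            donors["weekly_income"] = mean + scale * (donors["weekly_income"] - mean)
            sims = run_simulations(
                CounterfactualSpec(n_sims=200, master_seed=seed), cases, donors
            )
            lo, hi = percentile_ci(sims.draws["income"], 0.95)
            deltas.append(hi - lo)
        widths[label] = np.mean(deltas)
    assert widths["wide"] > widths["narrow"]


def test_select_donor_pool_contents(imputed):
    ft = select_donor_pool(imputed, "ft_no_ihd")
    assert (ft["labour_force_status"] == "employed_ft").all()
    assert not ft["main_condition"].isin(
        ["heart_disease", "angina", "myocardial_infarction"]
    ).any()
    lf = select_donor_pool(imputed, "labour_force_no_ihd")
    # whole labour force: includes unemployed job seekers, excludes NILF
    assert lf["labour_force_status"].isin(
        ["employed_ft", "employed_pt", "unemployed_seeking_ft", "unemployed_seeking_pt"]
    ).all()
    assert len(lf) > len(ft)
    with pytest.raises(ValueError):
        select_donor_pool(imputed, "everyone")
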