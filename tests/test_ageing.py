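"""Calibration, disease trends, uprating, and their composition."""

import numpy as np
import pandas as pd
import pytest

from plymod import (
    BenchmarkSet,
    UpratingRule,
    apply_disease_trend,
    default_disease_trends,
    gregwt_calibrate,
    make_benchmarks,
    project_to_year,
    uprate_economics,
)
from plymod.ageing import calibrate_weights, trend_exponent


def _records(rows):
    df = pd.DataFrame(rows)
    defaults = {
        "main_condition": "none",
        "weekly_income": 100.0,
        "weekly_welfare": 0.0,
        "weekly_tax": 10.0,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df


def _benchmarks_from(records, year=2015, pop_scale=1.0):
    rows = []
    for (ag, sex), sub in records.groupby(["age_group", "sex"]):
        total = sub["weight"].sum()
        ft = sub.loc[sub["labour_force_status"] == "employed_ft", "weight"].sum()
        pt = sub.loc[sub["labour_force_status"] == "employed_pt", "weight"].sum()
        rows.append(
            {"age_group": ag, "sex": sex, "population": total * pop_scale,
             "ft_rate": ft / total, "pt_rate": pt / total}
        )
    return BenchmarkSet(year=year, cells=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Calibration


def test_fixed_point_weights_unchanged():
    records = _records(
        [
            {"age_group": "45-49", "sex": "male", "labour_force_status": "employed_ft",
             "weight": 10.0},
            {"age_group": "45-49", "sex": "male", "labour_force_status": "nilf",
             "weight": 30.0},
        ]
    )
    bm = _benchmarks_from(records)
    result = gregwt_calibrate(records, bm)
    assert result.converged
    assert result.iterations <= 1
    np.testing.assert_allclose(result.weights, records["weight"], rtol=1e-12)


def test_single_margin_scales_all_weights():
    """With only a grand total, every weight is scaled by target/current."""
    d = np.array([1.0, 2.0, 3.0])
    X = np.ones((3, 1))
    result = calibrate_weights(d, X, np.array([12.0]))
    np.testing.assert_allclose(result.weights, d * 2.0, rtol=1e-10)
    assert result.converged


def test_two_margin_closed_form():
    """4-record, 2-margin fixture matches the analytic linear-calibration
    solution w = d (1 + x'lambda) with lambda solved directly."""
    d = np.array([1.0, 1.0, 1.0, 1.0])
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    targets = np.array([4.2, 2.6])
    # independent oracle: solve the 2x2 system  (X' diag(d) X) lam = t - X'd
    A = X.T @ (X * d[:, None])
    lam = np.linalg.solve(A, targets - X.T @ d)
    oracle = d * (1.0 + X @ lam)
    np.testing.assert_allclose(X.T @ oracle, targets, atol=1e-12)  # oracle sanity

    result = calibrate_weights(d, X, targets, tolerance=1e-10)
    np.testing.assert_allclose(result.weights, oracle, atol=1e-8)
    assert result.converged


def test_bounded_calibration_respects_bounds_and_converges():
    rng = np.random.default_rng(51)
    d = rng.uniform(50, 150, 400)
    X = np.column_stack(
        [rng.random(400) < p for p in (0.5, 0.3, 0.2)]
    ).astype(float)
    X = np.column_stack([np.ones(400), X])
    targets = X.T @ d * np.array([1.3, 0.8, 1.5, 1.1])
    result = calibrate_weights(d, X, targets, bounds=(0.5, 2.0), tolerance=1e-6)
    ratios = result.weights / d
    assert (ratios >= 0.5 - 1e-9).all() and (ratios <= 2.0 + 1e-9).all()
    if result.converged:
        assert result.max_rel_error <= 1e-6


def test_infeasible_margin_names_cell(base, imputed):
    bm = make_benchmarks(imputed, 2015)
    sub = imputed[imputed["age_group"] != "45-49"]  # empty cell, positive target
    with pytest.raises(ValueError, match="45-49"):
        gregwt_calibrate(sub, bm)


def test_nonconvergence_reported_not_raised():
    # a single record cannot hit two contradictory totals
    d = np.array([1.0])
    X = np.array([[1.0, 1.0]])
    result = calibrate_weights(d, X, np.array([2.0, 3.0]), max_iter=5)
    assert not result.converged
    assert result.max_rel_error > 1e-6


def test_calibration_hits_projection_benchmarks(imputed):
    bm = make_benchmarks(imputed, 2030)
    result = gregwt_calibrate(imputed, bm, tolerance=1e-6)
    assert result.converged
    # per-margin check, not just the max
    m = result.margins
    rel = (m["achieved"] - m["target"]).abs() / m["target"].abs()
    assert (rel <= 1e-6).all()
    total = result.weights.sum()
    assert total == pytest.approx(bm.cells["population"].sum(), rel=1e-6)


# ---------------------------------------------------------------------------
# Disease trends


def _trend_records():
    rows = []
    for i in range(40):
        rows.append(
            {
                "age_group": "50-54",
                "sex": "female",
                "labour_force_status": "nilf" if i % 4 == 0 else "employed_ft",
                "main_condition": "heart_disease" if i % 5 == 0 else
                ("type2_diabetes" if i % 5 == 1 else "none"),
                "weight": 10.0 + i,
            }
        )
    return _records(rows)


def _trends(ihd=1.0, t2d=1.0):
    t = default_disease_trends()
    t.loc[t["disease"] == "ihd", "annual_multiplier"] = ihd
    t.loc[t["disease"] == "type2_diabetes", "annual_multiplier"] = t2d
    t.loc[~t["disease"].isin(["ihd", "type2_diabetes"]), "annual_multiplier"] = 1.0
    return t


def _weighted_prevalence(df, conditions):
    return df.loc[df["main_condition"].isin(conditions), "weight"].sum() / df["weight"].sum()


def test_unit_multiplier_is_identity():
    records = _trend_records()
    out = apply_disease_trend(records, _trends(), target_year=2015)
    pd.testing.assert_frame_equal(out, records)


def test_prevalence_ratio_matches_power_law():
    """IHD multiplier 0.99/yr, 2009->2015: prevalence ratio 0.99^6, checked by
    direct recomputation of weighted prevalence."""
    records = _trend_records()
    out = apply_disease_trend(records, _trends(ihd=0.99), target_year=2015)
    ihd_codes = ["heart_disease", "angina", "myocardial_infarction"]
    before = _weighted_prevalence(records, ihd_codes)
    after = _weighted_prevalence(out, ihd_codes)
    assert after / before == pytest.approx(0.99**6, rel=1e-12)


def test_stratum_totals_conserved():
    records = _trend_records()
    out = apply_disease_trend(records, _trends(ihd=0.95, t2d=1.03), target_year=2020)
    for (_, _), sub in records.groupby(["sex", "age_group"]):
        before = sub["weight"].sum()
        after = out.loc[sub.index, "weight"].sum()
        assert after == pytest.approx(before, rel=1e-12)


def test_trend_stabilises_after_2023():
    records = _trend_records()
    trends = _trends(ihd=0.98, t2d=1.02)
    at_2023 = apply_disease_trend(records, trends, target_year=2023)
    for year in range(2024, 2031):
        later = apply_disease_trend(records, trends, target_year=year)
        pd.testing.assert_frame_equal(later, at_2023)
    assert trend_exponent(2009, 2030) == trend_exponent(2009, 2023) == 14


def test_excess_prevalence_rejected():
    records = _records(
        [
            {"age_group": "45-49", "sex": "male", "labour_force_status": "nilf",
             "main_condition": "type2_diabetes", "weight": 99.0},
            {"age_group": "45-49", "sex": "male", "labour_force_status": "nilf",
             "main_condition": "none", "weight": 1.0},
        ]
    )
    with pytest.raises(ValueError, match="prevalence"):
        apply_disease_trend(records, _trends(t2d=1.2), target_year=2023)


# ---------------------------------------------------------------------------
# Uprating


def test_uprating_factors_exact():
    records = _records(
        [{"age_group": "45-49", "sex": "male", "labour_force_status": "employed_ft",
          "weight": 1.0, "weekly_income": 100.0, "weekly_welfare": 321.87,
          "weekly_tax": 50.0}]
    )
    out = uprate_economics(records, target_year=2015)
    assert out.loc[0, "weekly_income"] == pytest.approx(102.01, abs=1e-12)
    assert out.loc[0, "weekly_welfare"] == 321.87  # zero real growth
    same = uprate_economics(records, target_year=2013)
    pd.testing.assert_frame_equal(same, records)


def test_unknown_component_rejected():
    with pytest.raises(ValueError, match="component"):
        UpratingRule("rent", 0.01)


def test_uprating_commutes_with_calibration(imputed):
    bm = make_benchmarks(imputed, 2020)
    a = uprate_economics(imputed, target_year=2020)
    res_a = gregwt_calibrate(a, bm)
    res_b = gregwt_calibrate(imputed, bm)
    b = imputed.copy()
    b["weight"] = res_b.weights
    b = uprate_economics(b, target_year=2020)
    np.testing.assert_allclose(res_a.weights, b["weight"], rtol=1e-12)
    pd.testing.assert_frame_equal(
        a.drop(columns="weight"), b.drop(columns="weight")
    )


# ---------------------------------------------------------------------------
# Composition


def test_projection_identity_under_neutral_inputs():
    records = _trend_records()
    bm = _benchmarks_from(records, year=2013)
    out, cal = project_to_year(records, bm, trends=_trends(), year=2013)
    assert cal.converged
    assert out.attrs["year"] == 2013
    pd.testing.assert_frame_equal(out[records.columns], records)


def test_projection_hits_population_total(imputed):
    bm = make_benchmarks(imputed, 2030)
    out, cal = project_to_year(imputed, bm, year=2030)
    assert cal.converged
    assert out["weight"].sum() == pytest.approx(
        bm.cells["population"].sum(), rel=1e-6
    )


def test_projection_deterministic(imputed):
    bm = make_benchmarks(imputed, 2025)
    a, _ = project_to_year(imputed, bm, year=2025)
    b, _ = project_to_year(imputed, bm, year=2025)
    pd.testing.assert_frame_equal(a, b)


def test_benchmark_csv_round_trip(tmp_path, imputed):
    bm = make_benchmarks(imputed, 2020)
    path = tmp_path / "bm.csv"
    bm.to_csv(path)
    again = BenchmarkSet.from_csv(path)
    assert again.year == 2020
    pd.testing.assert_frame_equal(again.cells, bm.cells)
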