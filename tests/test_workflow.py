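"""Growth-curve verification and the initiation-mass trend workflow."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bacsize.cellcycle import calibrated_c_plus_d, origins_for_growth_rates
from bacsize.reference import CONDITIONS, GROWTH_RATES_PER_H, size_table
from bacsize.workflow import (
    TREND_CONSTANT,
    TREND_DEPENDENT,
    GrowthCurve,
    WorkflowError,
    classify_trend,
    compare_settings,
    fit_growth_rate,
    initiation_mass,
    initiation_mass_series,
    max_pairwise_pct,
    mean_cell_mass,
    relative_series,
    simulate_growth_curve,
    stitch_dilutions,
    verify_steady_state,
)


def test_fit_recovers_exact_exponential():
    t = np.linspace(0, 3, 12)
    fit = fit_growth_rate(t, 0.05 * 2**t)
    assert fit.rate_per_h == pytest.approx(math.log(2), rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_of_constant_series_is_zero():
    assert fit_growth_rate([0, 1, 2, 3], [0.3, 0.3, 0.3, 0.3]).rate_per_h == 0.0


def test_fit_recovers_noisy_rate_within_three_se():
    curve = simulate_growth_curve(0.93, noise_cv=0.03, rng_seed=12)
    od = stitch_dilutions(curve.time_h, curve.od600, curve.dilution_events)
    fit = fit_growth_rate(curve.time_h, od)
    assert abs(fit.rate_per_h - 0.93) < 3 * fit.stderr


def test_fit_input_validation():
    with pytest.raises(WorkflowError):
        fit_growth_rate([0, 1], [1, 2])
    with pytest.raises(WorkflowError):
        fit_growth_rate([0, 1, 2], [1.0, -1.0, 2.0])


def test_steady_state_passes_on_matched_exponentials():
    t = np.linspace(0, 16, 40)
    od = 0.02 * np.exp(0.5 * t)
    curve = GrowthCurve(t, od, od * 1e9)
    report = verify_steady_state(curve)
    assert report.passed
    assert report.generations > 10


def test_steady_state_fails_on_rate_mismatch():
    t = np.linspace(0, 20, 50)
    curve = GrowthCurve(t, 0.02 * np.exp(0.7 * t), 2e7 * np.exp(0.5 * t))
    report = verify_steady_state(curve, rate_tolerance=0.05)
    assert not report.passed
    assert "rates differ" in report.reason


def test_steady_state_fails_below_ten_generations():
    t = np.linspace(0, 2, 12)
    od = 0.02 * np.exp(0.5 * t)
    report = verify_steady_state(GrowthCurve(t, od, od * 1e9))
    assert not report.passed
    assert "generations" in report.reason


def test_stitched_serial_dilution_curve_passes():
    curve = simulate_growth_curve(0.65, noise_cv=0.02, rng_seed=3)
    assert len(curve.dilution_events) >= 2
    report = verify_steady_state(curve)
    assert report.passed
    assert abs(report.od_fit.rate_per_h - 0.65) < 3 * report.od_fit.stderr


@pytest.mark.parametrize(
    "od,cells,expected",
    [(0.2, 2e8, 1.0), (0.4, 4e8, 1.0), (0.2, 4e8, 0.5)],
)
def test_mean_cell_mass_arithmetic(od, cells, expected):
    assert mean_cell_mass(od, cells) == pytest.approx(expected)


def test_mean_cell_mass_rejects_zero_counts():
    with pytest.raises(WorkflowError):
        mean_cell_mass(0.2, 0.0)


def test_initiation_mass_values():
    assert initiation_mass(1.0, 1.0) == pytest.approx(1.4427, abs=1e-4)
    # m_bar = 1 OD600*mL per 1e9 cells at o_bar = 2 is 7.21e-10 OD600*mL per origin
    assert initiation_mass(1.0, 2.0) * 10 == pytest.approx(7.21, abs=0.01)
    ratio = initiation_mass(1.21, 2.0) / initiation_mass(0.39, 1.0)
    assert ratio == pytest.approx(1.551, abs=1e-3)


@settings(derandomize=True, max_examples=40)
@given(
    m=st.floats(0.1, 10.0),
    o=st.floats(1.0, 8.0),
    a=st.floats(0.1, 5.0),
)
def test_initiation_mass_homogeneity(m, o, a):
    """m_i scales linearly with the mass proxy and inversely with o_bar."""
    base = initiation_mass(m, o)
    assert initiation_mass(a * m, o) == pytest.approx(a * base, rel=1e-9)
    assert initiation_mass(m, a * o) == pytest.approx(base / a, rel=1e-9)


def test_relative_series_examples_and_mean_one():
    assert np.allclose(relative_series([1, 1, 1, 1]), [1, 1, 1, 1])
    assert np.allclose(relative_series([1, 3]), [0.5, 1.5])
    mj = [0.39, 1.21]
    obar = [1.0, 2.0]
    rel = relative_series([initiation_mass(v, o) for v, o in zip(mj, obar)])
    assert rel[1] / rel[0] == pytest.approx(1.551, abs=1e-3)


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12))
def test_relative_series_always_averages_to_one(values):
    assert relative_series(values).mean() == pytest.approx(1.0, rel=1e-9)


def _reference_mi(setting, origin_ratio=2.0):
    rates = np.array([GROWTH_RATES_PER_H[c] for c in CONDITIONS])
    cd = calibrated_c_plus_d(origin_ratio, rates.max(), rates.min())
    obar = origins_for_growth_rates(rates, cd)
    tab = size_table()
    vols = (
        tab[(tab.feature == "volume_um3") & (tab.setting == setting)]
        .set_index("condition")
        .loc[list(CONDITIONS), "mean"]
        .to_numpy()
    )
    return rates, np.array([initiation_mass(v, o) for v, o in zip(vols, obar)])


def test_classify_trend_on_reference_series():
    rates, mi_dep = _reference_mi("microbej_-200")
    assert classify_trend(mi_dep, rates) == TREND_DEPENDENT
    rates, mi_const = _reference_mi("microbej_100")
    assert classify_trend(mi_const, rates) == TREND_CONSTANT
    assert classify_trend([1.0, 1.0, 1.0], [0.1, 0.5, 0.9]) == TREND_CONSTANT


def test_classify_trend_validation():
    with pytest.raises(WorkflowError):
        classify_trend([1.0], [0.5])
    with pytest.raises(WorkflowError):
        classify_trend([1.0, 2.0], [0.5, 0.5])


def _comparison_table(settings_wanted):
    rates = np.array([GROWTH_RATES_PER_H[c] for c in CONDITIONS])
    cd = calibrated_c_plus_d(2.0, rates.max(), rates.min())
    obar = dict(zip(CONDITIONS, origins_for_growth_rates(rates, cd)))
    tab = size_table()
    vols = tab[(tab.feature == "volume_um3") & tab.setting.isin(settings_wanted)]
    out = vols.rename(columns={"mean": "mass_proxy"})[
        ["setting", "condition", "growth_rate_per_h", "mass_proxy"]
    ].copy()
    out["mean_origins"] = out["condition"].map(obar)
    return out


def test_compare_settings_flags_the_conflict():
    comp = compare_settings(_comparison_table(["microbej_-200", "microbej_100"]))
    assert comp.conflict
    assert comp.series_by_setting["microbej_-200"].trend_label == TREND_DEPENDENT
    assert comp.series_by_setting["microbej_100"].trend_label == TREND_CONSTANT


def test_compare_settings_endpoint_ratios_for_oufti():
    comp = compare_settings(_comparison_table(["oufti_set1", "oufti_set2"]))
    r1 = comp.endpoint_increase_pct["oufti_set1"] / 100 + 1
    r2 = comp.endpoint_increase_pct["oufti_set2"] / 100 + 1
    assert r1 == pytest.approx(1.341, abs=1e-3)
    assert r2 == pytest.approx(1.112, abs=1e-3)
    assert r1 > r2


def test_compare_single_setting_cannot_conflict():
    comp = compare_settings(_comparison_table(["bacstalk"]))
    assert not comp.conflict


def test_compare_rejects_mismatched_condition_sets():
    table = _comparison_table(["microbej_-200", "microbej_100"])
    table = table.drop(table[(table.setting == "microbej_100")
                             & (table.condition == "glucose")].index)
    with pytest.raises(WorkflowError):
        compare_settings(table)


def test_initiation_mass_series_normalisation():
    rates, mi = _reference_mi("microbej_-200")
    series = initiation_mass_series(
        CONDITIONS, rates, mi * math.log(2) * 2.0, np.full(4, 2.0)
    )
    assert series.relative.mean() == pytest.approx(1.0)
    assert series.trend_label == TREND_DEPENDENT
    assert series.max_pairwise_pct_difference == pytest.approx(
        max_pairwise_pct(mi), rel=1e-9
    )
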