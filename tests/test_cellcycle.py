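"""Steady-state origin numbers, run-out simulation and DNA-histogram analysis."""

import math

import numpy as np
import pytest

from bacsize.cellcycle import (
    CellCycleParams,
    RunoutResult,
    calibrated_c_plus_d,
    estimate_mean_origins,
    mean_origins_closed_form,
    origins_for_growth_rates,
    simulate_dna_histogram,
    simulate_runout,
)


def test_closed_form_origin_numbers():
    assert mean_origins_closed_form(CellCycleParams(tau_min=60.0)) == pytest.approx(2.0)
    # slowest growth condition: lambda = 0.11 h^-1 -> tau = 378.1 min
    slow = CellCycleParams(tau_min=378.1)
    assert mean_origins_closed_form(slow) == pytest.approx(1.116, abs=1e-3)
    # non-overlapping limit: tau >> C+D
    assert mean_origins_closed_form(CellCycleParams(tau_min=1e7)) == pytest.approx(
        1.0, abs=1e-4
    )


def test_calibrated_c_plus_d_reproduces_endpoint_ratio():
    cd = calibrated_c_plus_d(2.0, 0.93, 0.11)
    obar = origins_for_growth_rates([0.11, 0.93], cd)
    assert obar[1] / obar[0] == pytest.approx(2.0, rel=1e-12)


def test_runout_fraction_matches_closed_form_at_half_cycle():
    """(C+D)/tau = 1.5: the 4-origin fraction is 2^0.5 - 1 from the age CDF."""
    params = CellCycleParams(tau_min=40.0)  # (40+20)/40 = 1.5
    n = 100000
    result = simulate_runout(params, n, rng_seed=1)
    p = 2**0.5 - 1
    se = math.sqrt(p * (1 - p) / n)
    assert set(result.origin_counts) == {2, 4}
    assert abs(result.origin_counts[4] - p) < 3 * se


def test_integer_cycle_gives_single_origin_class():
    params = CellCycleParams(tau_min=60.0)  # (C+D)/tau exactly 1
    result = simulate_runout(params, 5000, rng_seed=2)
    assert result.origin_counts == {2: 1.0}
    assert result.mean_origins == 2.0


@pytest.mark.parametrize("tau", [30.0, 44.72, 60.0, 90.0, 200.0])
def test_simulated_mean_matches_closed_form(tau):
    params = CellCycleParams(tau_min=tau, c_min=40.0, d_min=20.0)
    n = 50000
    result = simulate_runout(params, n, rng_seed=7)
    counts = np.array(list(result.origin_counts))
    fracs = np.array(list(result.origin_counts.values()))
    var = float(np.sum(fracs * counts**2) - result.mean_origins**2)
    se = math.sqrt(max(var, 1e-12) / n)
    assert abs(result.mean_origins - mean_origins_closed_form(params)) < 3 * se + 1e-9


def test_runout_result_invariants_enforced():
    with pytest.raises(ValueError):
        RunoutResult(origin_counts={2: 0.4, 4: 0.4}, mean_origins=3.0, n_cells=10)
    with pytest.raises(ValueError):
        RunoutResult(origin_counts={3: 1.0}, mean_origins=3.0, n_cells=10)


def test_histogram_conserves_events_and_is_deterministic():
    result = simulate_runout(CellCycleParams(tau_min=40.0), 20000, rng_seed=3)
    h1 = simulate_dna_histogram(result, 0.05, 30000, rng_seed=4)
    h2 = simulate_dna_histogram(result, 0.05, 30000, rng_seed=4)
    assert h1["count"].sum() == 30000
    assert h1.equals(h2)


def test_zero_cv_puts_all_mass_on_exact_peaks():
    result = simulate_runout(CellCycleParams(tau_min=40.0), 20000, rng_seed=5)
    hist = simulate_dna_histogram(result, 0.0, 20000, rng_seed=6)
    occupied = hist.loc[hist["count"] > 0, "bin_center"].to_numpy()
    width = hist["bin_center"].iloc[1] - hist["bin_center"].iloc[0]
    for c in occupied:
        assert min(abs(c - 2), abs(c - 4)) <= width


def test_histogram_round_trip_recovers_mean_origins():
    result = simulate_runout(CellCycleParams(tau_min=40.0), 50000, rng_seed=8)
    hist = simulate_dna_histogram(result, 0.03, 50000, rng_seed=9)
    est = estimate_mean_origins(hist)
    assert not est.low_confidence
    assert est.mean_origins == pytest.approx(result.mean_origins, rel=0.02)


def test_single_peak_histogram_is_exact():
    result = RunoutResult(origin_counts={2: 1.0}, mean_origins=2.0, n_cells=10)
    hist = simulate_dna_histogram(result, 0.0, 1000, rng_seed=0)
    assert estimate_mean_origins(hist).mean_origins == 2.0


def test_unresolvable_peaks_are_flagged_low_confidence():
    result = simulate_runout(CellCycleParams(tau_min=40.0), 20000, rng_seed=10)
    hist = simulate_dna_histogram(result, 0.4, 50000, rng_seed=11)
    assert estimate_mean_origins(hist).low_confidence


def test_paired_conditions_with_doubled_origins_recover_ratio_two():
    """Fast vs slow growth tuned so o_bar doubles: the recovered ratio is 2."""
    cd = calibrated_c_plus_d(2.0, 0.93, 0.11)
    fast = CellCycleParams.from_growth_rate(0.93, c_min=cd - 20.0, d_min=20.0)
    slow = CellCycleParams.from_growth_rate(0.11, c_min=cd - 20.0, d_min=20.0)
    ests = []
    for i, params in enumerate((slow, fast)):
        result = simulate_runout(params, 100000, rng_seed=20 + i)
        hist = simulate_dna_histogram(result, 0.03, 100000, rng_seed=30 + i)
        ests.append(estimate_mean_origins(hist).mean_origins)
    assert ests[1] / ests[0] == pytest.approx(2.0, abs=0.05)
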