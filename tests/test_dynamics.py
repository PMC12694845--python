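"""Per-cell kinetics: uptake, metabolism, potassium, membrane potential, ThT."""

import numpy as np
import pytest

from biofilmsig import dynamics
from biofilmsig.dynamics import (evaluate_signaling, glutamate_uptake,
                                 nernst_potential, resting_potential,
                                 step_biofilm, tht_uptake,
                                 update_internal_glutamate,
                                 update_membrane_potential, update_potassium,
                                 update_tht)
from biofilmsig.params import ModelParameters, SimulationConfig
from conftest import tiny_state

P = ModelParameters()


# ------------------------------------------------------------------ uptake

def test_uptake_zero_when_no_glutamate():
    assert glutamate_uptake(0.0, -80.0, P) == 0.0


def test_uptake_rejects_negative_glutamate():
    with pytest.raises(ValueError):
        glutamate_uptake(-1.0, -80.0, P)


def test_uptake_monotone_in_polarization_and_substrate():
    v = np.linspace(-120, 0, 200)
    flux = glutamate_uptake(np.full(200, 20.0), v, P)
    assert (np.diff(flux) <= 1e-12).all()  # depolarization slows uptake
    g = np.linspace(0, 50, 200)
    flux_g = glutamate_uptake(g, np.full(200, -80.0), P)
    assert (np.diff(flux_g) >= -1e-12).all()


def test_uptake_matches_direct_functional_form():
    """Brute-force evaluation of the kinetic form over a voltage sweep."""
    v = np.linspace(-110, -40, 73)
    g_e = 17.0
    expected = np.minimum(
        P.uptake_rate
        / (1 + np.exp((v - P.uptake_v_half) / P.uptake_v_slope))
        * g_e / (P.uptake_km + g_e),
        g_e,
    )
    np.testing.assert_allclose(glutamate_uptake(g_e, v, P), expected, rtol=1e-12)


def test_uptake_capped_at_available_glutamate():
    p = ModelParameters(uptake_rate=50.0)
    assert glutamate_uptake(0.01, -200.0, p) <= 0.01


# --------------------------------------------------------------- metabolism

def test_internal_glutamate_fixed_point_under_constant_uptake():
    """G' = G + u - dG converges to the analytic fixed point u/d."""
    g = 0.0
    for _ in range(300):
        g = update_internal_glutamate(g, 0.3, P)
    assert np.isclose(g, 0.3 / P.consumption_rate, rtol=1e-6)


def test_internal_glutamate_decays_monotonically_without_uptake():
    g = 5.0
    prev = g
    for _ in range(50):
        g = update_internal_glutamate(g, 0.0, P)
        assert 0 <= g < prev
        prev = g
    assert update_internal_glutamate(0.0, 0.0, P) == 0.0


# ---------------------------------------------------------------- signaling

def test_signaling_is_strictly_below_threshold():
    assert evaluate_signaling(2.9, 3.0)
    assert not evaluate_signaling(3.0, 3.0)  # boundary convention: strict
    # thresholds <= 0 can never be crossed by a non-negative pool
    assert not evaluate_signaling(0.0, -0.2)
    assert not evaluate_signaling(0.0, 0.0)


# ---------------------------------------------------------------- potassium

def test_nonsignaling_cell_at_set_point_is_fixed():
    k, release, pump = update_potassium(P.k_i_setpoint, False, P, g_i=3.0)
    assert k == P.k_i_setpoint and release == 0.0 and pump == 0.0


def test_signaling_cell_releases_into_pool():
    k, release, pump = update_potassium(P.k_i_setpoint, True, P, g_i=3.0)
    assert k < P.k_i_setpoint
    assert release > 0


def test_release_stops_at_the_non_releasable_floor():
    k, release, _ = update_potassium(P.k_i_floor, True, P, g_i=3.0)
    assert release == 0.0


def test_starved_cells_cannot_refill():
    _, _, pump_fed = update_potassium(200.0, False, P, g_i=3.0)
    _, _, pump_starved = update_potassium(200.0, False, P, g_i=0.0)
    assert pump_starved == 0.0 < pump_fed


def test_closed_system_potassium_conservation():
    """With media exchange off, sum(K_i) + n*K_e is conserved each tick."""
    state, cfg, rng = tiny_state(
        n_ring=2, pool_exchange_rate=0.0, pool_resupply_rate=0.0
    )
    n = state.n
    # force a mix of signaling and recovering cells
    state.threshold[:n] = np.linspace(0.5, 2.9, n)
    state.g_i[:n] = np.linspace(0.1, 4.0, n)
    state.k_i[:n] = np.linspace(180.0, 320.0, n)
    state.growing = False
    total0 = state.total_potassium()
    for _ in range(40):
        step_biofilm(state, cfg.g_m, cfg.k_m, cfg, rng)
        assert np.isclose(state.total_potassium(), total0, rtol=1e-10)


# --------------------------------------------------------- membrane potential

def test_nernst_potential_zero_at_equal_concentrations():
    assert nernst_potential(8.0, 8.0, P) == 0.0


def test_nernst_log_law_for_tenfold_change():
    base = nernst_potential(8.0, 300.0, P)
    assert np.isclose(nernst_potential(80.0, 300.0, P) - base, P.nernst_mv * np.log(10))


def test_membrane_potential_rejects_nonpositive_concentrations():
    with pytest.raises(ValueError):
        update_membrane_potential(-70.0, 0.0, 300.0, False, P)
    with pytest.raises(ValueError):
        update_membrane_potential(-70.0, 8.0, 0.0, False, P)


def test_membrane_potential_converges_geometrically_to_fixed_point():
    v = 0.0
    fp = resting_potential(8.0, 300.0, P)
    errors = []
    for _ in range(80):
        v = update_membrane_potential(v, 8.0, 300.0, False, P)
        errors.append(abs(v - fp))
    ratios = [b / a for a, b in zip(errors, errors[1:]) if a > 1e-9]
    assert max(ratios) < 1.0  # geometric contraction
    assert errors[-1] < 1e-6


def test_raising_extracellular_potassium_depolarizes():
    v1 = resting_potential(8.0, 300.0, P)
    v2 = resting_potential(80.0, 300.0, P)
    assert v2 > v1


def test_release_current_hyperpolarizes_the_releasing_cell():
    v_quiet = update_membrane_potential(-75.0, 8.0, 300.0, True, P, release=0.0)
    v_firing = update_membrane_potential(-75.0, 8.0, 300.0, True, P, release=15.0)
    assert v_firing < v_quiet


# ----------------------------------------------------------------------- ThT

def test_tht_converges_under_constant_potential():
    tht = 0.0
    for _ in range(300):
        tht = update_tht(tht, -90.0, P)
    assert np.isclose(tht, tht_uptake(-90.0, P), atol=1e-6)


def test_tht_pulse_rises_then_decays():
    tht = float(update_tht(0.05, -70.0, P))
    trace = [tht]
    for v in [-95.0] * 5 + [-70.0] * 40:
        tht = float(update_tht(tht, v, P))
        trace.append(tht)
    peak = int(np.argmax(trace))
    assert 0 < peak < 10
    assert trace[-1] < trace[peak] * 0.3


def test_tht_is_deterministic_in_voltage_history():
    rng = np.random.default_rng(0)
    vs = -70 - 30 * rng.random(50)
    a = b = 0.1
    for v in vs:
        a = update_tht(a, v, P)
        b = update_tht(b, v, P)
    assert a == b


# ---------------------------------------------------------------------- step

def test_step_is_deterministic_given_seed():
    s1, cfg, r1 = tiny_state(n_ring=3, seed=9)
    s2, _, r2 = tiny_state(n_ring=3, seed=9)
    for _ in range(30):
        step_biofilm(s1, cfg.g_m, cfg.k_m, cfg, r1)
        step_biofilm(s2, cfg.g_m, cfg.k_m, cfg, r2)
    np.testing.assert_array_equal(s1.g_i[:s1.n], s2.g_i[:s2.n])
    np.testing.assert_array_equal(s1.v[:s1.n], s2.v[:s2.n])
    assert s1.k_e == s2.k_e


def test_pool_stays_basal_when_no_threshold_reachable():
    state, cfg, rng = tiny_state(n_ring=2)
    state.threshold[:state.n] = 0.0  # nobody can ever signal
    state.growing = False
    for _ in range(60):
        step_biofilm(state, cfg.g_m, cfg.k_m, cfg, rng)
    assert np.isclose(state.k_e, cfg.k_m, atol=1e-6)
    assert not state.signaling[:state.n].any()


def test_concentrations_stay_nonnegative_under_stress():
    state, cfg, rng = tiny_state(n_ring=3)
    n = state.n
    state.threshold[:n] = 2.9
    state.g_i[:n] = 0.05
    state.growing = False
    for _ in range(100):
        step_biofilm(state, cfg.g_m, cfg.k_m, cfg, rng)
        assert state.g_i[:n].min() >= 0
        assert state.k_i[:n].min() >= 0
        assert state.g_e[:n].min() >= -1e-12
        assert state.k_e >= 0
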