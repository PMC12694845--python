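"""Per-tick cell physiology: glutamate metabolism, potassium signaling,
membrane potential, and the ThT polarization proxy.

The model couples three per-cell pools (internal glutamate ``G_i``, internal
potassium ``K_i``, membrane potential ``V``) to a shared extracellular
potassium pool ``K_e`` and a per-cell local extracellular glutamate ``G_e``:

* Uptake (voltage-dependent transporter): ``u = a * f(V) * G_e / (Km + G_e)``
  with a sigmoid voltage gate ``f(V) = 1 / (1 + exp((V - Vh) / s))`` —
  hyperpolarized cells absorb faster, uptake saturates in glutamate and can
  never exceed what is locally present.
* Metabolism: first-order consumption, ``G_i' = G_i + u - delta * G_i``.
* Signaling: a cell signals exactly while ``G_i < threshold`` (level
  triggered, re-evaluated every tick; thresholds <= 0 can never be crossed
  because ``G_i >= 0``).
* Potassium: signaling cells release ``release_rate * K_i`` into the shared
  pool; a metabolically gated pump relaxes ``K_i`` toward its set point,
  drawing from (or returning to) the same pool, so with media exchange
  disabled the total ``sum(K_i) + n * K_e`` is conserved exactly.  Starved
  cells cannot pump, so a drained, starving cell goes silent rather than
  trickling forever.
* Membrane potential relaxes toward a conductance-weighted combination of a
  leak potential and the potassium Nernst potential
  ``V_K = (RT/F) ln(K_e / K_i)``; signaling adds potassium conductance, so a
  releasing cell hyperpolarizes itself while the potassium it sheds
  depolarizes everyone else through the shared pool.
* ThT is a per-cell exponential smoothing of polarization magnitude
  (no spatial ThT diffusion).

All updates are one explicit step per tick on the model's coarse time grid.
"""

from __future__ import annotations

import numpy as np

from . import diffusion, growth
from .params import ModelParameters, SimulationConfig
from .state import BiofilmState

#: Fixed sub-step order of one tick (documented contract):
#: 1. glutamate shell transport, 2. uptake + consumption, 3. signaling
#: evaluation, 4. potassium release/recovery, 5. pool mixing and media
#: exchange, 6. membrane potential, 7. ThT, 8. growth (while growing).
STEP_ORDER = (
    "shell_transport", "glutamate", "signaling", "potassium",
    "mixing", "membrane_potential", "tht", "growth",
)


def voltage_factor(v, params: ModelParameters):
    """Transporter efficiency in (0, 1): a sigmoid gate on membrane potential.

    Hyperpolarized cells (V well below the gating midpoint) absorb at the
    full rate; depolarization past the midpoint shuts the transporter down
    over a few ``uptake_v_slope`` millivolts.
    """
    v = np.asarray(v, dtype=float)
    z = np.clip((v - params.uptake_v_half) / params.uptake_v_slope, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(z))


def glutamate_uptake(g_e, v, params: ModelParameters):
    """Voltage-dependent, saturating glutamate uptake flux (mM/tick).

    Monotone non-decreasing in polarization magnitude and in ``g_e``,
    and capped at ``g_e`` so a cell can never absorb more than is present.
    """
    g_e = np.asarray(g_e, dtype=float)
    if np.any(g_e < 0):
        raise ValueError("extracellular glutamate must be non-negative")
    flux = params.uptake_rate * voltage_factor(v, params) * g_e / (params.uptake_km + g_e)
    return np.minimum(flux, g_e)


def update_internal_glutamate(g_i, uptake_flux, params: ModelParameters):
    """One consumption/uptake step: ``G_i' = G_i + u - delta G_i``, clamped >= 0."""
    g_i = np.asarray(g_i, dtype=float)
    return np.maximum(g_i + uptake_flux - params.consumption_rate * g_i, 0.0)


def evaluate_signaling(g_i, threshold):
    """A cell signals exactly while its internal glutamate is below threshold."""
    return np.asarray(g_i, dtype=float) < np.asarray(threshold, dtype=float)


def update_potassium(k_i, signaling, params: ModelParameters, g_i=None):
    """Potassium release (while signaling) and pump recovery toward set point.

    Release is first-order in the *releasable* internal potassium (the store
    above a non-releasable floor) and active only while the cell signals, so
    a fresh signaler dumps a large burst that decays as its store drains and
    stops at the floor.  The recovery pump relaxes ``K_i`` toward the set point
    but needs metabolic activity: its rate carries a saturating gate on
    internal glutamate, so starved cells cannot refill their stores and fall
    silent once drained.

    Returns ``(k_i_new, release, pump)`` where ``release`` is the per-cell
    flux into the extracellular pool and ``pump`` the per-cell flux drawn
    from it (negative if the cell is shedding excess back).  The caller moves
    ``release - pump`` into the pool, which keeps the closed-system total
    exactly conserved.
    """
    k_i = np.asarray(k_i, dtype=float)
    sig = np.asarray(signaling, dtype=bool)
    release = np.where(sig, params.release_rate * np.clip(k_i - params.k_i_floor, 0.0, None), 0.0)
    if g_i is None:
        gate = 1.0
    else:
        g_i = np.asarray(g_i, dtype=float)
        gate = g_i / (g_i + params.recovery_km)
    pump = params.recovery_rate * gate * (params.k_i_setpoint - k_i)
    return k_i - release + pump, release, pump


def update_membrane_potential(v, k_e, k_i, signaling, params: ModelParameters,
                              release=0.0):
    """Relax V toward the leak/Nernst combination; signaling opens potassium
    conductance, and the release flux itself is an outward current that
    transiently hyperpolarizes the releasing cell (the membrane-potential
    spike at signaling onset)."""
    k_i = np.asarray(k_i, dtype=float)
    if k_e <= 0 or np.any(k_i <= 0):
        raise ValueError("potassium concentrations must be positive")
    v = np.asarray(v, dtype=float)
    v_k = params.nernst_mv * np.log(k_e / k_i)
    g = params.g_k + params.g_signal * np.asarray(signaling, dtype=float)
    return (v + params.g_leak * (params.v_leak - v) + g * (v_k - v)
            - params.release_v_gain * np.asarray(release, dtype=float))


def nernst_potential(k_e, k_i, params: ModelParameters):
    """Potassium Nernst potential, mV (strictly increasing in ``k_e / k_i``)."""
    return params.nernst_mv * np.log(np.asarray(k_e, dtype=float) / np.asarray(k_i, dtype=float))


def resting_potential(k_e, k_i, params: ModelParameters) -> float:
    """Fixed point of the V update for a non-signaling cell at fixed K levels."""
    v_k = params.nernst_mv * np.log(k_e / k_i)
    return (params.g_leak * params.v_leak + params.g_k * v_k) / (params.g_leak + params.g_k)


def tht_uptake(v, params: ModelParameters):
    """Instantaneous ThT uptake level in (0, 1): sigmoid in polarization."""
    z = np.clip((np.asarray(v, dtype=float) - params.tht_v_half) / params.tht_v_slope,
                -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(z))


def update_tht(tht, v, params: ModelParameters):
    """Low-pass polarization reporter: per-cell, no spatial diffusion.

    The uptake curve is a sharp sigmoid in membrane potential, so only
    strongly hyperpolarized cells accumulate appreciable dye, and the filter
    is asymmetric — fast accumulation while polarized, slow washout — so a
    cell that hyperpolarized at any point during the current signaling wave
    is still bright at the wave's peak.  This is what makes the colony ThT
    distribution at oscillation peaks bimodal.
    """
    tht = np.asarray(tht, dtype=float)
    target = tht_uptake(v, params)
    rate = np.where(target > tht, params.tht_rise_rate, params.tht_decay_rate)
    return tht + rate * (target - tht)


# --------------------------------------------------------------------- tick

def step_biofilm(state: BiofilmState, g_m: float, k_m: float,
                 config: SimulationConfig, rng) -> None:
    """Advance the colony by one tick (sub-step order in :data:`STEP_ORDER`)."""
    p = config.params
    n = state.n
    sl = slice(0, n)

    # (1) glutamate transport into the colony
    diffusion.glutamate_shell_update(state, g_m, p)

    # (2) uptake and metabolism
    u = glutamate_uptake(state.g_e[sl], state.v[sl], p)
    state.g_e[sl] -= u  # drained from the cell's extracellular share
    state.g_i[sl] = update_internal_glutamate(state.g_i[sl], u, p)
    state.uptake[sl] = u

    # (3) signaling evaluation (level-triggered)
    if p.signaling_enabled:
        state.signaling[sl] = evaluate_signaling(state.g_i[sl], state.threshold[sl])
    else:
        state.signaling[sl] = False

    # (4) potassium release / recovery, buffered for the mixing step
    k_i_new, release, pump = update_potassium(
        state.k_i[sl], state.signaling[sl], p, g_i=state.g_i[sl]
    )
    # the pool cannot be drawn below a tiny floor: scale down the pumps
    eps = 1e-9
    net_draw = float(pump.sum() - release.sum())
    if net_draw > 0 and net_draw / n > state.k_e - eps:
        pos = float(np.clip(pump, 0.0, None).sum())
        if pos > 0:
            allowed = max((state.k_e - eps) * n + release.sum()
                          + np.clip(pump, None, 0.0).sum() * -0.0, 0.0)
            scale = min(allowed / pos, 1.0)
            pump = np.where(pump > 0, pump * scale, pump)
        k_i_new = state.k_i[sl] - release + pump
    state.k_i[sl] = np.maximum(k_i_new, 0.0)
    state._release_buffer = float(release.sum())
    state._pump_buffer = float(pump.sum())

    # (5) instantaneous colony-wide mixing + media exchange
    diffusion.mix_potassium(state, k_m, p)

    # (6) membrane potential
    state.v[sl] = update_membrane_potential(
        state.v[sl], state.k_e, state.k_i[sl], state.signaling[sl], p,
        release=release,
    )

    # (7) ThT proxy
    state.tht[sl] = update_tht(state.tht[sl], state.v[sl], p)

    # (8) growth
    if state.growing:
        growth.grow_step(state, config, rng)
        if state.tick % config.depth_refresh_every == 0 or not state.growing:
            state.refresh_depth()
    elif state._depth_stale:
        state.refresh_depth()

    if not state.growing:
        state.accumulate_g_i()

    state.tick += 1
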