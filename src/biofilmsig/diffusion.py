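"""Glutamate transport into the colony and potassium mixing.

Glutamate moves much more slowly than potassium, so the two are treated
asymmetrically:

* **Potassium** equilibrates across the colony within a tick.  All per-cell
  release and recovery fluxes are pooled into a single extracellular value,
  which then exchanges with the flowing media toward basal potassium —
  washout of excess at one first-order rate, resupply of a depleted pool at
  a faster one, since the flow replenishes the boundary layer quickly.

* **Glutamate** enters from the media at the colony boundary and is
  attenuated on its way in by the cells that absorb it en route.  Cells are
  grouped into *shells* — BFS depth classes from the perimeter (depth 0 is
  the edge), which handle irregular grown boundaries — and each cell's local
  extracellular glutamate relaxes toward a per-shell target concentration

      target(k) = max(G_m - phi * sum_{j<k} ubar(j), 0)

  where ``ubar(j)`` is the mean realized uptake flux in shell ``j`` on the
  previous tick and ``phi`` the attenuation coefficient.  When the colony is
  polarized and absorbing quickly the target decays within a few tens of
  shells and deep cells receive essentially nothing; when the colony is
  depolarized (uptake suppressed) the target penetrates much deeper.  Total
  delivery per tick is additionally capped by the boundary supply.

The explicit 1-D radial diffusion-uptake solver at the bottom is the
validation oracle for the heuristic: it integrates the PDE to steady state
and is never used in the production loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .state import BiofilmState


@dataclass
class ShellDecomposition:
    """Cells grouped by BFS depth class, with per-shell summaries."""

    counts: np.ndarray      # cells per shell, indexed by depth
    mean_g_e: np.ndarray    # mean local extracellular glutamate per shell
    mean_uptake: np.ndarray  # mean realized uptake flux per shell (last tick)

    @property
    def n_shells(self) -> int:
        return len(self.counts)


def shell_decomposition(state: BiofilmState) -> ShellDecomposition:
    n = state.n
    depth = state.depths()
    k = int(depth.max()) + 1
    counts = np.bincount(depth, minlength=k).astype(float)
    safe = np.maximum(counts, 1.0)
    mean_g_e = np.bincount(depth, weights=state.g_e[:n], minlength=k) / safe
    mean_u = np.bincount(depth, weights=state.uptake[:n], minlength=k) / safe
    return ShellDecomposition(counts=counts, mean_g_e=mean_g_e, mean_uptake=mean_u)


def shell_targets(g_m: float, mean_uptake: np.ndarray, counts: np.ndarray,
                  params: ModelParameters) -> np.ndarray:
    """Inward target concentration per shell, attenuated by upstream uptake.

    The attenuation weights each upstream shell's uptake by its population
    relative to the boundary shell: nutrients enter through the perimeter
    while demand scales with the cells passed en route, so in a disc-shaped
    colony the interior of a small biofilm is easily fed while a large one
    develops a depleted core.
    """
    # reference boundary population: the colony edge is rough, which inflates
    # the outermost two depth classes; depth 3 tracks the smooth disc ring
    ref = counts[3] if len(counts) > 3 else counts[0]
    load = counts * mean_uptake / max(ref, 1.0)
    upstream = np.concatenate([[0.0], np.cumsum(load)[:-1]])
    return np.maximum(g_m - params.shell_attenuation * upstream, 0.0)


def glutamate_shell_update(state: BiofilmState, g_m: float,
                           params: ModelParameters) -> dict:
    """One transport tick: relax per-cell G_e toward the shell targets.

    Positive relaxation (delivery) is rationed outer-shell-first against the
    boundary supply cap; negative relaxation (washout where the media target
    dropped below the local concentration) is applied in full.  Returns an
    accounting dict with ``delivered``, ``washout`` and ``supply`` totals so
    callers can check mass balance.
    """
    n = state.n
    if n == 0:
        return {"delivered": 0.0, "washout": 0.0, "supply": 0.0}
    depth = state.depths()
    shells = shell_decomposition(state)
    target = shell_targets(g_m, shells.mean_uptake, shells.counts, params)

    want = params.shell_rate * (target[depth] - state.g_e[:n])  # per cell, signed
    pos = np.clip(want, 0.0, None)
    demand = np.bincount(depth, weights=pos, minlength=shells.n_shells)

    supply = params.supply_coeff * shells.counts[0] * g_m
    remaining = supply
    scale = np.ones(shells.n_shells)
    for k in range(shells.n_shells):
        if demand[k] <= 0:
            continue
        give = min(demand[k], remaining)
        scale[k] = give / demand[k]
        remaining -= give

    delta = pos * scale[depth] + np.minimum(want, 0.0)
    state.g_e[:n] += delta
    delivered = float((pos * scale[depth]).sum())
    washout = float(-np.minimum(want, 0.0).sum())
    return {"delivered": delivered, "washout": washout, "supply": float(supply)}


def mix_potassium(state: BiofilmState, k_m: float, params: ModelParameters) -> float:
    """Pool all per-cell potassium fluxes, then exchange with the media.

    The colony-wide pool concentration rises by the mean released flux and
    falls by the mean recovery draw (one-to-one in concentration units under
    the half-volume assumption), then relaxes toward basal ``k_m``.  Mixing
    is idempotent within a tick: a second call before the next tick is a
    no-op, so the pool is a single well-defined value per tick.
    """
    if state._mixed_tick == state.tick:
        return state.k_e
    n = max(state.n, 1)
    state.k_e += (state._release_buffer - state._pump_buffer) / n
    state._release_buffer = 0.0
    state._pump_buffer = 0.0
    state.k_e = max(state.k_e, 0.0)
    if state.k_e < k_m:
        state.k_e += params.pool_resupply_rate * (k_m - state.k_e)
    else:
        state.k_e += params.pool_exchange_rate * (k_m - state.k_e)
    state._mixed_tick = state.tick
    return state.k_e


# ------------------------------------------------------------------ analysis

def penetration_depth(g_m: float, params: ModelParameters, k_m: float = 8.0,
                      max_depth: int = 400, n_iter: int = 4000) -> int:
    """Depth to which media glutamate reaches a resting, non-signaling colony.

    Iterates the shell transport + resting-cell uptake system on an idealized
    column of shells to steady state and returns the first depth at which the
    extracellular concentration falls below the configured floor.  This is
    the exterior/interior boundary used by the analysis layer.
    """
    if g_m <= 0:
        return 0
    from .dynamics import resting_potential, voltage_factor

    v_rest = resting_potential(k_m, params.k_i_setpoint, params)
    f = float(voltage_factor(v_rest, params))
    g_e = np.zeros(max_depth)
    u = np.zeros(max_depth)
    for _ in range(n_iter):
        target = np.maximum(
            g_m - params.shell_attenuation * np.concatenate([[0.0], np.cumsum(u)[:-1]]), 0.0
        )
        g_e += params.shell_rate * (target - g_e)
        u = np.minimum(params.uptake_rate * f * g_e / (params.uptake_km + g_e), g_e)
        g_e -= u
    below = np.nonzero(g_e < params.penetration_floor)[0]
    return int(below[0]) if below.size else max_depth


def steady_shell_profile(g_m: float, params: ModelParameters, k_m: float = 8.0,
                         max_depth: int = 400, n_iter: int = 4000):
    """Steady-state (G_e, G_i) column profiles of the no-signaling heuristic."""
    from .dynamics import resting_potential, voltage_factor

    v_rest = resting_potential(k_m, params.k_i_setpoint, params)
    f = float(voltage_factor(v_rest, params))
    g_e = np.zeros(max_depth)
    g_i = np.zeros(max_depth)
    u = np.zeros(max_depth)
    for _ in range(n_iter):
        target = np.maximum(
            g_m - params.shell_attenuation * np.concatenate([[0.0], np.cumsum(u)[:-1]]), 0.0
        )
        g_e += params.shell_rate * (target - g_e)
        u = np.minimum(params.uptake_rate * f * g_e / (params.uptake_km + g_e), g_e)
        g_e -= u
        g_i = np.maximum(g_i + u - params.consumption_rate * g_i, 0.0)
    return g_e, g_i


def explicit_1d_oracle(radius: int, g_m: float, params: ModelParameters,
                       diffusivity: float = 40.0, k_m: float = 8.0,
                       dt: float = 0.02, tol: float = 1e-10,
                       max_steps: int = 2_000_000, geometry: str = "disc",
                       uptake_fn=None) -> np.ndarray:
    """Steady-state 1-D glutamate profile from an explicit diffusion-uptake PDE.

    Solves ``dc/dt = D (c'' + c'/r) - U(c)`` on a disc of the given radius
    (grid spacing = one cell diameter) with ``c(R) = g_m`` at the boundary
    and a no-flux center; ``geometry="slab"`` drops the curvature term.
    ``U`` defaults to the resting-cell saturating uptake; a custom callable
    ``uptake_fn(c)`` can replace it (e.g. linear uptake, for which the slab
    steady state has the closed-form decay length ``sqrt(D / k)``).
    Integrates until the update norm drops below ``tol``; raises on
    non-convergence with the residual in the message.

    This is the validation oracle for the shell heuristic — physically
    explicit, and far too slow for the production loop.
    """
    if uptake_fn is None:
        from .dynamics import resting_potential, voltage_factor

        v_rest = resting_potential(k_m, params.k_i_setpoint, params)
        f = float(voltage_factor(v_rest, params))

        def uptake_fn(c):
            return params.uptake_rate * f * c / (params.uptake_km + c)

    m = radius + 1
    c = np.full(m, float(g_m))
    r = np.arange(m, dtype=float)
    dt = min(dt, 0.2 / diffusivity)  # explicit stability
    for _ in range(max_steps):
        lap = np.zeros(m)
        lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
        if geometry == "disc":
            lap[1:-1] += (c[2:] - c[:-2]) / (2 * r[1:-1])
            lap[0] = 4.0 * (c[1] - c[0])  # symmetric center
        else:
            lap[0] = 2.0 * (c[1] - c[0])  # no-flux wall
        uptake = np.minimum(uptake_fn(c), c)
        delta = dt * (diffusivity * lap - uptake)
        delta[-1] = 0.0  # Dirichlet boundary at the media interface
        c = np.maximum(c + delta, 0.0)
        if np.abs(delta).max() < tol:
            return c
    raise RuntimeError(
        f"1-D oracle did not converge: residual {np.abs(delta).max():.3e} > {tol:.1e}"
    )
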