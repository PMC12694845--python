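"""Colony initialization, perimeter reproduction, and threshold inheritance.

Growth is perimeter-limited: each tick, one-fortieth of the cells on the
colony perimeter are selected uniformly at random *with replacement* to
reproduce (the count is rounded up so growth never stalls on tiny
perimeters).  A daughter is placed on one of its parent's empty neighbor
sites with probability proportional to the number of occupied neighbors of
each empty site, which keeps the colony compact; a fully enclosed parent
skips its reproduction attempt.  Daughters are clones of their parents
except for the signaling threshold, which is drawn from a truncated normal
centered on the parent's value.

The colony starts as a 7-cell hexagon with thresholds drawn uniformly over
the configured bounds and is first grown to a radius of 40 cells with all
physiology frozen (the nutrient-free phase); dynamics begin at radius 40
with every cell at the parameter set points.  Growth halts permanently at
the population cap (or optional radius cap) and never removes cells.
"""

from __future__ import annotations

import math

import numpy as np

from .hexlattice import NEIGHBOR_OFFSETS
from .params import GrowthPolicy, SimulationConfig, ThresholdDistribution
from .state import BiofilmState


def select_reproducers(perimeter_ids: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Draw ``ceil(fraction * len(perimeter))`` ids uniformly, with replacement."""
    perimeter_ids = np.asarray(perimeter_ids)
    if perimeter_ids.size == 0:
        raise ValueError("cannot select reproducers from an empty perimeter")
    k = math.ceil(fraction * perimeter_ids.size)
    return perimeter_ids[rng.integers(0, perimeter_ids.size, size=k)]


def place_daughter(parent_q: int, parent_r: int, lattice, rng):
    """Pick an empty neighbor of the parent, weighted by occupied-neighbor count.

    Returns ``(q, r)`` or ``None`` if the parent is fully enclosed (the
    reproduction attempt is skipped).
    """
    cid = lattice.cid
    h = lattice._half
    iq, ir = parent_q + h, parent_r + h
    empties = []
    weights = []
    for dq, dr in NEIGHBOR_OFFSETS:
        jq, jr = iq + dq, ir + dr
        if cid[jq, jr] < 0:
            w = 0
            for eq, er in NEIGHBOR_OFFSETS:
                if cid[jq + eq, jr + er] >= 0:
                    w += 1
            empties.append((jq - h, jr - h))
            weights.append(w)
    if not empties:
        return None
    if len(empties) == 1:
        return empties[0]
    total = float(sum(weights))
    x = rng.random() * total
    acc = 0.0
    for site, w in zip(empties, weights):
        acc += w
        if x < acc:
            return site
    return empties[-1]


def inherit_threshold(parent_threshold, dist: ThresholdDistribution, rng):
    """One truncated-normal draw centered on the parent's threshold."""
    dist.validate()
    return dist.sample(parent_threshold, rng)


def grow_step(state: BiofilmState, config: SimulationConfig, rng) -> int:
    """One growth tick: select, place, inherit.  Returns the number of births.

    Random draws occur in a fixed order: the reproducer selection, then one
    placement draw per parent in selection order, then a single batched
    inheritance draw for all daughters of the tick.
    """
    policy = config.growth
    if not state.growing:
        return 0
    lat = state.lattice
    parents = select_reproducers(lat.perimeter_ids(), policy.fraction, rng)

    placed_parents = []
    placed_sites = []
    for p in parents:
        site = place_daughter(int(lat.q[p]), int(lat.r[p]), lat, rng)
        if site is None:
            continue  # fully enclosed parent: attempt skipped
        # sequential emptiness: occupy now so later draws see the update
        cid = state.add_cell(site[0], site[1], threshold=0.0, parent=int(p))
        placed_parents.append(int(p))
        placed_sites.append(cid)

    if placed_sites:
        means = state.threshold[np.asarray(placed_parents)]
        state.threshold[np.asarray(placed_sites)] = config.thresholds.sample(means, rng)

    if state.n >= policy.population_cap or (
        policy.radius_cap is not None and lat.radius() >= policy.radius_cap
    ):
        state.growing = False
        state.growth_end_tick = state.tick
        state.refresh_depth()
    return len(placed_sites)


def initialize_biofilm(config: SimulationConfig, rng) -> BiofilmState:
    """Founding hexagon plus the nutrient-free growth phase to radius 40.

    The 7 founders get thresholds drawn i.i.d. uniform over the configured
    bounds.  The colony is then grown (threshold inheritance active, all
    other physiology frozen) until its radius reaches the nutrient-free
    radius; per-cell state is then set to the parameter set points, ready
    for the first dynamical tick.
    """
    config.validate()
    p = config.params
    cap = max(config.growth.population_cap + 4000, 12_000)
    state = BiofilmState(capacity=cap)
    tdist = config.thresholds

    founders = [(0, 0)] + [(dq, dr) for dq, dr in NEIGHBOR_OFFSETS]
    t0 = tdist.lower + (tdist.upper - tdist.lower) * rng.random(len(founders))
    for (q, r), t in zip(founders, t0):
        state.add_cell(q, r, threshold=float(t))

    while state.lattice.radius() < config.growth.nutrient_free_radius:
        grow_step(state, config, rng)

    from .dynamics import resting_potential

    n = state.n
    state.v[:n] = resting_potential(config.k_m, p.k_i_setpoint, p)
    state.g_i[:n] = p.g_i_init
    state.k_i[:n] = p.k_i_setpoint
    state.g_e[:n] = config.g_m
    state.k_e = config.k_m
    from .dynamics import tht_uptake

    state.tht[:n] = tht_uptake(state.v[:n], p)
    state.signaling[:n] = False
    state.refresh_depth()
    return state


def lineage_table(state: BiofilmState):
    """Lineage export: (cell id, parent id, birth tick, threshold)."""
    import pandas as pd

    n = state.n
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "parent_id": state.parent[:n],
            "birth_tick": state.birth_tick[:n],
            "threshold": state.threshold[:n],
        }
    )
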