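"""Colony state container: lattice + per-cell arrays + global potassium pool.

The simulator is array-of-structs: every per-cell quantity is a flat numpy
array indexed by cell id, and the lattice maps ids to hex coordinates.  A
single extracellular potassium value ``k_e`` is shared by the whole colony
(potassium diffuses fast relative to a tick, so it is mixed instantly),
while extracellular glutamate ``g_e`` is per cell and fed by the shell
transport heuristic in :mod:`biofilmsig.diffusion`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hexlattice import HexLattice


@dataclass
class CellState:
    """Read-only view of one cell (convenience for inspection and tests)."""

    cell_id: int
    q: int
    r: int
    v: float          # membrane potential, mV
    g_i: float        # internal glutamate, mM
    k_i: float        # internal potassium, mM
    g_e: float        # local extracellular glutamate, mM
    threshold: float  # signaling threshold, mM internal glutamate
    signaling: bool
    tht: float        # ThT polarization proxy, arbitrary units
    parent_id: int    # -1 for founders
    birth_tick: int


class BiofilmState:
    """All mutable simulation state for one colony."""

    __slots__ = (
        "lattice", "capacity", "v", "g_i", "k_i", "g_e", "threshold", "tht",
        "signaling", "uptake", "parent", "birth_tick", "depth", "k_e", "tick",
        "growing", "growth_end_tick", "_depth_stale", "_mixed_tick",
        "_release_buffer", "_pump_buffer", "_gi_accum", "_gi_accum_ticks",
    )

    def __init__(self, capacity: int = 70_000):
        self.lattice = HexLattice(max_cells=capacity)
        self.capacity = capacity
        self.v = np.zeros(capacity)
        self.g_i = np.zeros(capacity)
        self.k_i = np.zeros(capacity)
        self.g_e = np.zeros(capacity)
        self.threshold = np.zeros(capacity)
        self.tht = np.zeros(capacity)
        self.signaling = np.zeros(capacity, dtype=bool)
        self.uptake = np.zeros(capacity)  # realized uptake flux last tick, mM/tick
        self.parent = np.full(capacity, -1, dtype=np.int32)
        self.birth_tick = np.zeros(capacity, dtype=np.int32)
        self.depth = np.zeros(capacity, dtype=np.int32)
        self.k_e = 8.0
        self.tick = 0
        self.growing = True
        self.growth_end_tick: Optional[int] = None
        self._depth_stale = True
        self._mixed_tick = -1
        self._release_buffer = 0.0  # summed per-cell release this tick, mM
        self._pump_buffer = 0.0     # summed per-cell recovery draw this tick, mM
        self._gi_accum = np.zeros(capacity)
        self._gi_accum_ticks = 0

    # ------------------------------------------------------------------ cells
    @property
    def n(self) -> int:
        return self.lattice.n_cells

    def add_cell(self, q: int, r: int, threshold: float, parent: int = -1) -> int:
        cid = self.lattice.add_cell(q, r)
        if cid >= self.capacity:
            raise RuntimeError("cell capacity exceeded")
        self.threshold[cid] = threshold
        self.parent[cid] = parent
        self.birth_tick[cid] = self.tick
        if parent >= 0:
            # daughters are clones of their parent apart from the threshold
            for arr in (self.v, self.g_i, self.k_i, self.g_e, self.tht):
                arr[cid] = arr[parent]
            self.signaling[cid] = self.signaling[parent]
            self.depth[cid] = 0  # daughters sit on the colony edge
        self._depth_stale = True
        return cid

    def cell(self, cid: int) -> CellState:
        q, r = self.lattice.q[cid], self.lattice.r[cid]
        return CellState(
            cell_id=cid, q=int(q), r=int(r), v=float(self.v[cid]),
            g_i=float(self.g_i[cid]), k_i=float(self.k_i[cid]),
            g_e=float(self.g_e[cid]), threshold=float(self.threshold[cid]),
            signaling=bool(self.signaling[cid]), tht=float(self.tht[cid]),
            parent_id=int(self.parent[cid]), birth_tick=int(self.birth_tick[cid]),
        )

    # ------------------------------------------------------------------ depth
    def refresh_depth(self) -> None:
        n = self.n
        self.depth[:n] = self.lattice.depth_map()
        self._depth_stale = False

    def depths(self) -> np.ndarray:
        return self.depth[:self.n]

    # ------------------------------------------------------------ conservation
    def total_potassium(self) -> float:
        """Conserved quantity when media exchange is off: sum K_i + n * K_e.

        With half the biofilm volume intracellular and half extracellular
        media, per-cell concentration fluxes transfer one-to-one into the
        shared pool, so the conserved total (in concentration-times-volume
        units, with the single-cell volume as the unit) is the sum of the
        internal concentrations plus n times the pool concentration.
        """
        return float(self.k_i[:self.n].sum() + self.n * self.k_e)

    def mean_g_i_post_growth(self) -> np.ndarray:
        """Per-cell time-averaged internal glutamate since growth ended."""
        if self._gi_accum_ticks == 0:
            raise ValueError("no post-growth ticks have been accumulated yet")
        return self._gi_accum[:self.n] / self._gi_accum_ticks

    def accumulate_g_i(self) -> None:
        self._gi_accum[:self.n] += self.g_i[:self.n]
        self._gi_accum_ticks += 1
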