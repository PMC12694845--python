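"""Hexagonal lattice geometry for two-dimensional biofilm colonies.

Cells live on an axial-coordinate hex grid: a coordinate is an integer pair
``(q, r)`` and the six neighbors of every site are obtained by adding the
offsets in :data:`NEIGHBOR_OFFSETS` (fixed order E, NE, NW, W, SW, SE).  The
hex distance between two sites has the closed form

    d(a, b) = (|dq| + |dr| + |dq + dr|) / 2

which is the standard axial-coordinate metric.

:class:`HexLattice` stores occupancy as a dense integer grid (cell id per
site, ``-1`` for empty) so that the queries the simulator needs every tick —
perimeter extraction and depth-from-edge maps — can be computed with
vectorized array shifts rather than per-cell Python loops.
"""

from __future__ import annotations

import numpy as np

#: Axial offsets of the six hex neighbors, in fixed order E, NE, NW, W, SW, SE.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1),
)

HexCoord = tuple[int, int]


def hex_distance(a: HexCoord, b: HexCoord) -> int:
    """Hex (lattice) distance between two axial coordinates."""
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def neighbors(c: HexCoord) -> list[HexCoord]:
    """The six axial neighbors of ``c``, in the fixed order E, NE, NW, W, SW, SE."""
    q, r = c
    return [(q + dq, r + dr) for dq, dr in NEIGHBOR_OFFSETS]


def full_hexagon_population(radius: int) -> int:
    """Number of sites in a perfect hexagon of the given radius: 3r(r+1)+1."""
    return 3 * radius * (radius + 1) + 1


class HexLattice:
    """Occupancy grid for a connected hex colony grown from a founding cell.

    Cell ids are assigned consecutively from 0 in order of addition.  The
    founding cell is at the axial origin ``(0, 0)``; the backing grid grows
    automatically and always keeps an empty two-site margin so that the
    wrap-around of the vectorized shift operations can never read an
    occupied site.
    """

    def __init__(self, capacity_radius: int = 48, max_cells: int = 70_000):
        self._half = int(capacity_radius) + 2
        n = 2 * self._half + 1
        self.cid = np.full((n, n), -1, dtype=np.int32)
        self.q = np.empty(max_cells, dtype=np.int32)
        self.r = np.empty(max_cells, dtype=np.int32)
        self.n_cells = 0
        self._rmax = 0  # max hex distance from origin over occupied sites

    # ------------------------------------------------------------------ basic
    def _index(self, q: int, r: int) -> tuple[int, int]:
        return q + self._half, r + self._half

    def _ensure_capacity(self, q: int, r: int) -> None:
        h = self._half
        if abs(q) < h - 2 and abs(r) < h - 2:
            return
        new_half = max(2 * h, max(abs(q), abs(r)) + 4)
        n = 2 * new_half + 1
        grid = np.full((n, n), -1, dtype=np.int32)
        off = new_half - h
        grid[off:off + self.cid.shape[0], off:off + self.cid.shape[1]] = self.cid
        self.cid = grid
        self._half = new_half

    def add_cell(self, q: int, r: int) -> int:
        """Occupy site ``(q, r)`` with a new cell; returns its id."""
        self._ensure_capacity(q, r)
        iq, ir = self._index(q, r)
        if self.cid[iq, ir] >= 0:
            raise ValueError(f"site ({q}, {r}) already occupied")
        cid = self.n_cells
        if cid >= self.q.size:
            self.q = np.concatenate([self.q, np.empty(self.q.size, np.int32)])
            self.r = np.concatenate([self.r, np.empty(self.r.size, np.int32)])
        self.cid[iq, ir] = cid
        self.q[cid] = q
        self.r[cid] = r
        self.n_cells += 1
        d = (abs(q) + abs(r) + abs(q + r)) // 2
        if d > self._rmax:
            self._rmax = d
        return cid

    def cell_at(self, q: int, r: int) -> int:
        """Cell id at a site, or -1 if empty."""
        h = self._half
        if abs(q) > h - 1 or abs(r) > h - 1:
            return -1
        return int(self.cid[q + h, r + h])

    def is_occupied(self, q: int, r: int) -> bool:
        return self.cell_at(q, r) >= 0

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_cells
        return self.q[:n], self.r[:n]

    @classmethod
    def from_coords(cls, coords: "list[HexCoord]") -> "HexLattice":
        rad = max((hex_distance(c, (0, 0)) for c in coords), default=1)
        lat = cls(capacity_radius=rad + 2)
        for q, r in coords:
            lat.add_cell(int(q), int(r))
        return lat

    # --------------------------------------------------------------- geometry
    def radius(self) -> int:
        """Max hex distance from the origin over occupied sites (cells)."""
        if self.n_cells == 0:
            raise ValueError("radius of an empty lattice is undefined")
        return self._rmax

    def _occ(self) -> np.ndarray:
        return self.cid >= 0

    def perimeter_mask(self) -> np.ndarray:
        """Boolean grid mask of occupied sites with >= 1 empty neighbor."""
        occ = self._occ()
        has_empty = np.zeros_like(occ)
        for dq, dr in NEIGHBOR_OFFSETS:
            # neighbor value at (i+dq, j+dr): roll by (-dq, -dr)
            has_empty |= ~np.roll(occ, (-dq, -dr), axis=(0, 1))
        return occ & has_empty

    def perimeter_ids(self) -> np.ndarray:
        """Ids of cells on the colony perimeter (>= 1 unoccupied neighbor)."""
        m = self.perimeter_mask()
        return self.cid[m]

    def depth_grid(self) -> np.ndarray:
        """Multi-source BFS depth from the perimeter, on the backing grid.

        Perimeter cells have depth 0; unoccupied sites are -1.
        """
        occ = self._occ()
        depth = np.full(occ.shape, -1, dtype=np.int32)
        frontier = self.perimeter_mask()
        d = 0
        while frontier.any():
            depth[frontier] = d
            remaining = occ & (depth < 0)
            if not remaining.any():
                break
            nxt = np.zeros_like(frontier)
            for dq, dr in NEIGHBOR_OFFSETS:
                nxt |= np.roll(frontier, (dq, dr), axis=(0, 1))
            frontier = nxt & remaining
            d += 1
        return depth

    def depth_map(self) -> np.ndarray:
        """Per-cell BFS depth from the perimeter, indexed by cell id."""
        g = self.depth_grid()
        n = self.n_cells
        return g[self.q[:n] + self._half, self.r[:n] + self._half]

    def to_table(self):
        """Lattice snapshot as a (cell id, q, r, depth) table."""
        import pandas as pd

        depth = self.depth_map()
        q, r = self.coords()
        return pd.DataFrame(
            {"cell_id": np.arange(self.n_cells), "q": q, "r": r, "depth": depth}
        )
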