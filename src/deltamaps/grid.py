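"""Spatial grid topology.

A gridded field is modelled as a planar graph: each grid cell is a vertex and
edges connect spatially adjacent cells.  Domains are constrained to be
connected subgraphs of this graph, and a cell's *K-neighborhood* (the cell
plus its K nearest unmasked cells under a spatial metric) is the support of
the local homogeneity field used for seed selection.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGraph",
    "Neighborhood",
    "build_regular_grid",
    "build_latlon_grid",
    "k_neighborhood",
    "is_contiguous",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass
class GridGraph:
    """Planar adjacency structure over grid cells.

    Cells are identified by 0-based row-major integers.  ``adjacency[i]`` is
    the set of unmasked spatial neighbors of cell ``i``; masked cells have no
    adjacency entries.  ``coords`` holds one position per cell: ``(row, col)``
    indices for abstract grids or ``(lat, lon)`` in degrees for geographic
    ones (``geographic=True``).
    """

    n_cells: int
    adjacency: list
    coords: np.ndarray
    cell_weight: np.ndarray
    mask: np.ndarray  # True -> invalid cell
    geographic: bool = False
    shape: tuple | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_weight = np.asarray(self.cell_weight, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.cell_weight < 0):
            raise ValueError("cell weights must be nonnegative")

    @property
    def unmasked(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)

    def neighbors(self, i: int) -> set:
        return self.adjacency[i]

    def validate(self) -> None:
        """Check structural invariants (symmetry, no self loops, mask)."""
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError(f"self-adjacency at cell {i}")
            if self.mask[i] and nbrs:
                raise ValueError(f"masked cell {i} has adjacency entries")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric adjacency {i}->{j}")

    def to_edge_list(self, path=None):
        """Adjacency as a two-column 0-based integer edge list (i < j)."""
        edges = [
            (i, j)
            for i in range(self.n_cells)
            for j in sorted(self.adjacency[i])
            if i < j
        ]
        if path is not None:
            np.savetxt(path, np.asarray(edges, dtype=int), fmt="%d")
        return edges


@dataclass
class Neighborhood:
    """A cell plus its K nearest unmasked cells, guaranteed contiguous."""

    center: int
    members: tuple
    complete: bool = True  # False when the reachable component was exhausted

    def __len__(self):
        return len(self.members)


def _lattice_neighbors(rows, cols, r, c, connectivity, wrap_columns):
    steps4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    steps8 = steps4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    steps = steps4 if connectivity == 4 else steps8
    for dr, dc in steps:
        rr, cc = r + dr, c + dc
        if rr < 0 or rr >= rows:
            continue
        if wrap_columns:
            cc %= cols
        elif cc < 0 or cc >= cols:
            continue
        yield rr * cols + cc


def build_regular_grid(
    rows: int,
    cols: int,
    connectivity: int = 4,
    wrap_columns: bool = False,
    mask: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    cell_weight: np.ndarray | None = None,
    geographic: bool = False,
) -> GridGraph:
    """Build a rectangular lattice graph.

    With ``wrap_columns`` column 0 is adjacent to column ``cols-1`` (global
    longitude wrap).  Masked cells are removed from all adjacency sets.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    n = rows * cols
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool).reshape(n)
    if coords is None:
        rr, cc = np.divmod(np.arange(n), cols)
        coords = np.column_stack([rr, cc]).astype(float)
    if cell_weight is None:
        cell_weight = np.ones(n)
    wrap = wrap_columns and cols > 2  # wrap on <=2 columns would duplicate edges
    adjacency = []
    for i in range(n):
        if mask[i]:
            adjacency.append(set())
            continue
        r, c = divmod(i, cols)
        nbrs = {
            j
            for j in _lattice_neighbors(rows, cols, r, c, connectivity, wrap)
            if not mask[j] and j != i
        }
        adjacency.append(nbrs)
    return GridGraph(
        n_cells=n,
        adjacency=adjacency,
        coords=coords,
        cell_weight=cell_weight,
        mask=mask,
        geographic=geographic,
        shape=(rows, cols),
    )


def build_latlon_grid(
    lats: np.ndarray,
    lons: np.ndarray,
    mask: np.ndarray | None = None,
    connectivity: int = 4,
) -> GridGraph:
    """Lattice over a lat-lon grid: longitude wrap, cos-latitude cell weights.

    ``lats``/``lons`` are the 1-D coordinate axes in degrees; cells are
    serialized row-major in the order the axes are given.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    rows, cols = len(lats), len(lons)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    coords = np.column_stack([glat.ravel(), glon.ravel()])
    weight = np.cos(np.deg2rad(coords[:, 0]))
    weight = np.clip(weight, 0.0, None)
    return build_regular_grid(
        rows,
        cols,
        connectivity=connectivity,
        wrap_columns=True,
        mask=mask,
        coords=coords,
        cell_weight=weight,
        geographic=True,
    )


def _haversine(p, q):
    lat1, lon1, lat2, lon2 = map(np.deg2rad, (p[0], p[1], q[0], q[1]))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _distance(g: GridGraph, metric: str, center: int, j: int, hops: int) -> float:
    if metric == "graph-hops":
        return float(hops)
    p, q = g.coords[center], g.coords[j]
    if metric == "euclidean":
        return float(np.hypot(p[0] - q[0], p[1] - q[1]))
    if metric == "geodesic":
        return float(_haversine(p, q))
    raise ValueError(f"unknown metric {metric!r}")


def k_neighborhood(g: GridGraph, i: int, K: int, metric: str = "euclidean") -> Neighborhood:
    """Return cell ``i`` plus its ``K`` nearest unmasked cells.

    Nearest cells are collected with a best-first expansion over the adjacency
    structure ordered by distance from the center, so the result is always
    spatially contiguous and never jumps across masked gaps.  Ties are broken
    by ascending cell id.  If the reachable component is exhausted a smaller
    neighborhood is returned with ``complete=False``.
    """
    if g.mask[i]:
        raise ValueError(f"cell {i} is masked")
    if K < 1:
        raise ValueError("K must be >= 1")
    members = {i}
    # heap entries: (distance, cell id, hop count)
    frontier = []
    seen = {i}
    for j in sorted(g.adjacency[i]):
        heapq.heappush(frontier, (_distance(g, metric, i, j, 1), j, 1))
        seen.add(j)
    while len(members) < K + 1 and frontier:
        _, j, hops = heapq.heappop(frontier)
        members.add(j)
        for nb in sorted(g.adjacency[j]):
            if nb not in seen:
                heapq.heappush(frontier, (_distance(g, metric, i, nb, hops + 1), nb, hops + 1))
                seen.add(nb)
    return Neighborhood(
        center=i,
        members=tuple(sorted(members)),
        complete=(len(members) == K + 1),
    )


def is_contiguous(g: GridGraph, A) -> bool:
    """True iff the subgraph induced by cell set ``A`` is connected."""
    A = set(A)
    if not A:
        raise ValueError("empty cell set")
    if any(g.mask[i] for i in A):
        raise ValueError("cell set contains masked cells")
    start = next(iter(A))
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in g.adjacency[u]:
            if v in A and v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(A)
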