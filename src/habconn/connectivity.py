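"""Circuit-theory connectivity on raster resistance surfaces.

Habitat suitability H in [0, 1] is mapped to resistance R in [1, 100]
either linearly (R = 100 - 99 H) or through an exponential-decay family

    R = 100 - 99 * (1 - exp(-c H)) / (1 - exp(-c)),

where larger c makes resistance drop faster at low suitability (c = 2 and
c = 8 are the conventional shapes).  The raster is then a resistor network:
one node per valid cell, 8-neighborhood edges with conductance equal to the
mean of the two cells' conductances (diagonals scaled by 1/sqrt(2)).  Node
regions are contracted to super-nodes; passing unit current between a pair
yields node potentials from the graph Laplacian, per-cell current density,
and the pair's effective resistance.  Summing current over all region pairs
gives the cumulative map that is classified into equal-count deciles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .geodata import Grid

__all__ = [
    "ResistanceTransform",
    "NodeRegion",
    "RasterGraph",
    "CurrentMap",
    "suitability_to_resistance",
    "grid_to_graph",
    "solve_pair",
    "cumulative_current",
    "quantile_classify",
]


@dataclass(frozen=True)
class ResistanceTransform:
    """Suitability-to-resistance mapping onto the [1, 100] scale."""

    kind: str = "exponential"  # "linear" | "exponential"
    c: float = 2.0

    def __post_init__(self):
        if self.kind not in ("linear", "exponential"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "exponential" and self.c == 0:
            raise ValueError("c = 0 is degenerate; use the linear transform")

    @property
    def label(self) -> str:
        return "linear" if self.kind == "linear" else f"exp_c{self.c:g}"

    def __call__(self, H: np.ndarray) -> np.ndarray:
        H = np.asarray(H, float)
        if self.kind == "linear":
            return 100.0 - 99.0 * H
        return 100.0 - 99.0 * (1.0 - np.exp(-self.c * H)) / (1.0 - np.exp(-self.c))


def suitability_to_resistance(H_grid: Grid, transform: ResistanceTransform) -> Grid:
    """Apply the transform cellwise; H outside [0, 1] is clipped with a warning."""
    import warnings

    mask = H_grid.valid_mask()
    H = np.asarray(H_grid.values, float)
    out_of_range = mask & ((H < 0) | (H > 1))
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} suitability cells outside [0, 1] were clipped",
            stacklevel=2,
        )
    R = transform(np.clip(H, 0.0, 1.0))
    out = np.where(mask, R, H_grid.nodata)
    return Grid(out, H_grid.cell_size, H_grid.origin, H_grid.nodata, H_grid.crs_tag)


@dataclass(frozen=True)
class NodeRegion:
    """Cell mask acting as one contracted circuit node."""

    label: str
    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, bool)
        if not m.any():
            raise ValueError(f"region {self.label!r} is empty")
        object.__setattr__(self, "mask", m)


@dataclass
class RasterGraph:
    """Resistor network of a resistance grid.

    ``node_index`` maps cells to node ids (-1 = nodata); ``edges_u/v`` are
    endpoint node ids and ``conductance`` the edge conductances.
    """

    grid: Grid
    node_index: np.ndarray
    edges_u: np.ndarray
    edges_v: np.ndarray
    conductance: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.node_index.max() + 1)

    def region_nodes(self, mask: np.ndarray) -> np.ndarray:
        ids = self.node_index[np.asarray(mask, bool)]
        ids = ids[ids >= 0]
        if ids.size == 0:
            raise ValueError("region intersects no valid cells")
        return ids


def grid_to_graph(R_grid: Grid, neighborhood: int = 8) -> RasterGraph:
    """Build the resistor network: edge conductance is the arithmetic mean of
    the two cells' conductances 1/R, diagonal edges scaled by 1/sqrt(2)."""
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    valid = R_grid.valid_mask()
    if not valid.any():
        raise ValueError("all-nodata resistance grid")
    R = np.asarray(R_grid.values, float)
    if np.any(R[valid] <= 0):
        raise ValueError("resistance must be positive on valid cells")
    g = np.where(valid, 1.0 / np.where(valid, R, 1.0), 0.0)
    node_index = -np.ones(R.shape, int)
    node_index[valid] = np.arange(int(valid.sum()))
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        s = 1.0 / np.sqrt(2.0)
        offsets += [(1, 1, s), (1, -1, s)]
    eu, ev, ec = [], [], []
    for di, dj, scale in offsets:
        a = np.s_[max(di, 0) : R.shape[0] - max(-di, 0), max(dj, 0) : R.shape[1] - max(-dj, 0)]
        b = np.s_[max(-di, 0) : R.shape[0] - max(di, 0), max(-dj, 0) : R.shape[1] - max(dj, 0)]
        ok = valid[a] & valid[b]
        eu.append(node_index[a][ok])
        ev.append(node_index[b][ok])
        ec.append(scale * 0.5 * (g[a][ok] + g[b][ok]))
    return RasterGraph(
        grid=R_grid,
        node_index=node_index,
        edges_u=np.concatenate(eu),
        edges_v=np.concatenate(ev),
        conductance=np.concatenate(ec),
    )


@dataclass
class CurrentMap:
    """Cumulative current density with per-pair effective resistances."""

    grid: Grid
    pairs: list[tuple[str, str]]
    effective_resistance: dict[tuple[str, str], float]


class DisconnectedError(RuntimeError):
    pass


def _contract(graph: RasterGraph, nodes_a: np.ndarray, nodes_b: np.ndarray):
    """Relabel nodes so region A -> id 0, region B -> id 1, rest 2..N'-1."""
    n = graph.n_nodes
    relabel = -np.ones(n, int)
    relabel[nodes_a] = 0
    relabel[nodes_b] = 1
    rest = np.flatnonzero(relabel < 0)
    relabel[rest] = 2 + np.arange(rest.size)
    return relabel, 2 + rest.size


def solve_pair(graph: RasterGraph, region_a: NodeRegion, region_b: NodeRegion):
    """Unit current from region A (contracted) to region B (grounded).

    Returns ``(current Grid, effective resistance)``.  Per-cell current is
    half the sum of absolute currents on the cell's incident edges; cells of
    the source/ground regions instead carry the full current they feed into
    the network.  Raises :class:`DisconnectedError` when A and B lie in
    different connected components.
    """
    na = graph.region_nodes(region_a.mask)
    nb = graph.region_nodes(region_b.mask)
    if np.intersect1d(na, nb).size:
        raise ValueError(f"regions {region_a.label!r} and {region_b.label!r} overlap")
    relabel, n_contracted = _contract(graph, na, nb)
    u = relabel[graph.edges_u]
    v = relabel[graph.edges_v]
    keep = u != v  # intra-region edges vanish on contraction
    u, v, c = u[keep], v[keep], graph.conductance[keep]
    adj = coo_matrix((c, (u, v)), shape=(n_contracted, n_contracted))
    adj = adj + adj.T
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if labels[0] != labels[1]:
        sizes = np.bincount(labels)
        raise DisconnectedError(
            f"regions {region_a.label!r} (component {labels[0]}, {sizes[labels[0]]} nodes) and "
            f"{region_b.label!r} (component {labels[1]}, {sizes[labels[1]]} nodes) are disconnected"
        )
    comp = labels == labels[0]
    sub = np.flatnonzero(comp)
    pos = -np.ones(n_contracted, int)
    pos[sub] = np.arange(sub.size)
    in_comp = comp[u]
    uu, vv, cc = pos[u[in_comp]], pos[v[in_comp]], c[in_comp]
    m = sub.size
    deg = np.bincount(uu, weights=cc, minlength=m) + np.bincount(vv, weights=cc, minlength=m)
    L = coo_matrix(
        (
            np.concatenate([deg, -cc, -cc]),
            (np.concatenate([np.arange(m), uu, vv]), np.concatenate([np.arange(m), vv, uu])),
        ),
        shape=(m, m),
    ).tocsc()
    ground = pos[1]  # region B node
    keep_idx = np.delete(np.arange(m), ground)
    Lr = L[np.ix_(keep_idx, keep_idx)]
    rhs = np.zeros(m)
    rhs[pos[0]] = 1.0  # unit current injected at region A
    rhs = rhs[keep_idx]
    sol = splu(Lr.tocsc()).solve(rhs)
    pot = np.zeros(n_contracted)
    pot[sub[keep_idx]] = sol
    r_eff = float(pot[0] - pot[1])
    # per-edge currents on the original (uncontracted) edge list
    pu = pot[relabel[graph.edges_u]]
    pv = pot[relabel[graph.edges_v]]
    live = relabel[graph.edges_u] != relabel[graph.edges_v]
    i_edge = np.where(live, graph.conductance * (pu - pv), 0.0)
    n = graph.n_nodes
    abs_sum = np.bincount(graph.edges_u, weights=np.abs(i_edge), minlength=n)
    abs_sum += np.bincount(graph.edges_v, weights=np.abs(i_edge), minlength=n)
    node_cur = 0.5 * abs_sum
    node_cur[na] = abs_sum[na]  # source cells: current carried into the network
    node_cur[nb] = abs_sum[nb]
    cur = np.full(graph.grid.shape, graph.grid.nodata, float)
    cur[graph.node_index >= 0] = node_cur[graph.node_index[graph.node_index >= 0]]
    out = Grid(cur, graph.grid.cell_size, graph.grid.origin, graph.grid.nodata, graph.grid.crs_tag)
    return out, r_eff


def cumulative_current(graph: RasterGraph, regions: list[NodeRegion]) -> CurrentMap:
    """Sum per-cell current over all unordered region pairs.

    Failing pairs (e.g. disconnected) are reported in
    ``effective_resistance`` as ``nan`` and do not abort the others.
    """
    if len(regions) < 2:
        raise ValueError("need >= 2 node regions")
    for a, b in combinations(regions, 2):
        if (a.mask & b.mask).any():
            raise ValueError(f"regions {a.label!r} and {b.label!r} overlap")
    geom = graph.grid
    total = np.zeros(geom.shape)
    valid = geom.valid_mask()
    pairs, reff = [], {}
    for a, b in combinations(regions, 2):
        key = (a.label, b.label)
        pairs.append(key)
        try:
            cur, r = solve_pair(graph, a, b)
        except (DisconnectedError, ValueError) as exc:
            reff[key] = float("nan")
            import warnings

            warnings.warn(f"pair {key}: {exc}", stacklevel=2)
            continue
        total[valid] += cur.values[valid]
        reff[key] = r
    out = np.where(valid, total, geom.nodata)
    grid = Grid(out, geom.cell_size, geom.origin, geom.nodata, geom.crs_tag)
    return CurrentMap(grid=grid, pairs=pairs, effective_resistance=reff)


def quantile_classify(current_map: Grid, n_bins: int = 10) -> Grid:
    """Equal-count bins 1..n_bins over valid cells with positive current
    (bin n_bins = highest current)."""
    valid = current_map.valid_mask()
    vals = current_map.values[valid]
    pos = vals[vals > 0]
    if np.unique(pos).size < n_bins:
        raise ValueError(
            f"need >= {n_bins} distinct positive current values, got {np.unique(pos).size}"
        )
    edges = np.quantile(pos, np.linspace(0, 1, n_bins + 1)[1:-1])
    binned = np.zeros(current_map.shape)
    pv = current_map.values
    binned[valid] = np.where(pv[valid] > 0, np.searchsorted(edges, pv[valid], side="left") + 1, 0)
    out = np.where(valid, binned, current_map.nodata)
    return Grid(out, current_map.cell_size, current_map.origin, current_map.nodata,
                current_map.crs_tag)
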