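"""Multilevel force-directed layout in 2D or 3D.

The scheme follows the multilevel family of force-directed algorithms
(FMMM and kin): the graph is coarsened by repeated matching-based node
merging, the coarsest level is placed at random (seeded), and positions
are refined level by level with a spring-embedder sweep, each finer
level inheriting its parent's coordinates.

Force model (Fruchterman-Reingold, natural edge length ``l``):

* attraction along each edge, magnitude ``d^2 / l``;
* repulsion between node pairs closer than the cutoff ``R = 3 l``,
  magnitude ``l^2 / d`` (zero beyond the cutoff).

The truncated repulsion is what makes the grid acceleration exact: only
pairs in neighbouring grid cells of side ``R`` can interact, giving
O(n) work per sweep at bounded density instead of O(n^2).  An isolated
dyad therefore equilibrates where ``d^2/l = l^2/d``, i.e. exactly at
``d = l``.

Each sweep is accept/reject on the total energy

    E = sum_edges d^3 / (3 l)  +  sum_{pairs, d<R} l^2 ln(R / d)

so energy is non-increasing across sweeps by construction; a rejected
sweep halves the temperature (maximum per-node displacement), an
accepted one cools it geometrically by 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError
from .graph import TypedGraph

_EPS = 1e-12


@dataclass
class LayoutParams:
    """Knobs of the layout; all lengths in units of the natural edge length."""

    edge_length: float = 1.0      # natural spring length l (arbitrary units)
    repulsion: float = 1.0        # scales the repulsive constant l^2
    cutoff_factor: float = 3.0    # repulsion range R = cutoff_factor * l
    max_sweeps: int = 120         # refinement sweeps per level
    tol: float = 1e-3             # stop when max displacement < tol * l
    stop_size: int = 8            # coarsening stops at this many nodes

    def __post_init__(self) -> None:
        if min(self.edge_length, self.repulsion, self.cutoff_factor,
               self.max_sweeps, self.tol, self.stop_size) <= 0:
            raise PreconditionError("all layout parameters must be positive")


@dataclass
class LayoutResult:
    coordinates: dict[str, np.ndarray]
    dims: int
    seed: int
    iterations_used: int

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.coordinates[n] for n in order])


@dataclass
class CoarseLevel:
    """One level of the coarsening hierarchy."""

    n_nodes: int
    edges: np.ndarray                 # (m, 2) int array, deduplicated, no loops
    project: np.ndarray | None = None  # this level's node -> coarser node
    node_ids: list[str] | None = None  # only on the finest level


def coarsen(graph: TypedGraph, stop_size: int = 8) -> list[CoarseLevel]:
    """Matching-based coarsening hierarchy, finest level first.

    Matched neighbour pairs merge into one coarse node; unmatched nodes
    survive as singletons.  Levels strictly shrink; coarsening stops at
    ``stop_size`` nodes or when no neighbour pair can be matched (e.g. an
    edgeless graph).
    """
    if stop_size < 2:
        raise PreconditionError("stop_size must be >= 2")
    ids = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(ids)}
    edge_set = {
        (min(index[e.source], index[e.target]), max(index[e.source], index[e.target]))
        for e in graph.edges
        if e.source != e.target
    }
    edges = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
    levels = [CoarseLevel(n_nodes=len(ids), edges=edges, node_ids=ids)]

    while levels[-1].n_nodes > stop_size:
        level = levels[-1]
        adj: dict[int, list[int]] = {i: [] for i in range(level.n_nodes)}
        for u, v in level.edges:
            adj[int(u)].append(int(v))
            adj[int(v)].append(int(u))
        match = np.full(level.n_nodes, -1, dtype=np.int64)
        merged_any = False
        for u in range(level.n_nodes):
            if match[u] >= 0:
                continue
            for v in sorted(adj[u]):
                if v != u and match[v] < 0:
                    match[u] = v
                    match[v] = u
                    merged_any = True
                    break
        if not merged_any:
            break
        project = np.full(level.n_nodes, -1, dtype=np.int64)
        next_id = 0
        for u in range(level.n_nodes):
            if project[u] >= 0:
                continue
            project[u] = next_id
            if match[u] >= 0:
                project[match[u]] = next_id
            next_id += 1
        coarse_edges = {
            (min(int(project[u]), int(project[v])), max(int(project[u]), int(project[v])))
            for u, v in level.edges
            if project[u] != project[v]
        }
        level.project = project
        levels.append(
            CoarseLevel(
                n_nodes=next_id,
                edges=np.array(sorted(coarse_edges), dtype=np.int64).reshape(-1, 2),
            )
        )
    return levels


def _repulsion(pos: np.ndarray, k: float, c_rep: float, cutoff: float):
    """Truncated-cutoff repulsive forces and energy.

    Dense pairwise for small n; grid buckets of cell side ``cutoff`` for
    large n (identical physics — only pairs within the cutoff interact).
    """
    n = len(pos)
    forces = np.zeros_like(pos)
    energy = 0.0
    if n <= 600:
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(-1)) + _EPS
        np.fill_diagonal(d, np.inf)
        mask = d < cutoff
        mag = np.where(mask, c_rep * k**2 / d, 0.0)
        forces = ((mag / d)[:, :, None] * diff).sum(axis=1)
        with np.errstate(divide="ignore"):
            energy = float(np.where(mask, c_rep * k**2 * np.log(cutoff / d), 0.0).sum()) / 2.0
        return forces, energy

    cells: dict[tuple, list[int]] = {}
    keys = np.floor(pos / cutoff).astype(np.int64)
    for i in range(n):
        cells.setdefault(tuple(keys[i]), []).append(i)
    dims = pos.shape[1]
    from itertools import product as _product

    offsets = list(_product((-1, 0, 1), repeat=dims))
    for key, members in cells.items():
        idx = np.array(members)
        neigh: list[int] = []
        for off in offsets:
            neigh.extend(cells.get(tuple(np.array(key) + np.array(off)), []))
        jdx = np.array(sorted(neigh))
        diff = pos[idx][:, None, :] - pos[jdx][None, :, :]
        d = np.sqrt((diff**2).sum(-1)) + _EPS
        same = idx[:, None] == jdx[None, :]
        d = np.where(same, np.inf, d)
        mask = d < cutoff
        mag = np.where(mask, c_rep * k**2 / d, 0.0)
        forces[idx] += ((mag / d)[:, :, None] * diff).sum(axis=1)
        with np.errstate(divide="ignore"):
            energy += float(np.where(mask, c_rep * k**2 * np.log(cutoff / d), 0.0).sum()) / 2.0
    return forces, energy


def _attraction(pos: np.ndarray, edges: np.ndarray, k: float):
    forces = np.zeros_like(pos)
    if len(edges) == 0:
        return forces, 0.0
    dvec = pos[edges[:, 1]] - pos[edges[:, 0]]
    d = np.sqrt((dvec**2).sum(-1)) + _EPS
    # F = d^2/k along the edge -> vector contribution dvec * d / k
    contrib = dvec * (d / k)[:, None]
    np.add.at(forces, edges[:, 0], contrib)
    np.add.at(forces, edges[:, 1], -contrib)
    energy = float((d**3).sum() / (3.0 * k))
    return forces, energy


def _energy(pos: np.ndarray, edges: np.ndarray, k: float, c_rep: float, cutoff: float) -> float:
    _, e_rep = _repulsion(pos, k, c_rep, cutoff)
    _, e_att = _attraction(pos, edges, k)
    return e_rep + e_att


def _refine(pos: np.ndarray, edges: np.ndarray, params: LayoutParams,
            temp: float) -> tuple[np.ndarray, int]:
    k = params.edge_length
    cutoff = params.cutoff_factor * k
    energy = _energy(pos, edges, k, params.repulsion, cutoff)
    sweeps = 0
    for _ in range(params.max_sweeps):
        f_rep, _ = _repulsion(pos, k, params.repulsion, cutoff)
        f_att, _ = _attraction(pos, edges, k)
        force = f_rep + f_att
        norm = np.sqrt((force**2).sum(-1)) + _EPS
        step = np.minimum(norm, temp)
        disp = force / norm[:, None] * step[:, None]
        proposal = pos + disp
        new_energy = _energy(proposal, edges, k, params.repulsion, cutoff)
        sweeps += 1
        if new_energy <= energy + _EPS:
            moved = float(np.sqrt((disp**2).sum(-1)).max())
            pos = proposal
            energy = new_energy
            temp *= 0.95
            if moved < params.tol * k:
                break
        else:
            temp *= 0.5
        if temp < params.tol * k:
            break
    return pos, sweeps


def layout(graph: TypedGraph, dims: int = 2, params: LayoutParams | None = None,
           seed: int = 42) -> LayoutResult:
    """Seeded multilevel force-directed layout; origin-centred coordinates."""
    if graph.n_nodes == 0:
        raise PreconditionError("cannot lay out an empty graph")
    if dims not in (2, 3):
        raise PreconditionError("dims must be 2 or 3")
    params = params or LayoutParams()
    k = params.edge_length
    rng = np.random.RandomState(seed)

    ids = sorted(graph.nodes)
    if len(ids) == 1:
        return LayoutResult({ids[0]: np.zeros(dims)}, dims, seed, 0)

    levels = coarsen(graph, params.stop_size)
    coarsest = levels[-1]
    side = k * np.sqrt(coarsest.n_nodes)
    pos = rng.uniform(-side / 2.0, side / 2.0, size=(coarsest.n_nodes, dims))

    total_sweeps = 0
    for level in reversed(levels):
        if level is not coarsest:
            # prolong: children start at the parent position plus jitter
            pos = pos[level.project] + rng.normal(scale=0.05 * k,
                                                  size=(level.n_nodes, dims))
        pos, sweeps = _refine(pos, level.edges, params, temp=k)
        total_sweeps += sweeps

    pos = pos - pos.mean(axis=0)
    coords = {nid: pos[i].copy() for i, nid in enumerate(ids)}
    return LayoutResult(coords, dims, seed, total_sweeps)


def layout_energy(graph: TypedGraph, result: LayoutResult,
                  params: LayoutParams | None = None) -> float:
    """Total energy of a layout under the package's force model."""
    params = params or LayoutParams()
    ids = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(ids)}
    pos = result.as_array(ids)
    edge_set = {
        (min(index[e.source], index[e.target]), max(index[e.source], index[e.target]))
        for e in graph.edges
        if e.source != e.target
    }
    edges = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
    return _energy(pos, edges, params.edge_length, params.repulsion,
                   params.cutoff_factor * params.edge_length)
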