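"""Graphs, lattices, local neighborhoods, and graph-respecting partitions.

A partition of a graph's vertices is *graph respecting* when every block
induces a connected subgraph.  Restricting a mixture model to such
partitions shrinks the discrete state space dramatically relative to
unrestricted set partitions (e.g. 1434 vs the 9th Bell number 21147 for a
3x3 lattice), which is what makes exhaustive local inference tractable.

Vertices are integers ``0..N-1``.  Lattice graphs carry integer
coordinates with vertex id ``v = x + dims[0]*(y + dims[1]*z)`` (x fastest).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "Partition",
    "Subgraph",
    "NEIGHBORHOOD_KINDS",
    "build_lattice_graph",
    "read_edge_list",
    "window_offsets",
    "local_subgraph",
    "is_graph_respecting",
    "enumerate_graph_respecting_partitions",
    "bell_number",
    "central_block_stats",
]

NEIGHBORHOOD_KINDS = ("lattice3x3", "star2d", "star3d")

#: safety cap on exhaustive partition enumeration
DEFAULT_ENUMERATION_CAP = 12


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with optional integer lattice coordinates."""

    n: int
    edges: frozenset[tuple[int, int]]
    coords: np.ndarray | None = None
    dims: tuple[int, ...] | None = None

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) endpoint outside 0..{self.n - 1}")
            if u > v:
                raise ValueError("edges must be stored as sorted pairs")

    @property
    def vertices(self) -> range:
        return range(self.n)

    def adjacency_masks(self) -> list[int]:
        """Per-vertex bitmask of neighbors (fast connectivity primitives)."""
        adj = [0] * self.n
        for u, v in self.edges:
            adj[u] |= 1 << v
            adj[v] |= 1 << u
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        return _mask_connected((1 << self.n) - 1, self.adjacency_masks())

    def shape_key(self) -> tuple:
        return (self.n, tuple(sorted(self.edges)))


def make_edges(pairs: Iterable[Sequence[int]]) -> frozenset[tuple[int, int]]:
    return frozenset((min(u, v), max(u, v)) for u, v in pairs)


@dataclass(frozen=True)
class Partition:
    """Canonical partition: blocks sorted by smallest member, sorted within."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        canon = tuple(sorted((tuple(sorted(b)) for b in self.blocks), key=lambda b: b[0]))
        object.__setattr__(self, "blocks", canon)
        seen: set[int] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("empty block")
            if seen & set(b):
                raise ValueError("blocks are not disjoint")
            seen.update(b)

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks)

    def block_of(self, v: int) -> int:
        for k, b in enumerate(self.blocks):
            if v in b:
                return k
        raise KeyError(f"vertex {v} not in partition")

    def labels(self) -> np.ndarray:
        lab = np.empty(self.n, dtype=np.intp)
        for k, b in enumerate(self.blocks):
            lab[list(b)] = k
        return lab


@dataclass(frozen=True)
class Subgraph:
    """A local subgraph: vertex ids of the parent graph plus local structure.

    ``vertices[i]`` is the parent id of local vertex ``i``; ``center`` is the
    local index of the window center; ``slots`` are indices into the
    canonical full-window offset list (used to subset globally estimated
    scale matrices to clipped windows).
    """

    graph: Graph
    vertices: tuple[int, ...]
    center: int
    slots: tuple[int, ...]


def build_lattice_graph(dims: Sequence[int]) -> Graph:
    """Rook-adjacency lattice graph: edges connect points at L1 distance 1."""
    dims = tuple(int(d) for d in dims)
    if len(dims) not in (2, 3):
        raise ValueError("dims must have 2 or 3 entries")
    if any(d < 1 for d in dims):
        raise ValueError("lattice dims must be positive")
    n = int(np.prod(dims))
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    # vertex id = x + dims[0]*(y + dims[1]*z): x fastest -> Fortran raveling
    coords = np.stack([g.ravel(order="F") for g in grids], axis=1)
    edges = []
    strides = [1, dims[0], dims[0] * dims[1]]
    for axis, d in enumerate(dims):
        mask = coords[:, axis] < d - 1
        for v in np.flatnonzero(mask):
            edges.append((int(v), int(v + strides[axis])))
    return Graph(n=n, edges=make_edges(edges), coords=coords, dims=dims)


def read_edge_list(path) -> Graph:
    """Read a two-column whitespace-delimited edge list into a Graph."""
    arr = np.loadtxt(path, dtype=int, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError("edge list must have exactly two integer columns")
    n = int(arr.max()) + 1 if arr.size else 0
    return Graph(n=n, edges=make_edges(arr.tolist()))


def window_offsets(kind: str, ndim: int) -> list[tuple[int, ...]]:
    """Canonical offset list of the full (unclipped) window for a neighborhood.

    The center is always slot 0; remaining slots are sorted lexicographically.
    """
    if kind not in NEIGHBORHOOD_KINDS:
        raise ValueError(f"unknown neighborhood kind {kind!r}")
    if kind == "star3d" and ndim != 3:
        raise ValueError("star3d requires a 3D lattice")
    zero = (0,) * ndim
    if kind == "lattice3x3":
        offs = [(dx, dy) + (0,) * (ndim - 2) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    elif kind == "star2d":
        offs = [zero, (-1,) + (0,) * (ndim - 1), (1,) + (0,) * (ndim - 1),
                (0, -1) + (0,) * (ndim - 2), (0, 1) + (0,) * (ndim - 2)]
    else:  # star3d
        offs = [zero]
        for axis in range(3):
            for s in (-1, 1):
                o = [0, 0, 0]
                o[axis] = s
                offs.append(tuple(o))
    offs = [o for o in offs if o != zero]
    return [zero] + sorted(offs)


def local_subgraph(graph: Graph, center: int, kind: str) -> Subgraph:
    """Extract the local model subgraph around ``center``.

    ``lattice3x3`` gives the induced subgraph on the in-slice 3x3 window
    (clipped at lattice borders); ``star2d``/``star3d`` give the center plus
    its 4 (in-slice) or 6 first-order neighbors with center-leaf edges only.
    """
    if graph.coords is None or graph.dims is None:
        raise ValueError("local_subgraph requires a lattice graph with coords")
    if not (0 <= center < graph.n):
        raise KeyError(f"vertex {center} not in graph")
    dims = graph.dims
    ndim = len(dims)
    offs = window_offsets(kind, ndim)
    c = tuple(int(x) for x in graph.coords[center])
    strides = [1, dims[0], dims[0] * dims[1] if ndim == 3 else 0]

    vertices: list[int] = []
    slots: list[int] = []
    for slot, off in enumerate(offs):
        p = tuple(c[a] + off[a] for a in range(ndim))
        if all(0 <= p[a] < dims[a] for a in range(ndim)):
            vertices.append(sum(p[a] * strides[a] for a in range(ndim)))
            slots.append(slot)
    local_index = {g: i for i, g in enumerate(vertices)}

    if kind == "lattice3x3":
        pos = {g: graph.coords[g] for g in vertices}
        pairs = [
            (local_index[u], local_index[v])
            for u, v in combinations(vertices, 2)
            if int(np.abs(pos[u] - pos[v]).sum()) == 1
        ]
    else:
        ci = local_index[center]
        pairs = [(ci, i) for i in range(len(vertices)) if i != ci]
    sub = Graph(n=len(vertices), edges=make_edges(pairs))
    return Subgraph(graph=sub, vertices=tuple(vertices),
                    center=local_index[center], slots=tuple(slots))


def _mask_connected(mask: int, adj: list[int]) -> bool:
    if mask == 0:
        return False
    start = mask & -mask
    seen = start
    frontier = start
    while frontier:
        nxt = 0
        m = frontier
        while m:
            u = m & -m
            m ^= u
            nxt |= adj[u.bit_length() - 1]
        frontier = nxt & mask & ~seen
        seen |= frontier
    return seen == mask


def is_graph_respecting(partition: Partition, graph: Graph) -> bool:
    """True iff every block of ``partition`` induces a connected subgraph."""
    covered = sorted(v for b in partition.blocks for v in b)
    if covered != list(range(graph.n)):
        raise ValueError("partition does not cover the graph's vertex set")
    adj = graph.adjacency_masks()
    for b in partition.blocks:
        mask = 0
        for v in b:
            mask |= 1 << v
        block_adj = [adj[v] & mask for v in range(graph.n)]
        if not _mask_connected(mask, block_adj):
            return False
    return True


def _connected_supersets(seed: int, allowed: int, adj: list[int]) -> list[int]:
    """All connected vertex subsets (bitmasks) of ``allowed`` containing seed."""
    out: list[int] = []

    def rec(cur: int, cand: int, banned: int) -> None:
        if cand == 0:
            out.append(cur)
            return
        u = cand & -cand
        rec(cur, cand ^ u, banned | u)  # u excluded from this subset forever
        ui = u.bit_length() - 1
        newcur = cur | u
        newcand = ((cand ^ u) | (adj[ui] & allowed)) & ~newcur & ~banned
        rec(newcur, newcand, banned)

    si = seed.bit_length() - 1
    rec(seed, adj[si] & allowed & ~seed, 0)
    return out


_PARTITION_CACHE: dict[tuple, tuple[Partition, ...]] = {}


def enumerate_graph_respecting_partitions(
    graph: Graph, cap: int = DEFAULT_ENUMERATION_CAP
) -> tuple[Partition, ...]:
    """Exhaustively enumerate all graph-respecting partitions.

    The block containing the smallest unassigned vertex is grown over all
    connected subsets of the remaining induced graph, then the remainder is
    handled recursively.  Results are cached per graph shape.
    """
    if graph.n > cap:
        raise ValueError(f"graph order {graph.n} exceeds enumeration cap {cap}")
    if not graph.is_connected():
        raise ValueError("enumeration requires a connected graph")
    key = graph.shape_key()
    hit = _PARTITION_CACHE.get(key)
    if hit is not None:
        return hit

    adj = graph.adjacency_masks()
    results: list[list[int]] = []

    def rec(remaining: int, acc: list[int]) -> None:
        if remaining == 0:
            results.append(acc.copy())
            return
        seed = remaining & -remaining
        for block in _connected_supersets(seed, remaining, adj):
            acc.append(block)
            rec(remaining & ~block, acc)
            acc.pop()

    rec((1 << graph.n) - 1, [])

    def unmask(mask: int) -> tuple[int, ...]:
        out = []
        while mask:
            u = mask & -mask
            mask ^= u
            out.append(u.bit_length() - 1)
        return tuple(out)

    parts = tuple(Partition(tuple(unmask(m) for m in blocks)) for blocks in results)
    _PARTITION_CACHE[key] = parts
    return parts


def bell_number(n: int) -> int:
    """Exact Bell number via the Bell-triangle recurrence (0 <= n <= 20)."""
    if not (0 <= n <= 20):
        raise ValueError("bell_number supports 0 <= n <= 20")
    if n == 0:
        return 1
    row = [1]
    for _ in range(n - 1):
        nxt = [row[-1]]
        for x in row:
            nxt.append(nxt[-1] + x)
        row = nxt
    return row[-1]


def central_block_stats(partitions: Sequence[Partition], center: int) -> dict:
    """Distribution of the center vertex's block size under the uniform law.

    Returns the probability mass function of the size of the block containing
    ``center`` and the median block count K over the given partitions.
    """
    if not partitions:
        raise ValueError("empty partition list")
    sizes = []
    ks = []
    for p in partitions:
        b = p.blocks[p.block_of(center)]
        sizes.append(len(b))
        ks.append(p.K)
    uniq, counts = np.unique(sizes, return_counts=True)
    pmf = {int(s): float(c) / len(partitions) for s, c in zip(uniq, counts)}
    return {
        "size_pmf": pmf,
        "median_K": float(statistics.median(ks)),
        "n_partitions": len(partitions),
    }
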