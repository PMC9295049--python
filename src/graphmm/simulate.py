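"""Lattice-structured synthetic two-group data with blocked latent means.

Scenarios emulate a coronal brain slice: a contiguous partition of the
lattice carries block-constant base means, a fraction of blocks is shifted
between the groups, and Gaussian noise (independent or spatially
correlated) is added per sample.  Ground truth (the partition, the shifted
blocks, per-vertex null indicators) is recorded so empirical FDR and TPR
can be scored exactly.

Blocks are consecutive segments of a serpentine traversal of the lattice:
contiguity is guaranteed by construction and the segment lengths follow the
requested block-size law exactly, at the cost of elongated block shapes
(see the methods note).  Setting ``graph_respecting=False`` afterwards
reassigns a fraction of vertices to non-adjacent blocks, producing latent
means that are clustered but not contiguous (the robustness experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graphs import Graph, Partition, build_lattice_graph
from .model import TwoGroupData

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "scenario_preset",
    "generate_blocked_partition",
    "generate_scenario_data",
    "simulate_scenario",
    "permute_sample_labels",
    "permute_voxels",
]


@dataclass
class ScenarioSpec:
    """Parameters of one generative scenario."""

    dims: tuple[int, ...] = (20, 25)
    block_size_law: tuple = ("uniform", 12, 14)
    shift_fraction: float = 0.2
    shift_magnitude: float = 0.6     # in units of the marginal noise SD
    noise: tuple = ("independent",)  # or ("gaussian", range_in_voxels)
    M_X: int = 30
    M_Y: int = 30
    mu0: float = 0.0
    tau2: float = 1.0
    graph_respecting: bool = True
    reassign_fraction: float = 0.2   # only used when graph_respecting=False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must lie in [0, 1]")
        if not (0.0 <= self.reassign_fraction <= 1.0):
            raise ValueError("reassign_fraction must lie in [0, 1]")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")
        if not np.isfinite(self.shift_magnitude):
            raise ValueError("shift_magnitude must be finite")


@dataclass
class GroundTruth:
    """Latent truth of a synthetic data set."""

    partition: Partition
    shifted_blocks: frozenset[int]
    is_null: np.ndarray
    block_means_x: np.ndarray | None = None   # per-block base means (group 1)
    block_means_y: np.ndarray | None = None   # per-block means of group 2

    def __post_init__(self):
        labels = self.partition.labels()
        expect = ~np.isin(labels, list(self.shifted_blocks))
        if not np.array_equal(expect, self.is_null):
            raise ValueError("null indicators inconsistent with shifted blocks")


_PRESETS = {
    # scenario 1: large blocks (12-14 voxels), moderate shifts
    1: dict(block_size_law=("uniform", 12, 14), shift_fraction=0.2, shift_magnitude=0.6),
    # scenario 2: blocks sized like the local prior's typical blocks
    2: dict(block_size_law=("uniform", 2, 4), shift_fraction=0.2, shift_magnitude=0.6),
    # scenario 3: very large blocks
    3: dict(block_size_law=("uniform", 20, 25), shift_fraction=0.2, shift_magnitude=0.6),
    # scenario 4: mean block size 4; fewer, relatively strong changes
    4: dict(block_size_law=("mean", 4.0), shift_fraction=0.1, shift_magnitude=1.0),
    # scenario 5: mean block size 4; more frequent, relatively weak changes
    5: dict(block_size_law=("mean", 4.0), shift_fraction=0.4, shift_magnitude=0.35),
}


def scenario_preset(number: int, **overrides) -> ScenarioSpec:
    """The five study scenario shapes, as ScenarioSpec instances."""
    if number not in _PRESETS:
        raise KeyError(f"scenario {number} not defined (1-5)")
    return ScenarioSpec(**{**_PRESETS[number], **overrides})


def _serpentine_order(dims: tuple[int, ...]) -> np.ndarray:
    """Vertex ids along a boustrophedon path (consecutive ids are adjacent)."""
    nx = dims[0]
    order = []
    planes = range(dims[2]) if len(dims) == 3 else [0]
    stride_z = dims[0] * dims[1]
    for z in planes:
        for y in range(dims[1]):
            row = np.arange(nx) + dims[0] * y + stride_z * z
            if (y + z) % 2 == 1:
                row = row[::-1]
            order.extend(row.tolist())
    return np.asarray(order)


def _sample_sizes(law: tuple, n: int, rng: np.random.Generator) -> list[int]:
    kind = law[0]
    if kind == "singleton":
        return [1] * n
    if kind == "uniform":
        lo, hi = int(law[1]), int(law[2])
        if lo < 1 or hi < lo:
            raise ValueError("uniform law needs 1 <= lo <= hi")
        if n < lo:
            raise ValueError("lattice smaller than the minimum block size")
        # random composition of n with all parts in [lo, hi]
        m = int(round(n / ((lo + hi) / 2)))
        m = max(m, -(-n // hi))           # enough parts to stay <= hi
        m = min(m, n // lo)               # few enough to stay >= lo
        if not (m * lo <= n <= m * hi):
            raise ValueError(f"cannot tile {n} vertices with parts in [{lo},{hi}]")
        sizes = np.full(m, lo)
        extra = n - m * lo
        while extra > 0:
            room = np.flatnonzero(sizes < hi)
            take = min(extra, room.size)
            bump = rng.choice(room, size=take, replace=False)
            sizes[bump] += 1
            extra -= take
        return rng.permutation(sizes).tolist()
    if kind == "mean":
        mean = float(law[1])
        if mean < 1:
            raise ValueError("mean block size must be >= 1")
        sizes = []
        left = n
        while left > 0:
            s = 1 + rng.poisson(mean - 1.0)
            s = min(s, left)
            sizes.append(int(s))
            left -= s
        return sizes
    raise ValueError(f"unknown block size law {kind!r}")


def generate_blocked_partition(spec: ScenarioSpec, rng=None) -> Partition:
    """Contiguous random partition of the lattice matching the size law."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    graph = build_lattice_graph(spec.dims)
    order = _serpentine_order(spec.dims)
    sizes = _sample_sizes(spec.block_size_law, graph.n, rng)
    blocks = []
    pos = 0
    for s in sizes:
        blocks.append(tuple(int(v) for v in order[pos:pos + s]))
        pos += s
    part = Partition(tuple(blocks))
    if not spec.graph_respecting:
        part = _scatter_vertices(part, graph, spec.reassign_fraction, rng)
    return part


def _scatter_vertices(part: Partition, graph: Graph, fraction: float, rng) -> Partition:
    """Reassign a fraction of vertices to non-adjacent blocks (breaking
    contiguity while keeping the latent means clustered)."""
    blocks = [set(b) for b in part.blocks]
    labels = part.labels()
    adj = [set() for _ in range(graph.n)]
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    n_move = int(round(fraction * graph.n))
    movers = rng.choice(graph.n, size=n_move, replace=False)
    for v in movers:
        src = labels[v]
        if len(blocks[src]) <= 1:
            continue
        neighbor_blocks = {labels[u] for u in adj[v]} | {src}
        candidates = [k for k in range(len(blocks)) if k not in neighbor_blocks]
        if not candidates:
            continue
        dst = int(rng.choice(candidates))
        blocks[src].discard(int(v))
        blocks[dst].add(int(v))
        labels[v] = dst
    return Partition(tuple(tuple(sorted(b)) for b in blocks if b))


def _noise_chol(spec: ScenarioSpec, graph: Graph) -> np.ndarray | None:
    if spec.noise[0] == "independent":
        return None
    if spec.noise[0] == "gaussian":
        rho = float(spec.noise[1])
        d2 = ((graph.coords[:, None, :] - graph.coords[None, :, :]) ** 2).sum(axis=2)
        C = np.exp(-d2 / (2.0 * rho**2))
        return np.linalg.cholesky(C + 1e-8 * np.eye(graph.n))
    raise ValueError(f"unknown noise model {spec.noise[0]!r}")


def generate_scenario_data(
    partition: Partition, spec: ScenarioSpec, rng=None
) -> tuple[TwoGroupData, GroundTruth]:
    """Draw one data set given a (usually blocked) latent partition.

    Block base-means are N(mu0, tau2); each block is shifted with
    probability ``shift_fraction`` by +-shift_magnitude noise-SDs in group 2.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    graph = build_lattice_graph(spec.dims)
    if partition.n != graph.n:
        raise ValueError("partition does not cover the lattice")
    K = partition.K
    labels = partition.labels()
    phi = rng.normal(spec.mu0, np.sqrt(spec.tau2), size=K)
    shifted = rng.random(K) < spec.shift_fraction
    signs = rng.choice([-1.0, 1.0], size=K)
    nu = phi + shifted * signs * spec.shift_magnitude  # noise SD is 1 by construction
    chol = _noise_chol(spec, graph)

    def draw(mean_v, M):
        noise = rng.standard_normal((graph.n, M))
        if chol is not None:
            noise = chol @ noise
        return mean_v[:, None] + noise

    X = draw(phi[labels], spec.M_X)
    Y = draw(nu[labels], spec.M_Y)
    truth = GroundTruth(partition=partition,
                        shifted_blocks=frozenset(np.flatnonzero(shifted).tolist()),
                        is_null=~shifted[labels],
                        block_means_x=phi, block_means_y=nu)
    return TwoGroupData(X, Y), truth


def simulate_scenario(spec: ScenarioSpec) -> tuple[TwoGroupData, GroundTruth]:
    """Partition + data in one call, fully reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    part = generate_blocked_partition(spec, rng)
    return generate_scenario_data(part, spec, rng)


def permute_sample_labels(data: TwoGroupData, seed: int) -> TwoGroupData:
    """Pool all columns and re-split at random into the original group sizes."""
    rng = np.random.default_rng(seed)
    pooled = np.hstack([data.X, data.Y])
    perm = rng.permutation(pooled.shape[1])
    pooled = pooled[:, perm]
    return TwoGroupData(pooled[:, : data.M_X], pooled[:, data.M_X:])


def permute_voxels(data: TwoGroupData, seed: int) -> tuple[TwoGroupData, np.ndarray]:
    """Apply one random vertex permutation identically to every sample.

    Preserves per-vertex marginals but destroys spatial structure.  Returns
    the permuted data and the permutation p (row v of the output is row
    p[v] of the input), so the operation can be inverted exactly.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_vertices)
    return TwoGroupData(data.X[perm], data.Y[perm]), perm
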