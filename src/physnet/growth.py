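"""Sequential growth of a physical network on a lattice substrate.

A first node is seeded and grown freely to a target volume; every later node
starts at a uniformly random unoccupied site and grows — by a loop-erased
random walk or a digitized straight ray — until its head steps onto a site
owned by an existing node, at which point the lattice edge crossed becomes a
bond and a single combinatorial link is recorded.  Running until no free
site remains ("saturation") with the walk process produces a uniform
spanning tree of the torus partitioned into node trajectories.

The inner walk loops are deliberately written against flat Python lists with
batched RNG draws: they execute tens of millions of elementary steps in a
saturation run and this is the fastest pure-Python formulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .substrate import EMPTY, Occupancy, Substrate, sample_unoccupied

__all__ = [
    "PhysicalNode",
    "Bond",
    "PhysicalLayout",
    "CombinatorialNetwork",
    "GrowthConfig",
    "GrowthEvent",
    "default_fractal_dimension",
    "grow_lerw_trajectory",
    "grow_straight_trajectory",
    "seed_initial_node",
    "grow_network",
    "saturate_and_partition",
]

Process = Literal["lerw", "straight_random_dir", "straight_axis"]

_RNG_BATCH = 1 << 14


def default_fractal_dimension(process: str, d: int) -> float:
    """Fractal dimension of a free trajectory of the given growth process.

    Walk trajectories: 5/4 in d=2, 1.6236 in d=3, and 2 at and above the
    upper critical dimension d=4 (the d=4 logarithmic correction is not
    modeled).  Straight rays are one-dimensional in any d.
    """
    if process == "lerw":
        if d == 2:
            return 1.25
        if d == 3:
            return 1.6236
        return 2.0
    if process in ("straight_random_dir", "straight_axis"):
        return 1.0
    raise ValueError(f"unknown process {process!r}")


@dataclass
class PhysicalNode:
    """A grown trajectory: an ordered self-avoiding lattice path."""

    id: int
    trajectory: list[int]

    @property
    def volume(self) -> int:
        return len(self.trajectory)

    @property
    def internal_edges(self) -> list[tuple[int, int]]:
        t = self.trajectory
        return list(zip(t[:-1], t[1:]))

    def bbox_extent(self, substrate: Substrate) -> int:
        """Side length (in sites) of the minimal axis-aligned bounding box.

        Computed on periodically unwrapped coordinates so that trajectories
        crossing the boundary are not artificially truncated.
        """
        uw = unwrapped_coords(self.trajectory, substrate)
        return int(np.ptp(uw, axis=0).max()) + 1


def unwrapped_coords(trajectory, substrate: Substrate) -> np.ndarray:
    """Absolute (non-modular) coordinates along a lattice-neighbor path."""
    traj = np.asarray(trajectory, dtype=np.int64)
    L = substrate.L
    out = np.empty((len(traj), substrate.d), dtype=np.int64)
    for a, stride in enumerate(substrate.strides):
        c = (traj // stride) % L
        if len(c) > 1:
            dd = np.diff(c)
            dd[dd == L - 1] = -1
            dd[dd == -(L - 1)] = 1
            out[0, a] = c[0]
            out[1:, a] = c[0] + np.cumsum(dd)
        else:
            out[0, a] = c[0]
    return out


@dataclass(frozen=True)
class Bond:
    """A lattice edge joining sites of two distinct physical nodes."""

    site_a: int
    site_b: int
    node_i: int
    node_j: int


@dataclass
class GrowthEvent:
    t: int
    seed_site: int
    volume: int
    hit_node: int  # -1 when the node closed without forming a bond
    proposals: int  # raw trajectory length before loop erasures


@dataclass
class PhysicalLayout:
    substrate: Substrate
    nodes: list[PhysicalNode]
    bonds: list[Bond]
    occupancy: Occupancy
    volume_trajectory: list[int]
    saturated: bool = False
    events: list[GrowthEvent] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_volume(self) -> int:
        return self.volume_trajectory[-1] if self.volume_trajectory else 0

    def check_invariants(self) -> None:
        owner = self.occupancy.owner
        total = 0
        for node in self.nodes:
            total += node.volume
            for s in node.trajectory:
                if owner[s] != node.id:
                    raise AssertionError(f"site {s} not owned by node {node.id}")
        if total != self.occupancy.n_occupied:
            raise AssertionError("sum of node volumes != occupied site count")
        for b in self.bonds:
            if b.node_i == b.node_j:
                raise AssertionError("bond connects a node to itself")

    def write(self, outdir: str | Path) -> None:
        """Export nodes/bonds/edge-list TSVs plus a metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "nodes.tsv", "w") as f:
            f.write("id\tvolume\tbbox_extent\tbirth_t\n")
            for node in self.nodes:
                f.write(
                    f"{node.id}\t{node.volume}\t"
                    f"{node.bbox_extent(self.substrate)}\t{node.id}\n"
                )
        with open(outdir / "bonds.tsv", "w") as f:
            f.write("site_a\tsite_b\tnode_i\tnode_j\n")
            for b in self.bonds:
                f.write(f"{b.site_a}\t{b.site_b}\t{b.node_i}\t{b.node_j}\n")
        net = CombinatorialNetwork.from_layout(self)
        with open(outdir / "edges.tsv", "w") as f:
            f.write("node_i\tnode_j\tmultiplicity\n")
            for i, j, m in net.links:
                f.write(f"{i}\t{j}\t{m}\n")
        with open(outdir / "volume_trajectory.csv", "w") as f:
            f.write("t,V_t\n")
            for t, v in enumerate(self.volume_trajectory):
                f.write(f"{t},{v}\n")
        meta = {
            "d": self.substrate.d,
            "L": self.substrate.L,
            "n_nodes": self.n_nodes,
            "saturated": self.saturated,
            "total_volume": self.total_volume,
        }
        with open(outdir / "meta.json", "w") as f:
            json.dump(meta, f, indent=2)


@dataclass
class CombinatorialNetwork:
    """Coarse-grained weighted graph: one vertex per physical node."""

    N: int
    links: list[tuple[int, int, int]]  # (i, j, multiplicity), i < j
    degrees: np.ndarray
    volumes: np.ndarray

    @classmethod
    def from_layout(cls, layout: PhysicalLayout) -> "CombinatorialNetwork":
        N = layout.n_nodes
        mult: dict[tuple[int, int], int] = {}
        for b in layout.bonds:
            key = (min(b.node_i, b.node_j), max(b.node_i, b.node_j))
            mult[key] = mult.get(key, 0) + 1
        degrees = np.zeros(N, dtype=np.int64)
        links = []
        for (i, j), m in sorted(mult.items()):
            links.append((i, j, m))
            degrees[i] += m
            degrees[j] += m
        volumes = np.array([n.volume for n in layout.nodes], dtype=np.int64)
        return cls(N=N, links=links, degrees=degrees, volumes=volumes)

    def is_tree(self) -> bool:
        if sum(m for _, _, m in self.links) != self.N - 1:
            return False
        # union-find connectivity
        parent = list(range(self.N))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, _ in self.links:
            ri, rj = find(i), find(j)
            if ri == rj:
                return False
            parent[ri] = rj
        return True


@dataclass
class GrowthConfig:
    d: int
    L: int
    process: Process = "lerw"
    n_max: int | None = None  # None -> grow to saturation
    v0: int | str = "span"  # explicit volume or "span" -> round(L**d_f)
    d_f: float | None = None  # override of the process fractal dimension
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.n_max is not None and self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if self.process not in ("lerw", "straight_random_dir", "straight_axis"):
            raise ValueError(f"unknown process {self.process!r}")

    @property
    def fractal_dimension(self) -> float:
        if self.d_f is not None:
            return self.d_f
        return default_fractal_dimension(self.process, self.d)

    def v0_target(self) -> int:
        n_sites = self.L**self.d
        if self.v0 == "span":
            target = int(round(self.L**self.fractal_dimension))
        else:
            target = int(self.v0)
        if not 1 <= target <= n_sites:
            raise ValueError(f"v0 target {target} outside [1, {n_sites}]")
        return target


# ---------------------------------------------------------------------------
# walk kernels


def _walk_lerw(
    neigh: list[int],
    twod: int,
    owner: list[int],
    pos: list[int],
    start: int,
    rng: np.random.Generator,
    target_len: int | None = None,
    max_steps: int | None = None,
) -> tuple[list[int], int, int]:
    """Kinetic loop-erased walk from ``start``.

    Proposals to a site owned by another node stop the walk (a bond forms on
    that edge); proposals to the walk's own trajectory erase the loop back to
    that site; anything else extends the head.  Returns
    ``(path, hit_site_or_-1, n_proposals)``.  ``pos`` scratch entries are
    restored to -1 before returning.
    """
    path = [start]
    pos[start] = 0
    cur = start
    proposals = 0
    hit = -1
    batch: list[int] = []
    bi = 0
    while True:
        if target_len is not None and len(path) >= target_len:
            break
        if max_steps is not None and proposals >= max_steps:
            break
        if bi == len(batch):
            batch = rng.integers(0, twod, size=_RNG_BATCH).tolist()
            bi = 0
        nb = neigh[cur * twod + batch[bi]]
        bi += 1
        proposals += 1
        if owner[nb] != EMPTY:
            hit = nb
            break
        j = pos[nb]
        if j != -1:
            # loop erasure: drop everything after the revisited site
            for s in path[j + 1 :]:
                pos[s] = -1
            del path[j + 1 :]
            cur = nb
        else:
            pos[nb] = len(path)
            path.append(nb)
            cur = nb
    for s in path:
        pos[s] = -1
    return path, hit, proposals


def _walk_straight(
    substrate: Substrate,
    owner: list[int],
    pos: list[int],
    start: int,
    direction: np.ndarray,
    target_len: int | None = None,
) -> tuple[list[int], int, int]:
    """Digitized straight ray from ``start`` along unit vector ``direction``.

    The ray is rasterized as a staircase of single-axis steps (advance the
    dominant axis each iteration, carry fractional error on the others) so
    consecutive sites are always lattice neighbors.  Stops at the first
    contact with a foreign site (hit) or with its own trajectory (closure
    after periodic wrap; no bond).
    """
    L = substrate.L
    strides = substrate.strides
    a_star = int(np.argmax(np.abs(direction)))
    slopes = [
        abs(float(direction[a] / direction[a_star])) if a != a_star else 0.0
        for a in range(substrate.d)
    ]
    signs = [1 if direction[a] >= 0 else -1 for a in range(substrate.d)]
    err = [0.0] * substrate.d

    path = [start]
    pos[start] = 0
    cur = start
    proposals = 0
    hit = -1

    def step(site: int, axis: int) -> int:
        stride = strides[axis]
        coord = (site // stride) % L
        if signs[axis] > 0:
            return site + stride * (1 - L if coord == L - 1 else 1)
        return site + stride * (L - 1 if coord == 0 else -1)

    done = False
    while not done:
        if target_len is not None and len(path) >= target_len:
            break
        pending = [a_star]
        for a in range(substrate.d):
            if a == a_star:
                continue
            err[a] += slopes[a]
            if err[a] >= 1.0:
                err[a] -= 1.0
                pending.append(a)
        for axis in pending:
            nb = step(cur, axis)
            proposals += 1
            if owner[nb] != EMPTY:
                hit = nb
                done = True
                break
            if pos[nb] != -1:  # self-contact after wrap: close without bond
                done = True
                break
            pos[nb] = len(path)
            path.append(nb)
            cur = nb
            if target_len is not None and len(path) >= target_len:
                done = True
                break
    for s in path:
        pos[s] = -1
    return path, hit, proposals


# ---------------------------------------------------------------------------
# public per-trajectory operations


def _check_start(occupancy: Occupancy, start_site: int) -> None:
    if occupancy.owner[start_site] != EMPTY:
        raise ValueError(f"start site {start_site} is occupied")


def _random_direction(d: int, rng: np.random.Generator, axis_only: bool) -> np.ndarray:
    if axis_only:
        u = np.zeros(d)
        u[int(rng.integers(0, d))] = 1.0 if rng.integers(0, 2) else -1.0
        return u
    while True:
        u = rng.standard_normal(d)
        norm = np.linalg.norm(u)
        if norm > 1e-12:
            return u / norm


def grow_lerw_trajectory(
    substrate: Substrate,
    occupancy: Occupancy,
    start_site: int,
    rng: np.random.Generator,
    node_id: int | None = None,
    target_len: int | None = None,
    max_steps: int | None = None,
    _neigh: list[int] | None = None,
    _pos: list[int] | None = None,
) -> tuple[list[int], Bond | None]:
    """Grow one loop-erased-walk node; claim its sites; return (path, bond)."""
    _check_start(occupancy, start_site)
    neigh = _neigh if _neigh is not None else substrate.neighbor_table()
    pos = _pos if _pos is not None else [-1] * substrate.n_sites
    if node_id is None:
        node_id = (max(occupancy.owner) + 1) if occupancy.n_occupied else 0
    path, hit, _ = _walk_lerw(
        neigh, 2 * substrate.d, occupancy.owner, pos, start_site, rng,
        target_len=target_len, max_steps=max_steps,
    )
    occupancy.claim_many(path, node_id)
    bond = None
    if hit != -1:
        bond = Bond(path[-1], hit, node_id, occupancy.owner[hit])
    return path, bond


def grow_straight_trajectory(
    substrate: Substrate,
    occupancy: Occupancy,
    start_site: int,
    rng: np.random.Generator,
    mode: str = "random_dir",
    node_id: int | None = None,
    target_len: int | None = None,
    direction: np.ndarray | None = None,
    _pos: list[int] | None = None,
) -> tuple[list[int], Bond | None]:
    """Grow one straight-ray node; claim its sites; return (path, bond)."""
    if mode not in ("random_dir", "axis"):
        raise ValueError(f"unknown straight mode {mode!r}")
    _check_start(occupancy, start_site)
    pos = _pos if _pos is not None else [-1] * substrate.n_sites
    if direction is None:
        direction = _random_direction(substrate.d, rng, axis_only=(mode == "axis"))
    if node_id is None:
        node_id = (max(occupancy.owner) + 1) if occupancy.n_occupied else 0
    path, hit, _ = _walk_straight(
        substrate, occupancy.owner, pos, start_site, direction, target_len=target_len
    )
    occupancy.claim_many(path, node_id)
    bond = None
    if hit != -1:
        bond = Bond(path[-1], hit, node_id, occupancy.owner[hit])
    return path, bond


def seed_initial_node(
    config: GrowthConfig,
    substrate: Substrate,
    rng: np.random.Generator,
    occupancy: Occupancy | None = None,
    _neigh: list[int] | None = None,
    _pos: list[int] | None = None,
) -> PhysicalNode:
    """Free-grow node 0 to its target volume on an empty lattice."""
    if occupancy is None:
        occupancy = Occupancy(substrate)
    if occupancy.n_occupied:
        raise ValueError("seed_initial_node requires an empty occupancy")
    target = config.v0_target()
    start = sample_unoccupied(occupancy, substrate, rng)
    if config.process == "lerw":
        # proposal budget: a free walk needs ~ target**(d/d_f) raw steps to
        # reach post-erasure length `target`; allow a generous multiple.
        d_over_df = max(config.d / config.fractal_dimension, 1.0)
        cap = 10_000 + int(100 * target**d_over_df)
        path, _ = grow_lerw_trajectory(
            substrate, occupancy, start, rng, node_id=0,
            target_len=target, max_steps=cap, _neigh=_neigh, _pos=_pos,
        )
        if len(path) < target:
            raise RuntimeError(
                f"seed node reached length {len(path)} < target {target} "
                f"within {cap} proposals"
            )
    else:
        path, _ = grow_straight_trajectory(
            substrate, occupancy, start, rng,
            mode="axis" if config.process == "straight_axis" else "random_dir",
            node_id=0, target_len=target, _pos=_pos,
        )
        # a straight ray may close on itself (after wrapping) before the
        # target; the node then spans a full period, which we accept.
    return PhysicalNode(id=0, trajectory=path)


def grow_network(
    config: GrowthConfig,
) -> tuple[PhysicalLayout, CombinatorialNetwork, list[GrowthEvent]]:
    """Run the full growth process described in the module docstring."""
    substrate = Substrate(config.d, config.L)
    occupancy = Occupancy(substrate)
    rng = np.random.default_rng(config.seed)
    twod = 2 * substrate.d
    neigh = substrate.neighbor_table() if config.process == "lerw" else None
    pos = [-1] * substrate.n_sites

    node0 = seed_initial_node(
        config, substrate, rng, occupancy=occupancy, _neigh=neigh, _pos=pos
    )
    nodes = [node0]
    bonds: list[Bond] = []
    events = [GrowthEvent(0, node0.trajectory[0], node0.volume, -1, node0.volume)]
    V = [node0.volume]

    owner = occupancy.owner
    t = 0
    while not occupancy.is_full:
        t += 1
        if config.n_max is not None and t >= config.n_max:
            break
        start = sample_unoccupied(occupancy, substrate, rng)
        if config.process == "lerw":
            path, hit, proposals = _walk_lerw(neigh, twod, owner, pos, start, rng)
        else:
            direction = _random_direction(
                substrate.d, rng, axis_only=(config.process == "straight_axis")
            )
            path, hit, proposals = _walk_straight(
                substrate, owner, pos, start, direction
            )
        occupancy.claim_many(path, t)
        nodes.append(PhysicalNode(id=t, trajectory=path))
        hit_node = -1
        if hit != -1:
            hit_node = owner[hit]
            bonds.append(Bond(path[-1], hit, t, hit_node))
        V.append(V[-1] + len(path))
        events.append(GrowthEvent(t, start, len(path), hit_node, proposals))

    layout = PhysicalLayout(
        substrate=substrate,
        nodes=nodes,
        bonds=bonds,
        occupancy=occupancy,
        volume_trajectory=V,
        saturated=occupancy.is_full,
        events=events,
    )
    network = CombinatorialNetwork.from_layout(layout)
    return layout, network, events


def saturate_and_partition(config: GrowthConfig) -> np.ndarray:
    """Saturate the substrate; return the site -> node-id partition array."""
    if config.n_max is not None:
        raise ValueError("saturate_and_partition requires n_max=None")
    layout, _, _ = grow_network(config)
    part = layout.occupancy.owner_array()
    if (part == EMPTY).any():
        raise AssertionError("saturated layout left unassigned sites")
    return part
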