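"""Periodic cubic-lattice substrate: site indexing, adjacency and occupancy.

The substrate is a ``d``-dimensional cubic lattice with linear size ``L`` and
periodic boundary conditions.  Sites are indexed row-major (last coordinate
fastest), 0-based.  Occupancy tracks which site belongs to which physical
node; the growth loop relies on ``sample_unoccupied`` staying O(1) amortized
even close to saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Substrate",
    "Occupancy",
    "coords_to_site",
    "site_to_coords",
    "neighbors",
    "sample_unoccupied",
]

EMPTY = -1


@dataclass(frozen=True)
class Substrate:
    """A ``d``-dimensional periodic cubic lattice with ``L**d`` sites."""

    d: int
    L: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"dimension must be >= 1, got d={self.d}")
        if self.L < 2:
            raise ValueError(f"linear size must be >= 2, got L={self.L}")

    @property
    def n_sites(self) -> int:
        return self.L**self.d

    @property
    def strides(self) -> tuple[int, ...]:
        # row-major: stride of axis a is L**(d-1-a)
        return tuple(self.L ** (self.d - 1 - a) for a in range(self.d))

    def neighbor_table(self) -> list[int]:
        """Flat neighbor table: entry ``site * 2d + j`` is the j-th neighbor.

        Directions are ordered (axis 0 +, axis 0 -, axis 1 +, ...).  Returned
        as a plain Python list: the growth inner loop indexes it site by site
        and list access is measurably faster than ndarray scalar access.
        """
        L, d, n = self.L, self.d, self.n_sites
        sites = np.arange(n)
        cols = np.empty((n, 2 * d), dtype=np.int64)
        for a, stride in enumerate(self.strides):
            coord = (sites // stride) % L
            up = sites + stride * (np.where(coord == L - 1, 1 - L, 1))
            dn = sites + stride * (np.where(coord == 0, L - 1, -1))
            cols[:, 2 * a] = up
            cols[:, 2 * a + 1] = dn
        return cols.ravel().tolist()


def coords_to_site(coords, substrate: Substrate) -> int:
    """Row-major site index of integer coordinates in ``[0, L)**d``."""
    if len(coords) != substrate.d:
        raise ValueError(f"expected {substrate.d} coordinates, got {len(coords)}")
    site = 0
    for c in coords:
        if not 0 <= c < substrate.L:
            raise ValueError(f"coordinate {c} out of range [0, {substrate.L})")
        site = site * substrate.L + int(c)
    return site


def site_to_coords(site: int, substrate: Substrate) -> tuple[int, ...]:
    """Inverse of :func:`coords_to_site`."""
    if not 0 <= site < substrate.n_sites:
        raise ValueError(f"site {site} out of range [0, {substrate.n_sites})")
    coords = []
    for _ in range(substrate.d):
        coords.append(site % substrate.L)
        site //= substrate.L
    return tuple(reversed(coords))


def neighbors(site: int, substrate: Substrate) -> list[int]:
    """The (up to) ``2d`` periodic lattice neighbors of ``site``.

    For ``L == 2`` the +/- neighbors along an axis coincide; duplicates are
    collapsed, so the degree invariant is exactly ``2d`` only for ``L >= 3``.
    """
    if not 0 <= site < substrate.n_sites:
        raise ValueError(f"site {site} out of range [0, {substrate.n_sites})")
    L = substrate.L
    out: list[int] = []
    for a, stride in enumerate(substrate.strides):
        coord = (site // stride) % L
        up = site + stride * (1 - L if coord == L - 1 else 1)
        dn = site + stride * (L - 1 if coord == 0 else -1)
        out.append(up)
        if dn != up:
            out.append(dn)
    return out


@dataclass
class Occupancy:
    """Site ownership bookkeeping.

    ``owner`` is a dense per-site array with ``EMPTY`` (= -1) for free sites.
    A lazily rebuilt candidate list keeps uniform sampling of unoccupied
    sites cheap at high fill fractions.
    """

    substrate: Substrate
    owner: list[int] = field(init=False, repr=False)
    n_occupied: int = field(init=False, default=0)
    _candidates: np.ndarray | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        self.owner = [EMPTY] * self.substrate.n_sites

    @property
    def n_sites(self) -> int:
        return self.substrate.n_sites

    @property
    def is_full(self) -> bool:
        return self.n_occupied == self.n_sites

    def claim(self, site: int, node_id: int) -> None:
        if self.owner[site] != EMPTY:
            raise ValueError(f"site {site} already owned by node {self.owner[site]}")
        self.owner[site] = node_id
        self.n_occupied += 1

    def claim_many(self, sites, node_id: int) -> None:
        owner = self.owner
        for s in sites:
            if owner[s] != EMPTY:
                raise ValueError(f"site {s} already owned by node {owner[s]}")
            owner[s] = node_id
        self.n_occupied += len(sites)

    def release(self, site: int) -> None:
        if self.owner[site] == EMPTY:
            raise ValueError(f"site {site} is not occupied")
        self.owner[site] = EMPTY
        self.n_occupied -= 1

    def owner_array(self) -> np.ndarray:
        return np.asarray(self.owner, dtype=np.int64)

    def _rebuild_candidates(self) -> None:
        owner = np.asarray(self.owner, dtype=np.int64)
        self._candidates = np.flatnonzero(owner == EMPTY)


def sample_unoccupied(
    occupancy: Occupancy, substrate: Substrate, rng: np.random.Generator
) -> int | None:
    """A uniformly random unoccupied site, or ``None`` if the lattice is full.

    Strategy: batched rejection sampling over all sites below 50% fill; above
    that, rejection over a cached unoccupied-site list that is compacted
    whenever its hit rate drops below a half.  Total cost over a full
    saturation run is O(n log n).
    """
    if occupancy.substrate is not substrate and occupancy.substrate != substrate:
        raise ValueError("occupancy does not belong to this substrate")
    n = substrate.n_sites
    if occupancy.is_full:
        return None
    owner = occupancy.owner
    if occupancy.n_occupied * 2 < n:
        while True:
            for s in rng.integers(0, n, size=32).tolist():
                if owner[s] == EMPTY:
                    return s
    # dense regime: sample within the cached candidate list
    while True:
        cand = occupancy._candidates
        n_free = n - occupancy.n_occupied
        if cand is None or len(cand) > 2 * n_free:
            occupancy._rebuild_candidates()
            cand = occupancy._candidates
        m = len(cand)
        for i in rng.integers(0, m, size=32).tolist():
            s = int(cand[i])
            if owner[s] == EMPTY:
                return s
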