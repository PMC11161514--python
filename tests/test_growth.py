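import itertools

import numpy as np
import pytest

from physnet.growth import (
    Bond,
    CombinatorialNetwork,
    GrowthConfig,
    default_fractal_dimension,
    grow_lerw_trajectory,
    grow_network,
    grow_straight_trajectory,
    saturate_and_partition,
    seed_initial_node,
    unwrapped_coords,
)
from physnet.substrate import EMPTY, Occupancy, Substrate, coords_to_site


class TestLerwTrajectory:
    def test_forced_immediate_hit(self):
        # all four neighbors of the start owned by another node
        s = Substrate(2, 5)
        occ = Occupancy(s)
        start = coords_to_site((2, 2), s)
        for nb in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            occ.claim(coords_to_site(nb, s), 0)
        rng = np.random.default_rng(0)
        path, bond = grow_lerw_trajectory(s, occ, start, rng, node_id=1)
        assert path == [start]
        assert bond is not None
        assert bond.site_a == start
        assert bond.node_i == 1
        assert bond.node_j == 0

    def test_empty_lattice_no_hit_with_budget(self):
        s = Substrate(2, 8)
        occ = Occupancy(s)
        rng = np.random.default_rng(1)
        path, bond = grow_lerw_trajectory(s, occ, 0, rng, node_id=0, max_steps=200)
        assert bond is None
        assert len(path) >= 1

    def test_occupied_start_rejected(self):
        s = Substrate(2, 4)
        occ = Occupancy(s)
        occ.claim(5, 0)
        with pytest.raises(ValueError):
            grow_lerw_trajectory(s, occ, 5, np.random.default_rng(0), node_id=1)

    def test_trajectory_is_self_avoiding_neighbor_path(self):
        s = Substrate(2, 10)
        occ = Occupancy(s)
        occ.claim(0, 0)
        rng = np.random.default_rng(2)
        start = coords_to_site((5, 5), s)
        path, bond = grow_lerw_trajectory(s, occ, start, rng, node_id=1)
        assert len(set(path)) == len(path)
        from physnet.substrate import neighbors

        for a, b in zip(path[:-1], path[1:]):
            assert b in neighbors(a, s)
        assert bond is not None and bond.site_b == 0

    def test_d1_ring_absorption_time_oracle(self):
        """Mean trajectory steps on a ring with one absorbing site match a
        brute-force Markov-chain absorption-time computation."""
        L = 9
        s = Substrate(1, L)
        # exact expected absorption time of SRW on a ring from site k to
        # absorbing neighborhood of site 0, via linear solve
        # E[T from i] = 1 + (E[i-1] + E[i+1]) / 2, E[absorbed] = 0;
        # absorption happens when the walk *proposes* site 0, i.e. from
        # sites 1 and L-1 with prob 1/2 per step.
        A = np.zeros((L - 1, L - 1))
        b = np.ones(L - 1)
        for idx, site in enumerate(range(1, L)):
            A[idx, idx] = 1.0
            for nb, pr in [((site - 1) % L, 0.5), ((site + 1) % L, 0.5)]:
                if nb == 0:
                    continue  # absorbed: contributes 0
                A[idx, list(range(1, L)).index(nb)] -= pr
        expected_T = np.linalg.solve(A, b)
        start = 4
        n_runs = 4000
        rng = np.random.default_rng(3)
        steps = []
        for _ in range(n_runs):
            occ = Occupancy(s)
            occ.claim(0, 0)
            pos = [-1] * s.n_sites
            from physnet.growth import _walk_lerw

            path, hit, proposals = _walk_lerw(
                s.neighbor_table(), 2, occ.owner, pos, start, rng
            )
            assert hit == 0
            steps.append(proposals)
        mean_T = np.mean(steps)
        target = expected_T[start - 1]
        assert abs(mean_T - target) < 4 * np.std(steps) / np.sqrt(n_runs)

    def test_loop_erasure_releases_sites(self):
        # erased sites must not be claimed in occupancy at the end
        s = Substrate(2, 12)
        occ = Occupancy(s)
        occ.claim(0, 0)
        rng = np.random.default_rng(4)
        start = coords_to_site((6, 6), s)
        path, _ = grow_lerw_trajectory(s, occ, start, rng, node_id=1)
        assert occ.n_occupied == len(path) + 1


class TestStraightTrajectory:
    def test_axis_mode_wraps_and_closes(self):
        s = Substrate(2, 8)
        occ = Occupancy(s)
        rng = np.random.default_rng(0)
        path, bond = grow_straight_trajectory(s, occ, 0, rng, mode="axis", node_id=0)
        assert bond is None
        assert len(path) == 8  # a lattice line on the torus has period L

    def test_parallel_axis_lines_never_bond(self):
        s = Substrate(2, 8)
        occ = Occupancy(s)
        rng = np.random.default_rng(0)
        d0 = np.array([0.0, 1.0])
        p0, b0 = grow_straight_trajectory(
            s, occ, coords_to_site((1, 0), s), rng, mode="axis",
            node_id=0, direction=d0,
        )
        p1, b1 = grow_straight_trajectory(
            s, occ, coords_to_site((3, 0), s), rng, mode="axis",
            node_id=1, direction=d0,
        )
        assert b0 is None and b1 is None
        rows0 = {c[0] for c in (divmod(site, 8) for site in p0)}
        rows1 = {c[0] for c in (divmod(site, 8) for site in p1)}
        assert rows0 == {1} and rows1 == {3}

    def test_diagonal_rasterization_oracle(self):
        """Direction (1,1)/sqrt(2): the staircase must alternate axis steps,
        visiting exactly the sites of the brute-force rasterization."""
        L = 8
        s = Substrate(2, L)
        occ = Occupancy(s)
        rng = np.random.default_rng(0)
        u = np.array([1.0, 1.0]) / np.sqrt(2)
        path, bond = grow_straight_trajectory(
            s, occ, 0, rng, node_id=0, direction=u, target_len=9
        )
        # oracle: starting at (0,0), emit dominant-axis (axis 0) step, then
        # carry err=1 on axis 1 -> one axis-1 step each iteration
        expect = [(0, 0)]
        x = [0, 0]
        for _ in range(4):
            x[0] += 1
            expect.append(tuple(x))
            x[1] += 1
            expect.append(tuple(x))
        expected_sites = [coords_to_site((a % L, b % L), s) for a, b in expect]
        assert path == expected_sites[: len(path)]

    def test_hit_forms_bond(self):
        s = Substrate(2, 8)
        occ = Occupancy(s)
        # occupy a full column at x-coordinate 4 as node 0
        for y in range(8):
            occ.claim(coords_to_site((4, y), s), 0)
        rng = np.random.default_rng(0)
        u = np.array([1.0, 0.0])
        path, bond = grow_straight_trajectory(
            s, occ, coords_to_site((0, 3), s), rng, node_id=1, direction=u
        )
        assert bond is not None
        assert bond.node_j == 0
        assert bond.site_b == coords_to_site((4, 3), s)
        assert len(path) == 4  # (0,3),(1,3),(2,3),(3,3)


class TestSeedNode:
    def test_explicit_v0_single_site(self):
        cfg = GrowthConfig(d=2, L=8, v0=1, seed=0)
        s = Substrate(2, 8)
        node = seed_initial_node(cfg, s, np.random.default_rng(0))
        assert node.volume == 1

    def test_span_policy_d2(self):
        # round(100**1.25) = 316 with the d=2 walk fractal dimension 5/4
        cfg = GrowthConfig(d=2, L=100, v0="span", process="lerw", seed=0)
        assert cfg.v0_target() == 316
        s = Substrate(2, 100)
        node = seed_initial_node(cfg, s, np.random.default_rng(0))
        assert node.volume == 316

    def test_span_policy_d4(self):
        # at and above the upper critical dimension d_f = 2: v0 = L**2
        cfg = GrowthConfig(d=4, L=7, v0="span", process="lerw", seed=0)
        assert cfg.v0_target() == 49

    def test_v0_exceeding_lattice_rejected(self):
        cfg = GrowthConfig(d=2, L=4, v0=17, seed=0)
        s = Substrate(2, 4)
        with pytest.raises(ValueError):
            seed_initial_node(cfg, s, np.random.default_rng(0))

    def test_fractal_dimension_lookup(self):
        assert default_fractal_dimension("lerw", 2) == 1.25
        assert default_fractal_dimension("lerw", 3) == pytest.approx(1.6236)
        assert default_fractal_dimension("lerw", 4) == 2.0
        assert default_fractal_dimension("lerw", 5) == 2.0
        assert default_fractal_dimension("straight_axis", 3) == 1.0
        assert default_fractal_dimension("straight_random_dir", 2) == 1.0


class TestGrowNetwork:
    def test_n_max_1_only_seed(self):
        cfg = GrowthConfig(d=2, L=16, n_max=1, seed=0)
        layout, net, events = grow_network(cfg)
        assert layout.n_nodes == 1
        assert net.N == 1
        assert len(net.links) == 0

    def test_saturation_is_spanning_tree(self, saturated_small):
        layout, net, _ = saturated_small
        L = layout.substrate.L
        assert layout.saturated
        edges = set()
        for node in layout.nodes:
            for a, b in node.internal_edges:
                edges.add((min(a, b), max(a, b)))
        for bond in layout.bonds:
            edges.add((min(bond.site_a, bond.site_b), max(bond.site_a, bond.site_b)))
        assert len(edges) == L * L - 1
        # connectivity via union-find over lattice sites
        parent = list(range(L * L))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        assert len({find(x) for x in range(L * L)}) == 1

    def test_layout_invariants(self, saturated_small):
        layout, net, _ = saturated_small
        layout.check_invariants()
        V = layout.volume_trajectory
        assert all(b > a for a, b in zip(V[:-1], V[1:]))
        assert V[-1] == layout.occupancy.n_occupied
        assert len(layout.bonds) == layout.n_nodes - 1

    def test_combinatorial_tree(self, saturated_small):
        _, net, _ = saturated_small
        assert net.is_tree()
        assert all(m == 1 for _, _, m in net.links)
        assert net.degrees.sum() == 2 * len(net.links)

    def test_determinism(self):
        cfg = GrowthConfig(d=2, L=16, seed=42)
        l1, n1, e1 = grow_network(cfg)
        l2, n2, e2 = grow_network(cfg)
        assert [n.trajectory for n in l1.nodes] == [n.trajectory for n in l2.nodes]
        assert l1.bonds == l2.bonds
        assert n1.links == n2.links

    def test_saturation_density_concentrates(self):
        densities = []
        for L in (24, 48):
            vals = []
            for seed in range(3):
                cfg = GrowthConfig(d=2, L=L, seed=seed)
                layout, _, _ = grow_network(cfg)
                vals.append(layout.n_nodes / L**2)
            densities.append(np.mean(vals))
        assert abs(densities[0] - densities[1]) / densities[1] < 0.2

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            GrowthConfig(d=0, L=10)
        with pytest.raises(ValueError):
            GrowthConfig(d=2, L=10, n_max=0)
        with pytest.raises(ValueError):
            GrowthConfig(d=2, L=10, process="bogus")


class TestPartition:
    def test_partition_covers_lattice(self):
        cfg = GrowthConfig(d=2, L=12, seed=5)
        part = saturate_and_partition(cfg)
        assert part.size == 144
        assert (part >= 0).all()

    def test_partition_cells_are_paths(self):
        cfg = GrowthConfig(d=2, L=12, seed=5)
        layout, _, _ = grow_network(cfg)
        part = layout.occupancy.owner_array()
        sizes = np.bincount(part)
        assert sizes.sum() == 144
        # each cell is the node's trajectory: connected by construction
        for node in layout.nodes:
            assert sizes[node.id] == node.volume

    def test_mean_cell_volume_bounded(self):
        means = []
        for L in (24, 48):
            cfg = GrowthConfig(d=2, L=L, seed=9)
            layout, _, _ = grow_network(cfg)
            means.append(L**2 / layout.n_nodes)
        assert abs(means[0] - means[1]) / means[1] < 0.25

    def test_requires_saturation_config(self):
        with pytest.raises(ValueError):
            saturate_and_partition(GrowthConfig(d=2, L=8, n_max=5))


class TestUnwrappedCoords:
    def test_straight_path_across_boundary(self):
        s = Substrate(2, 5)
        # path walking +y across the wrap: (0,3),(0,4),(0,0),(0,1)
        path = [coords_to_site((0, y), s) for y in (3, 4)] + [
            coords_to_site((0, y), s) for y in (0, 1)
        ]
        uw = unwrapped_coords(path, s)
        assert uw[:, 1].tolist() == [3, 4, 5, 6]
        assert np.ptp(uw[:, 0]) == 0


class TestUstUniformity:
    def test_saturated_tree_distribution_on_3x3_torus(self):
        """Saturated growth with a single-site seed draws spanning trees of
        the 3x3 torus uniformly (chi-square against the matrix-tree count)."""
        L = 3
        s = Substrate(2, L)
        # total spanning trees via Kirchhoff determinant on the 3x3 torus
        import networkx as nx

        G = nx.Graph()
        for site in range(9):
            from physnet.substrate import neighbors

            for nb in neighbors(site, s):
                G.add_edge(site, nb)
        Q = nx.laplacian_matrix(G).toarray()
        n_trees = round(float(np.linalg.det(Q[1:, 1:])))
        assert n_trees > 0

        from collections import Counter

        n_runs = 30_000
        counts: Counter = Counter()
        for seed in range(n_runs):
            cfg = GrowthConfig(d=2, L=L, v0=1, seed=seed)
            layout, _, _ = grow_network(cfg)
            edges = []
            for node in layout.nodes:
                for a, b in node.internal_edges:
                    edges.append((min(a, b), max(a, b)))
            for bond in layout.bonds:
                edges.append(
                    (min(bond.site_a, bond.site_b), max(bond.site_a, bond.site_b))
                )
            counts[frozenset(edges)] += 1
        assert len(counts) <= n_trees
        expected = n_runs / n_trees
        chi2 = sum((o - expected) ** 2 / expected for o in counts.values())
        chi2 += (n_trees - len(counts)) * expected
        # with ~2.6 expected counts per cell the chi-square distribution is
        # approximated normally with the exact Poisson per-cell variance
        mean = n_trees - 1
        sd = np.sqrt(n_trees * (2 + 1 / expected))
        assert chi2 < mean + 4 * sd
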