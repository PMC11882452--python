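"""Bond graphs, face enumeration, network density and border ratio."""

import math

import networkx as nx
import numpy as np
import pytest

from patchnet import (ISLAND_THRESHOLD, analyze_frame, border_ratio,
                      build_bond_graph, compact_reference_edges,
                      enumerate_faces, islands_of, make_compact_island,
                      network_density)
from patchnet.morphology import Island

LATTICE = 16.0


def island_from_points(pts, cutoff=None):
    g = build_bond_graph(np.asarray(pts), cutoff=cutoff)
    isls = islands_of(g)
    return max(isls, key=lambda i: i.size)


def hexagon_points(centre=(0.0, 0.0), radius=1.0):
    return [(centre[0] + radius * math.cos(k * math.pi / 3 + math.pi / 6),
             centre[1] + radius * math.sin(k * math.pi / 3 + math.pi / 6))
            for k in range(6)]


class TestBondGraph:
    def test_six_ring_from_points(self):
        g = build_bond_graph(np.array(hexagon_points()), cutoff=1.25)
        assert g.number_of_nodes() == 6 and g.number_of_edges() == 6

    def test_gas_has_no_edges(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10.0]])
        g = build_bond_graph(pts, cutoff=1.25)
        assert g.number_of_edges() == 0

    def test_empty_input_gives_empty_graph(self):
        g = build_bond_graph(np.empty((0, 2)))
        assert g.number_of_nodes() == 0

    def test_degree_four_artefact_pruned_by_longest_edge(self):
        # a spurious point close to a honeycomb vertex makes it degree 4;
        # the longest incident edge must go
        flower = make_compact_island(n_rings=2, seed=0)
        pts = list(flower.points)
        victim = 0
        spur = flower.points[victim] + np.array([0.0, 1.19 * LATTICE])
        pts.append(spur)
        g = build_bond_graph(np.array(pts), cutoff=1.25 * LATTICE)
        assert max(dict(g.degree).values()) <= 3


class TestFaceEnumeration:
    def test_triangle(self):
        pts = [(0, 0), (1, 0), (0.5, math.sqrt(3) / 2)]
        isl = island_from_points(pts, cutoff=1.2)
        ps = enumerate_faces(isl)
        assert ps.sizes == [3]

    def test_open_chain_has_no_polygons(self):
        pts = [(i * 1.0, 0.2 * (i % 2)) for i in range(10)]
        isl = island_from_points(pts, cutoff=1.3)
        ps = enumerate_faces(isl)
        assert ps.sizes == [] and ps.voids == 0

    def test_flower_has_seven_hexagons(self, flower):
        isl = island_from_points(flower.points)
        ps = enumerate_faces(isl)
        assert sorted(ps.sizes) == [6] * 7
        assert len(set(ps.outer_boundary)) == 18  # all but the central hexagon

    def test_faces_match_cycle_basis_oracle_on_random_islands(self):
        # islands built from random connected unions of hexagonal cells;
        # every interior face is a chordless cycle, so the minimum cycle
        # basis enumerates exactly the bounded faces
        rng = np.random.default_rng(42)
        a1 = np.array([math.sqrt(3), 0.0])
        a2 = np.array([math.sqrt(3) / 2, 1.5])
        for trial in range(50):
            k = int(rng.integers(1, 6))
            cells = {(0, 0)}
            while len(cells) < k:
                i, j = list(cells)[int(rng.integers(len(cells)))]
                di, dj = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)][
                    int(rng.integers(6))]
                cells.add((i + di, j + dj))
            pts = {}
            edges = set()
            for (i, j) in cells:
                c = i * a1 + j * a2
                corner_ids = []
                for t in range(6):
                    p = c + np.array([math.cos(t * math.pi / 3 + math.pi / 6),
                                      math.sin(t * math.pi / 3 + math.pi / 6)])
                    key = (round(p[0], 6), round(p[1], 6))
                    if key not in pts:
                        pts[key] = len(pts)
                    corner_ids.append(pts[key])
                for t in range(6):
                    edges.add(tuple(sorted((corner_ids[t],
                                            corner_ids[(t + 1) % 6]))))
            coords = {v: kxy for kxy, v in pts.items()}
            isl = Island(nodes=sorted(coords), edges=sorted(edges),
                         coords=coords, embed_edges=sorted(edges))
            ps = enumerate_faces(isl)
            got = sorted([len(f) for f in ps.faces]
                         + [len(set(w)) for w in ps.void_faces])
            G = nx.Graph(list(edges))
            oracle = sorted(len(c) for c in nx.minimum_cycle_basis(G))
            assert got == oracle, f"trial {trial}"

    def test_euler_formula_on_random_islands(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(30, 90))
            fld = make_compact_island(n_particles=n,
                                      defect_rates=(0.1, 0.1),
                                      seed=int(rng.integers(2**31)))
            for isl in islands_of(build_bond_graph(fld.points)):
                if isl.size < 3:
                    continue
                ps = enumerate_faces(isl)
                # V - E + F = 2 counting the outer face
                assert isl.size - isl.n_edges + ps.n_traversal_faces + \
                    (1 if ps.n_traversal_faces else 2) - 1 == 2

    def test_crossing_edges_beyond_budget_raise(self):
        # an X of two crossing bonds amid a tiny island
        pts = [(0, 0), (1, 1), (1, 0), (0, 1)]
        isl = Island(nodes=[0, 1, 2, 3], edges=[(0, 1), (2, 3)],
                     coords={i: p for i, p in enumerate(pts)},
                     embed_edges=[(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="crossing"):
            enumerate_faces(isl, max_cross_fraction=0.0)


class TestNetworkDensity:
    def test_ideal_compact_island_is_one(self, flower):
        isl = island_from_points(flower.points)
        assert network_density(isl) == 1.0

    def test_six_ring_is_one(self):
        isl = island_from_points(hexagon_points(), cutoff=1.25)
        assert network_density(isl) == 1.0

    def test_chain_value(self):
        pts = [(i * 1.0, 0.0) for i in range(24)]
        isl = island_from_points(pts, cutoff=1.2)
        assert network_density(isl) == pytest.approx(
            23 / compact_reference_edges(24))
        assert network_density(isl) < 1.0

    def test_invariance_under_rigid_motion_and_relabelling(self, flower):
        pts = np.array(flower.points)
        base = network_density(island_from_points(pts))
        th = 0.7
        rot = pts @ np.array([[math.cos(th), math.sin(th)],
                              [-math.sin(th), math.cos(th)]]) + [123.0, -45.0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(rot))
        assert network_density(island_from_points(rot[perm])) == base

    def test_empty_island_rejected(self):
        with pytest.raises(ValueError):
            network_density(Island(nodes=[], edges=[], coords={}))


class TestFaceDensity:
    def test_ideal_crystal_is_one(self, flower):
        from patchnet import face_density

        assert face_density(island_from_points(flower.points)) == 1.0

    def test_chain_is_zero(self):
        from patchnet import face_density

        pts = [(i * 1.0, 0.0) for i in range(24)]
        assert face_density(island_from_points(pts, cutoff=1.2)) == 0.0

    def test_between_zero_and_one_on_defective_islands(self):
        from patchnet import face_density
        from patchnet import make_compact_island

        fld = make_compact_island(n_particles=80, defect_rates=(0.1, 0.1),
                                  seed=2)
        v = face_density(island_from_points(fld.points))
        assert 0.0 < v <= 1.0


class TestBorderRatio:
    def test_no_polygons_is_zero(self):
        pts = [(i * 1.0, 0.0) for i in range(8)]
        isl = island_from_points(pts, cutoff=1.2)
        assert border_ratio(isl) == 0.0

    def test_single_hexagon_is_one(self):
        isl = island_from_points(hexagon_points(), cutoff=1.25)
        assert border_ratio(isl) == 1.0

    def test_flower_six_sevenths(self, flower):
        isl = island_from_points(flower.points)
        assert border_ratio(isl) == pytest.approx(6 / 7)

    def test_adding_a_hexagon_ring_strictly_decreases_border_ratio(self):
        two = make_compact_island(n_rings=2, seed=0)
        three = make_compact_island(n_rings=3, seed=0)
        b2 = border_ratio(island_from_points(two.points))
        b3 = border_ratio(island_from_points(three.points))
        assert 0.0 < b3 < b2 <= 1.0


class TestFrameReport:
    def test_weighted_nd_single_island(self):
        fld = make_compact_island(n_rings=3, seed=0)  # 54 >= threshold
        rep = analyze_frame(fld.points)
        assert rep.weighted_nd == 1.0
        assert len(rep.eligible) == 1

    def test_small_islands_excluded_from_summary(self, flower):
        # only 23 of the 24 particles -> below the eligibility threshold
        rep = analyze_frame(flower.points[:23])
        assert rep.islands and not rep.eligible
        assert math.isnan(rep.weighted_nd)
        assert rep.island_density == 0.0

    def test_gas_frame_all_counts_zero(self):
        pts = np.array([[0, 0], [40, 0], [0, 40.0]])
        rep = analyze_frame(pts)
        assert sum(rep.polygon_counts().values()) == 0
        assert rep.hexagon_fraction == 0.0

    def test_hexagon_fraction_ideal(self, flower):
        rep = analyze_frame(flower.points)
        assert rep.hexagon_fraction == 1.0
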