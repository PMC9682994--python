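"""Rips filtration construction and persistence pairing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cagetda.distance import bottleneck_distance
from cagetda.reference import rips_diagram_bruteforce
from cagetda.rips import (
    betti_at,
    build_rips_filtration,
    compute_persistence_diagram,
    rips_diagram,
)
from cagetda.structure import PointCloud


def canon(d):
    return sorted(
        zip(d.dims.tolist(), np.round(d.births, 10).tolist(),
            np.round(d.deaths, 10).tolist(), d.essential.tolist())
    )


class TestFiltration:
    def test_right_triangle_simplex_census(self):
        cloud = PointCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float))
        f = build_rips_filtration(cloud, 1.5)
        assert f.n_simplices(0) == 3
        assert f.n_simplices(1) == 3
        assert f.n_simplices(2) == 1
        assert f.n_simplices() == 7
        assert sorted(np.round(f.values[1], 10)) == [1.0, 1.0, round(2**0.5, 10)]
        assert np.isclose(f.values[2][0], 2**0.5)

    def test_small_scale_keeps_vertices_only(self):
        cloud = PointCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float))
        f = build_rips_filtration(cloud, 0.5)
        assert f.n_simplices() == 3

    def test_single_point(self):
        f = build_rips_filtration(PointCloud(np.zeros((1, 3))), 1.0)
        assert f.n_simplices() == 1
        assert f.values[0][0] == 0.0

    def test_rips_property_value_is_diameter(self):
        rng = np.random.default_rng(3)
        pts = rng.random((7, 3))
        f = build_rips_filtration(PointCloud(pts), 1.2)
        for dim in (1, 2, 3):
            if dim not in f.simplices:
                continue
            for verts, val in zip(f.simplices[dim], f.values[dim]):
                diam = max(
                    np.linalg.norm(pts[a] - pts[b])
                    for i, a in enumerate(verts) for b in verts[i + 1:]
                )
                assert np.isclose(val, diam)

    def test_faces_enter_no_later_than_cofaces(self):
        rng = np.random.default_rng(4)
        f = build_rips_filtration(PointCloud(rng.random((8, 3))), 1.0)
        for dim in (2, 3):
            if dim not in f.simplices:
                continue
            lower = {tuple(s): v for s, v in zip(f.simplices[dim - 1], f.values[dim - 1])}
            for verts, val in zip(f.simplices[dim], f.values[dim]):
                verts = tuple(verts)
                for drop in range(len(verts)):
                    assert lower[verts[:drop] + verts[drop + 1:]] <= val + 1e-12


class TestDiagram:
    def test_two_points_b0(self):
        d = rips_diagram(PointCloud(np.array([[0, 0, 0], [1, 0, 0]], float)), 2.0)
        assert canon(d) == [(0, 0.0, 1.0, False), (0, 0.0, 2.0, True)]

    def test_unit_square_b1(self, square_cloud):
        d = rips_diagram(square_cloud, 2.0)
        b1 = d.in_dim(1)
        assert b1.shape == (1, 2)
        assert abs(b1[0, 0] - 1.0) < 1e-9
        assert abs(b1[0, 1] - 2**0.5) < 1e-9

    def test_octahedron_b2(self, octahedron_cloud):
        d = rips_diagram(octahedron_cloud, 2.5)
        b2 = d.in_dim(2)
        assert b2.shape == (1, 2)
        assert abs(b2[0, 0] - 2**0.5) < 1e-9
        assert abs(b2[0, 1] - 2.0) < 1e-9

    def test_hexagon_b1(self):
        theta = np.linspace(0, 2 * np.pi, 7)[:-1]
        d = rips_diagram(PointCloud(np.c_[np.cos(theta), np.sin(theta), np.zeros(6)]), 2.0)
        b1 = d.in_dim(1)
        assert b1.shape == (1, 2)
        assert abs(b1[0, 0] - 1.0) < 1e-9
        assert abs(b1[0, 1] - 3**0.5) < 1e-9

    def test_unsupported_dimension_rejected(self, square_cloud):
        f = build_rips_filtration(square_cloud, 2.0)
        with pytest.raises(ValueError, match="dimensions above 2"):
            compute_persistence_diagram(f, max_dim=3)

    def test_one_essential_b0_per_component(self):
        pts = np.vstack([np.zeros((3, 3)) + np.arange(3)[:, None] * 0.1,
                         np.zeros((2, 3)) + 50 + np.arange(2)[:, None] * 0.1])
        d = rips_diagram(PointCloud(pts), 1.0)
        ess = d.essential & (d.dims == 0)
        assert int(ess.sum()) == 2
        assert np.all(d.deaths[ess] == 1.0)

    def test_births_deaths_within_range(self):
        rng = np.random.default_rng(9)
        d = rips_diagram(PointCloud(rng.random((10, 3))), 0.9)
        assert np.all(d.births >= 0) and np.all(d.deaths <= 0.9)
        assert np.all(d.deaths > d.births)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_reduction(self, seed):
        """Dual route: cohomology-with-clearing vs global boundary-matrix reduction."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pts = rng.random((n, 3))
        L = float(rng.uniform(0.3, 1.6))
        assert canon(rips_diagram(PointCloud(pts), L)) == canon(
            rips_diagram_bruteforce(pts, L)
        )

    def test_stability_under_perturbation(self):
        """Moving every point by <= eps moves the diagram by <= 2*eps (bottleneck)."""
        eps = 0.01
        rng = np.random.default_rng(21)
        for cloud_pts in (
            np.c_[np.cos(t := np.linspace(0, 2 * np.pi, 13)[:-1]), np.sin(t), 0 * t] * 0.3 + 0.5,
            rng.random((12, 3)) * 0.5,
        ):
            shift = rng.uniform(-1, 1, cloud_pts.shape)
            shift *= eps / np.linalg.norm(shift, axis=1, keepdims=True).max()
            d1 = rips_diagram(PointCloud(cloud_pts), 0.8)
            d2 = rips_diagram(PointCloud(cloud_pts + shift), 0.8)
            for dim in (0, 1, 2):
                assert bottleneck_distance(d1, d2, dim) <= 2 * eps + 1e-12

    def test_serialization_roundtrip(self, square_cloud, tmp_path):
        from cagetda.rips import PersistenceDiagram

        d = rips_diagram(square_cloud, 2.0)
        path = tmp_path / "diag.json"
        d.to_json(path)
        d2 = PersistenceDiagram.from_json(path)
        assert canon(d) == canon(d2)
        assert d2.max_edge_length == d.max_edge_length


class TestBettiAt:
    def test_square_before_edges(self, square_cloud):
        f = build_rips_filtration(square_cloud, 2.0)
        assert betti_at(f, 0.5) == (4, 0, 0)

    def test_square_with_loop(self, square_cloud):
        f = build_rips_filtration(square_cloud, 2.0)
        assert betti_at(f, 1.2) == (1, 1, 0)

    def test_out_of_range_rejected(self, square_cloud):
        f = build_rips_filtration(square_cloud, 2.0)
        with pytest.raises(ValueError):
            betti_at(f, 2.5)

    @given(st.integers(0, 2**31 - 1))
    def test_consistent_with_alive_diagram_features(self, seed):
        """Rank-based Betti numbers equal counts of diagram features alive at t."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pts = rng.random((n, 3))
        L = 1.2
        f = build_rips_filtration(PointCloud(pts), L)
        d = compute_persistence_diagram(f)
        t = float(rng.uniform(0, L))
        alive = [0, 0, 0]
        for dim, b, death, ess in zip(d.dims, d.births, d.deaths, d.essential):
            if b <= t and (ess or death > t):
                alive[dim] += 1
        # zero-persistence pairs are dropped from the diagram but never alter counts
        assert betti_at(f, t) == tuple(alive)
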