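import numpy as np
import pytest

import oracles
from conftest import grid_mesh_faces
from phytopoint.core import PointCloud, RigidTransform, TriangleMesh
from phytopoint.errors import DegenerateGeometryError
from phytopoint.surface import (
    GeodesicField,
    GeodesicSolver,
    convex_hull,
    farthest_point,
    geodesic_distances,
    graph_geodesic_distances,
    mesh_area,
    mesh_surface,
    projected_area,
)


class TestGeodesics:
    def test_flat_grid_equals_euclidean(self, planar_grid):
        fld = geodesic_distances(planar_grid, source=0)
        euclid = np.linalg.norm(planar_grid.points - planar_grid.points[0], axis=1)
        rel = np.abs(fld.distances[1:] - euclid[1:]) / euclid[1:]
        assert rel.max() < 0.005

    def test_cylinder_half_circumference(self, cylinder_cloud):
        cloud, r = cylinder_cloud
        src = int(np.argmin(np.linalg.norm(cloud.points - [r, 0, 30], axis=1)))
        tgt = int(np.argmin(np.linalg.norm(cloud.points - [-r, 0, 30], axis=1)))
        fld = geodesic_distances(cloud, src)
        assert fld.distances[tgt] == pytest.approx(np.pi * r, rel=0.02)

    def test_geodesic_never_below_euclidean(self, rng):
        pts = rng.uniform(0, 60, (900, 2))
        cloud = PointCloud(np.column_stack([pts, 0.02 * pts[:, 0]]))
        fld = geodesic_distances(cloud, 17)
        euclid = np.linalg.norm(cloud.points - cloud.points[17], axis=1)
        finite = np.isfinite(fld.distances)
        assert np.all(fld.distances[finite] >= euclid[finite] - 1e-9)

    def test_upper_bounded_by_graph_dijkstra(self, rng):
        """The k-NN-graph distance is a chordal upper bound; the surface
        solver must never exceed it."""
        pts = rng.uniform(0, 50, (800, 2))
        cloud = PointCloud(np.column_stack([pts, np.zeros(800)]))
        ours = geodesic_distances(cloud, 3).distances
        graph = graph_geodesic_distances(cloud.points, 3)
        finite = np.isfinite(graph)
        assert np.all(ours[finite] <= graph[finite] * (1 + 1e-9))
        # and stays within the graph's metric-distortion envelope
        far = finite & (graph > 10.0)
        assert np.quantile(graph[far] - ours[far], 0.95) / 50.0 < 0.09

    def test_straight_line_farthest_point(self):
        line = np.column_stack([np.linspace(0, 100, 101),
                                np.zeros(101), np.zeros(101)])
        fld = geodesic_distances(PointCloud(line), 0)
        idx, dist = farthest_point(fld)
        assert idx == 100
        assert dist == pytest.approx(100.0, rel=1e-6)

    def test_l_shaped_polyline_path_length(self):
        arm_a = np.column_stack([np.linspace(0, 60, 61), np.zeros(61), np.zeros(61)])
        arm_b = np.column_stack([np.zeros(80), np.linspace(1, 80, 80), np.zeros(80)])
        cloud = PointCloud(np.vstack([arm_a, arm_b]))
        fld = geodesic_distances(cloud, 60)   # far end of the 60-mm arm
        idx, dist = farthest_point(fld)
        assert idx == 140                      # far end of the 80-mm arm
        assert dist == pytest.approx(140.0, rel=0.02)

    def test_farthest_tie_broken_by_lowest_index(self):
        fld = GeodesicField(0, np.array([0.0, 5.0, 5.0, 2.0]))
        idx, dist = farthest_point(fld)
        assert (idx, dist) == (1, 5.0)

    def test_all_infinite_field_raises(self):
        with pytest.raises(DegenerateGeometryError):
            farthest_point(GeodesicField(0, np.full(4, np.inf)))

    def test_disconnected_component_gets_infinity(self):
        x, y = np.meshgrid(np.arange(10.0), np.arange(10.0))
        patch = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
        far = patch + [500.0, 0.0, 0.0]
        cloud = PointCloud(np.vstack([patch, far]))
        fld = geodesic_distances(cloud, 0)
        assert np.isinf(fld.distances[len(patch):]).all()
        assert np.isfinite(fld.distances[:len(patch)]).all()

    def test_mesh_input_used_directly(self, planar_grid):
        mesh = TriangleMesh(planar_grid.points, grid_mesh_faces(51, 51))
        fld = geodesic_distances(mesh, 0)
        corner = 51 * 51 - 1
        assert fld.distances[corner] == pytest.approx(50 * np.sqrt(2), rel=0.005)


class TestConvexHull:
    def test_unit_cube(self, unit_cube_cloud):
        h = convex_hull(unit_cube_cloud)
        assert h.volume_mm3 == pytest.approx(1.0, abs=1e-12)
        assert h.area_mm2 == pytest.approx(6.0, abs=1e-12)
        assert not h.degenerate

    def test_regular_tetrahedron_closed_form(self):
        a = 10.0
        pts = np.array([[0, 0, 0], [a, 0, 0],
                        [a / 2, a * np.sqrt(3) / 2, 0],
                        [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3.0)]])
        h = convex_hull(PointCloud(pts))
        assert h.volume_mm3 == pytest.approx(a ** 3 / (6 * np.sqrt(2)), rel=1e-9)

    def test_matches_delaunay_volume_oracle(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(500, 3))
        pts = u / np.linalg.norm(u, axis=1, keepdims=True)
        pts *= 20.0 * rng.random((500, 1)) ** (1 / 3)
        h = convex_hull(PointCloud(pts))
        assert h.volume_mm3 == pytest.approx(
            oracles.delaunay_hull_volume(pts), rel=1e-9)

    def test_invariant_under_rigid_transforms(self, rng):
        pts = rng.uniform(0, 30, (200, 3))
        ref = convex_hull(PointCloud(pts))
        for _ in range(20):
            t = RigidTransform.random_small(rng, 180.0, 500.0)
            h = convex_hull(PointCloud(t.apply(pts)))
            assert h.volume_mm3 == pytest.approx(ref.volume_mm3, rel=1e-9)
            assert h.area_mm2 == pytest.approx(ref.area_mm2, rel=1e-9)

    def test_coplanar_input_degenerate_volume_zero(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                               np.zeros(10)])
        h = convex_hull(PointCloud(pts))
        assert h.degenerate
        assert h.volume_mm3 == 0.0

    def test_all_points_inside_hull(self, rng):
        pts = rng.uniform(-5, 5, (100, 3))
        from scipy.spatial import ConvexHull as SciHull

        h = convex_hull(PointCloud(pts))
        eqs = SciHull(pts).equations
        dist = pts @ eqs[:, :3].T + eqs[:, 3]
        assert dist.max() <= 1e-6


class TestProjectedArea:
    def test_dense_rectangle(self):
        x, y = np.meshgrid(np.arange(101.0), np.arange(51.0))
        cloud = PointCloud(np.column_stack([x.ravel(), y.ravel(),
                                            np.zeros(x.size)]))
        assert projected_area(cloud, alpha_mm=5.0) == pytest.approx(5000, rel=0.01)

    def test_rectangle_with_hole(self):
        x, y = np.meshgrid(np.arange(101.0), np.arange(51.0))
        keep = ~((x > 40) & (x < 60) & (y > 15) & (y < 35))
        cloud = PointCloud(np.column_stack([x[keep], y[keep],
                                            np.zeros(keep.sum())]))
        assert projected_area(cloud, alpha_mm=3.0) == pytest.approx(4600, rel=0.03)

    def test_infinite_alpha_equals_convex_hull_area(self, rng):
        pts = rng.uniform(0, 30, (300, 3))
        from scipy.spatial import ConvexHull as SciHull

        hull_area = SciHull(pts[:, :2]).volume   # 2D "volume" is area
        assert projected_area(PointCloud(pts), alpha_mm=np.inf) == \
            pytest.approx(hull_area, rel=1e-12)

    def test_monotone_in_alpha(self, rng):
        pts = rng.uniform(0, 40, (400, 3))
        cloud = PointCloud(pts)
        areas = [projected_area(cloud, a) for a in (2.0, 4.0, 8.0, 16.0, np.inf)]
        assert np.all(np.diff(areas) >= -1e-9)

    def test_collinear_projection_returns_zero(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.arange(10.0)])
        assert projected_area(PointCloud(pts), alpha_mm=5.0) == 0.0


class TestMeshing:
    def test_planar_grid_mesh_area(self, planar_grid):
        mesh = mesh_surface(planar_grid)
        assert mesh_area(mesh) == pytest.approx(2500.0, rel=0.02)
        assert len(np.unique(mesh.faces)) <= len(planar_grid)

    def test_remeshing_is_deterministic(self, rng):
        pts = rng.uniform(0, 30, (500, 2))
        cloud = PointCloud(np.column_stack([pts, np.sin(pts[:, 0] / 5.0)]))
        m1 = mesh_surface(cloud)
        m2 = mesh_surface(cloud)
        assert np.array_equal(m1.faces, m2.faces)

    def test_mesh_area_rigid_invariance_and_additivity(self, rng):
        verts = rng.uniform(0, 10, (30, 3))
        faces = np.array([[i, i + 1, i + 2] for i in range(0, 27, 3)])
        mesh = TriangleMesh(verts, faces)
        total = mesh_area(mesh)
        t = RigidTransform.random_small(rng, 170.0, 300.0)
        assert mesh_area(TriangleMesh(t.apply(verts), faces)) == \
            pytest.approx(total, rel=1e-9)
        parts = sum(mesh_area(TriangleMesh(verts, faces[[i]]))
                    for i in range(len(faces)))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_degenerate_face_contributes_zero(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        degenerate = mesh_area(TriangleMesh(verts, np.array([[0, 1, 2]])))
        assert degenerate == 0.0

    def test_icosphere_area_below_smooth_sphere(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        area = mesh_area(TriangleMesh(ico.vertices, ico.faces))
        assert area < 4 * np.pi * 100.0
        assert area == pytest.approx(4 * np.pi * 100.0, rel=0.02)
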