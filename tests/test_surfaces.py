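"""Surface geometry: normals, vol2surf sampling, surf2vol projection, thresholding."""

import numpy as np
import pytest
from scipy import ndimage

import fsubextract as fx
from fsubextract.errors import EmptyInputError, ParameterError, SpaceMismatchError


def flat_grid_mesh(n=11, spacing=1.0, z=0.0):
    """Regular triangulated sheet at constant z, CCW winding from +z."""
    xs = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v10 = i * n + j, (i + 1) * n + j
            v01, v11 = i * n + j + 1, (i + 1) * n + j + 1
            faces += [[v00, v10, v11], [v00, v11, v01]]
    return fx.SurfaceMesh(vertices=vertices, faces=np.array(faces))


def sphere_mesh(subdiv=3):
    """Icosphere by midpoint subdivision of an icosahedron, radius 1."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
    verts = list(verts)
    for _ in range(subdiv):
        cache, new_faces = {}, []
        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (verts[a] + verts[b]) / 2
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = new_faces
    return fx.SurfaceMesh(vertices=np.array(verts), faces=np.array(faces))


class TestVertexNormals:
    def test_flat_sheet_normals_point_up(self):
        mesh = flat_grid_mesh()
        normals = fx.compute_vertex_normals(mesh)
        np.testing.assert_allclose(normals, np.tile([0, 0, 1.0], (mesh.n_vertices, 1)),
                                   atol=1e-12)

    def test_sphere_normals_are_radial(self):
        mesh = sphere_mesh()
        normals = fx.compute_vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        cos = np.sum(normals * radial, axis=1)
        angles_deg = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert angles_deg.max() < 5.0

    def test_single_triangle_normals_equal_face_normal(self):
        mesh = fx.SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]]),
            faces=np.array([[0, 1, 2]]),
        )
        normals = fx.compute_vertex_normals(mesh)
        for n in normals:
            np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_unit_length(self):
        normals = fx.compute_vertex_normals(sphere_mesh(subdiv=2))
        np.testing.assert_allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-6)

    def test_isolated_vertex_warns_with_zero_normal(self):
        mesh = fx.SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5]]),
            faces=np.array([[0, 1, 2]]),
        )
        with pytest.warns(UserWarning, match="no incident face"):
            normals = fx.compute_vertex_normals(mesh)
        np.testing.assert_array_equal(normals[3], [0, 0, 0])


def centered_volume(values):
    """Volume whose voxel centers sit at integer world coordinates around 0."""
    values = np.asarray(values, dtype=float)
    affine = np.eye(4)
    affine[:3, 3] = -(np.array(values.shape) - 1) / 2
    return fx.VolumeImage(values=values, affine=affine)


class TestSampleVolume:
    def test_constant_volume(self):
        vol = centered_volume(np.full((31, 31, 21), 7.0))
        mesh = flat_grid_mesh(n=9)
        out = fx.sample_volume_at_vertices(vol, mesh, fx.ProjectionParams())
        np.testing.assert_allclose(out.values, 7.0)

    def test_linear_ramp_trilinear_depth0(self):
        shape = (15, 15, 15)
        k = np.arange(shape[2], dtype=float)
        vol = centered_volume(np.broadcast_to(k - 7.0, shape).copy())
        mesh = flat_grid_mesh(n=5, z=1.25)
        out = fx.sample_volume_at_vertices(
            vol, mesh, fx.ProjectionParams(inward_depth_mm=0.0, step_mm=0.25),
            interp="trilinear",
        )
        np.testing.assert_allclose(out.values, 1.25, atol=1e-12)

    def test_vertex_outside_grid_is_zero_and_flagged(self):
        vol = centered_volume(np.full((5, 5, 5), 3.0))
        mesh = fx.SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 50.0],
                               [1, 0, 50], [0, 1, 50]]),
            faces=np.array([[0, 1, 2], [3, 4, 5]]),
        )
        out = fx.sample_volume_at_vertices(
            vol, mesh, fx.ProjectionParams(inward_depth_mm=0.0, step_mm=0.25))
        assert out.values[3] == 0.0 and out.missing[3]
        assert out.values[0] == 3.0 and not out.missing[0]

    def test_all_outside_raises_space_mismatch(self):
        vol = centered_volume(np.ones((5, 5, 5)))
        mesh = flat_grid_mesh(n=3, z=500.0)
        with pytest.raises(SpaceMismatchError):
            fx.sample_volume_at_vertices(vol, mesh)

    def test_max_combine_is_monotone(self, rng):
        small = centered_volume(rng.uniform(0, 1, (21, 21, 11)))
        big = fx.VolumeImage(values=small.values + rng.uniform(0, 1, small.shape),
                             affine=small.affine)
        mesh = flat_grid_mesh(n=7)
        p = fx.ProjectionParams(combine="max")
        lo = fx.sample_volume_at_vertices(small, mesh, p).values
        hi = fx.sample_volume_at_vertices(big, mesh, p).values
        assert (hi >= lo - 1e-12).all()


class TestProjectLabel:
    def test_single_vertex_depth0_sets_one_voxel(self):
        grid = centered_volume(np.zeros((11, 11, 11)))
        mesh = flat_grid_mesh(n=5)  # vertex at world (0,0,0) == center of voxel (5,5,5)
        vid = int(np.argmin(np.linalg.norm(mesh.vertices, axis=1)))
        label = fx.VertexLabel(vertex_indices=[vid])
        # depth 0 requires a positive step but samples only depth 0
        mask = fx.project_label_to_volume(
            mesh, label, grid, fx.ProjectionParams(inward_depth_mm=0.0, step_mm=0.25))
        assert mask.n_set == 1
        np.testing.assert_array_equal(np.argwhere(mask.values)[0], [5, 5, 5])

    def test_disc_projection_matches_cylinder_oracle(self):
        """Projected disc == brute-force point-in-cylinder voxel test, up to
        the 1-voxel boundary shell."""
        grid = centered_volume(np.zeros((31, 31, 11)))
        mesh = flat_grid_mesh(n=31, z=0.0)
        d = np.linalg.norm(mesh.vertices[:, :2], axis=1)
        label = fx.VertexLabel(vertex_indices=np.where(d <= 5.0)[0])
        depth = 2.0
        mask = fx.project_label_to_volume(
            mesh, label, grid, fx.ProjectionParams(inward_depth_mm=depth, step_mm=0.25))

        ijk = np.indices(grid.shape).reshape(3, -1).T
        centers = grid.voxel_to_world(ijk.astype(float))
        in_cyl = (np.linalg.norm(centers[:, :2], axis=1) <= 5.0) & \
                 (centers[:, 2] <= 0.0) & (centers[:, 2] >= -depth)
        oracle = np.zeros(grid.shape, bool)
        oracle[ijk[in_cyl, 0], ijk[in_cyl, 1], ijk[in_cyl, 2]] = True

        diff = oracle ^ (mask.values > 0)
        # symmetric difference confined to the 1-voxel shell around the cylinder
        dist_in = ndimage.distance_transform_edt(~oracle)
        dist_out = ndimage.distance_transform_edt(oracle)
        shell = (dist_in <= 1.0) | (dist_out <= 1.0)
        assert not (diff & ~shell).any()

    def test_two_patches_give_two_components(self):
        grid = centered_volume(np.zeros((31, 31, 11)))
        mesh = flat_grid_mesh(n=31)
        d1 = np.linalg.norm(mesh.vertices[:, :2] - [-9, 0], axis=1)
        d2 = np.linalg.norm(mesh.vertices[:, :2] - [9, 0], axis=1)
        label = fx.VertexLabel(vertex_indices=np.where((d1 <= 3) | (d2 <= 3))[0])
        mask = fx.project_label_to_volume(mesh, label, grid)
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        _, n_components = ndimage.label(mask.values, structure=structure)
        assert n_components == 2

    def test_empty_label_rejected(self):
        grid = centered_volume(np.zeros((5, 5, 5)))
        with pytest.raises((EmptyInputError, Exception)):
            fx.project_label_to_volume(
                flat_grid_mesh(n=3),
                fx.VertexLabel(vertex_indices=np.array([], dtype=int)),
                grid,
            )

    def test_voxel_count_monotone_in_depth(self):
        grid = centered_volume(np.zeros((21, 21, 11)))
        mesh = flat_grid_mesh(n=15)
        d = np.linalg.norm(mesh.vertices[:, :2], axis=1)
        label = fx.VertexLabel(vertex_indices=np.where(d <= 4)[0])
        counts = [
            fx.project_label_to_volume(
                mesh, label, grid,
                fx.ProjectionParams(inward_depth_mm=dep, step_mm=0.25)).n_set
            for dep in (0.5, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts)


class TestThresholdPercentile:
    def test_top_10_percent_of_1_to_100(self):
        """100 values 1..100 at the 90th percentile keep exactly the top 10."""
        stat = fx.SurfaceMap(values=np.arange(1.0, 121.0))  # 120-vertex mesh
        searchspace = fx.VertexLabel(vertex_indices=np.arange(100))
        out = fx.threshold_percentile(stat, searchspace, 90.0)
        assert len(out) == 10
        assert set(stat.values[out.vertex_indices]) == set(range(91, 101))

    def test_selection_order_invariant(self, rng):
        vals = rng.uniform(size=200)
        stat = fx.SurfaceMap(values=vals)
        idx = np.arange(150)
        base = fx.threshold_percentile(stat, fx.VertexLabel(vertex_indices=idx), 75.0)
        shuffled = fx.threshold_percentile(
            stat, fx.VertexLabel(vertex_indices=rng.permutation(idx)), 75.0)
        np.testing.assert_array_equal(base.vertex_indices, shuffled.vertex_indices)

    def test_constant_map_empty_with_warning(self):
        stat = fx.SurfaceMap(values=np.full(50, 3.0))
        with pytest.warns(UserWarning, match="no vertices"):
            out = fx.threshold_percentile(
                stat, fx.VertexLabel(vertex_indices=np.arange(50)), 90.0)
        assert len(out) == 0

    def test_percentile_zero_keeps_all_above_minimum(self):
        stat = fx.SurfaceMap(values=np.array([5.0, 1.0, 2.0, 3.0]))
        out = fx.threshold_percentile(
            stat, fx.VertexLabel(vertex_indices=np.arange(4)), 0.0)
        assert set(out.vertex_indices) == {0, 2, 3}

    @pytest.mark.parametrize("bad", [-1.0, 100.0, 250.0])
    def test_out_of_range_percentile_rejected(self, bad):
        stat = fx.SurfaceMap(values=np.arange(10.0))
        with pytest.raises(ParameterError):
            fx.threshold_percentile(
                stat, fx.VertexLabel(vertex_indices=np.arange(10)), bad)

    def test_selection_bound(self, rng):
        """At most ceil((100-p)/100 * n) vertices survive."""
        vals = rng.normal(size=500)
        stat = fx.SurfaceMap(values=vals)
        space = fx.VertexLabel(vertex_indices=np.arange(500))
        for p in (10.0, 50.0, 90.0, 99.0):
            out = fx.threshold_percentile(stat, space, p)
            assert len(out) <= int(np.ceil((100 - p) / 100 * 500))


class TestApplyAffine:
    def test_identity(self, rng):
        pts = rng.uniform(-10, 10, (20, 3))
        np.testing.assert_array_equal(fx.apply_affine(pts, np.eye(4)), pts)

    def test_rigid_preserves_distances(self, rng):
        theta = 0.7
        rot = np.eye(4)
        rot[:3, :3] = [[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        rot[:3, 3] = [3, -2, 5]
        pts = rng.uniform(-10, 10, (30, 3))
        out = fx.apply_affine(pts, rot)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_inverse_round_trip(self, rng):
        x = np.eye(4)
        x[:3, :3] = rng.uniform(-1, 1, (3, 3)) + 2 * np.eye(3)
        x[:3, 3] = rng.uniform(-5, 5, 3)
        pts = rng.uniform(-10, 10, (25, 3))
        back = fx.apply_affine(fx.apply_affine(pts, x), np.linalg.inv(x))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_tractogram_transform(self):
        t = fx.Tractogram(streamlines=[np.array([[1, 1, 1], [2, 2, 2]], "f4")])
        m = np.eye(4)
        m[0, 3] = 2
        out = fx.apply_affine(t, m)
        np.testing.assert_allclose(out.streamlines[0][0], [3, 1, 1])
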