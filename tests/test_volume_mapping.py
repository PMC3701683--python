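"""Volume sampling algorithms, sign filtering, colormaps and ROI meshes."""

import numpy as np
import pytest

from bnv import (
    COLORMAP_PRESETS,
    ColormapSpec,
    MAPPING_ALGORITHMS,
    ParameterError,
    SurfaceMesh,
    ValidationError,
    VertexValues,
    VolumeImage,
    apply_sign_filter,
    colorize,
    colormap_names,
    map_volume_to_surface,
    roi_cluster_mesh,
    world_to_voxel,
)
from bnv.fixtures import make_gradient_volume


def mesh_at(points):
    """Degenerate test mesh: one triangle face reusing the first vertices."""
    pts = np.atleast_2d(np.asarray(points, float))
    while len(pts) < 3:
        pts = np.vstack([pts, pts[-1] + 1e-9])
    return SurfaceMesh(pts, [[0, 1, 2]])


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def test_world_to_voxel_identity_scale_translate(gradient_volume):
    np.testing.assert_allclose(
        world_to_voxel([1.2, 0.9, 2.1], gradient_volume), [1.2, 0.9, 2.1]
    )
    vol2 = VolumeImage(gradient_volume.grid, np.diag([2.0, 2.0, 2.0, 1.0]))
    np.testing.assert_allclose(world_to_voxel([4.0, 0, 0], vol2), [2, 0, 0])
    aff = np.eye(4)
    aff[:3, 3] = [-10, -10, -10]
    vol3 = VolumeImage(gradient_volume.grid, aff)
    np.testing.assert_allclose(world_to_voxel([0.0, 0, 0], vol3), [10, 10, 10])


# ---------------------------------------------------------------------------
# the eight mapping algorithms
# ---------------------------------------------------------------------------

def test_nearest_voxel_rounds_half_up(gradient_volume):
    got = map_volume_to_surface(mesh_at([1.2, 0.9, 2.1]), gradient_volume, "nearest_voxel")
    assert got.values[0] == 211  # voxel (1,1,2): 1 + 10 + 200


def test_interpolated_midpoint(gradient_volume):
    got = map_volume_to_surface(mesh_at([0.5, 0, 0]), gradient_volume, "interpolated")
    assert got.values[0] == pytest.approx(0.5)


def test_interpolated_equals_nearest_at_integral_coords(gradient_volume, rng):
    pts = rng.integers(0, 3, size=(10, 3)).astype(float)
    mesh = SurfaceMesh(pts, [[0, 1, 2]])
    a = map_volume_to_surface(mesh, gradient_volume, "interpolated")
    b = map_volume_to_surface(mesh, gradient_volume, "nearest_voxel")
    np.testing.assert_allclose(a.values, b.values)


def test_all_algorithms_collapse_on_constant_volume():
    vol = make_gradient_volume((4, 4, 4), pattern="constant", constant=3.5)
    mesh = mesh_at([[1, 1, 1], [2.2, 1.7, 0.4], [3, 0, 2]])
    for algo in MAPPING_ALGORITHMS:
        got = map_volume_to_surface(mesh, vol, algo)
        np.testing.assert_allclose(got.values, 3.5, err_msg=algo)


def test_block_reductions_ordered(gradient_volume, rng):
    pts = rng.uniform(0, 2, size=(12, 3))
    mesh = SurfaceMesh(pts, [[0, 1, 2]])
    avg = map_volume_to_surface(mesh, gradient_volume, "average_voxel").values
    mx = map_volume_to_surface(mesh, gradient_volume, "maximum_voxel").values
    mn = map_volume_to_surface(mesh, gradient_volume, "minimum_voxel").values
    ext = map_volume_to_surface(mesh, gradient_volume, "extremum_voxel").values
    assert (avg <= mx + 1e-12).all() and (avg >= mn - 1e-12).all()
    assert (np.abs(ext) >= np.abs(mx) - 1e-12).all()
    assert (np.abs(ext) >= np.abs(mn) - 1e-12).all()


def test_extremum_prefers_sign_magnitude():
    grid = np.zeros((3, 3, 3))
    grid[0, 1, 1] = -5.0
    grid[2, 1, 1] = 3.0
    vol = VolumeImage(grid, np.eye(4))
    got = map_volume_to_surface(mesh_at([1, 1, 1]), vol, "extremum_voxel")
    assert got.values[0] == -5.0
    grid[2, 1, 1] = 5.0  # magnitude tie: positive wins
    got = map_volume_to_surface(mesh_at([1, 1, 1]), VolumeImage(grid, np.eye(4)),
                                "extremum_voxel")
    assert got.values[0] == 5.0


def test_gaussian_sigma_zero_is_nearest(gradient_volume, rng):
    pts = rng.uniform(0, 2, size=(8, 3))
    mesh = SurfaceMesh(pts, [[0, 1, 2]])
    g = map_volume_to_surface(mesh, gradient_volume, "gaussian", sigma=0.0)
    nn = map_volume_to_surface(mesh, gradient_volume, "nearest_voxel")
    np.testing.assert_allclose(g.values, nn.values)


def test_average_vertex_smooths_over_one_ring():
    # a 3-vertex path: smoothing replaces each value by its closed-ring mean
    vol = make_gradient_volume((5, 5, 5), pattern="axis_gradient")
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
    nn = map_volume_to_surface(mesh, vol, "nearest_voxel").values
    av = map_volume_to_surface(mesh, vol, "average_vertex").values
    np.testing.assert_allclose(av, [nn.mean()] * 3)  # single face = full 1-ring


def test_out_of_grid_vertices_flagged(gradient_volume):
    got = map_volume_to_surface(mesh_at([50.0, 0, 0]), gradient_volume, "nearest_voxel")
    assert got.unmapped[0] and got.values[0] == 0.0


def test_unknown_algorithm(gradient_volume):
    with pytest.raises(ParameterError):
        map_volume_to_surface(mesh_at([0, 0, 0]), gradient_volume, "bilinear")


# ---------------------------------------------------------------------------
# sign filter
# ---------------------------------------------------------------------------

def test_sign_filter():
    v = VertexValues([-1.0, 0.0, 2.0])
    pos = apply_sign_filter(v, "positive")
    np.testing.assert_allclose(pos.values, [0, 0, 2])
    assert pos.unmapped.tolist() == [True, False, False]
    neg = apply_sign_filter(v, "negative")
    np.testing.assert_allclose(neg.values, [-1, 0, 0])
    assert neg.unmapped.tolist() == [False, False, True]
    both = apply_sign_filter(v, "both")
    np.testing.assert_allclose(both.values, v.values)
    assert not both.unmapped.any()


# ---------------------------------------------------------------------------
# colormaps
# ---------------------------------------------------------------------------

def test_registry_has_24_presets_including_named_six():
    names = colormap_names()
    assert len(names) == 24 and len(set(names)) == 24
    for required in ("jet", "hsv", "hot", "cold", "winter", "summer"):
        assert required in names
    for tab in COLORMAP_PRESETS.values():
        assert tab.shape[1] == 3 and len(tab) >= 2


def test_custom_colormap_linear_blend_and_clamp():
    spec = ColormapSpec(custom=[[0, 0, 0], [1, 1, 1]], display_range=(0.0, 1.0))
    rgb = colorize(VertexValues([0.5, 2.0, -1.0]), spec)
    np.testing.assert_allclose(rgb[0], [0.5, 0.5, 0.5])
    np.testing.assert_allclose(rgb[1], [1, 1, 1])   # clamps to last color
    np.testing.assert_allclose(rgb[2], [0, 0, 0])
    with pytest.raises(ParameterError):
        ColormapSpec(custom=[[1, 1, 1]]).table()


def test_unmapped_vertices_get_base_color():
    spec = ColormapSpec(custom=[[0, 0, 0], [1, 1, 1]], display_range=(0, 1))
    vals = VertexValues([0.5, 0.5], unmapped=[False, True])
    rgb = colorize(vals, spec, base_color=(0.2, 0.3, 0.4))
    np.testing.assert_allclose(rgb[1], [0.2, 0.3, 0.4])


def test_autoscale_range_excludes_unmapped():
    spec = ColormapSpec(custom=[[0, 0, 0], [1, 1, 1]])
    vals = VertexValues([0.0, 1.0, 100.0], unmapped=[False, False, True])
    rgb = colorize(vals, spec)
    np.testing.assert_allclose(rgb[1], [1, 1, 1])  # 1.0 is the observed max


# ---------------------------------------------------------------------------
# ROI isosurfaces
# ---------------------------------------------------------------------------

def single_voxel_volume(i=2, j=2, k=2, shape=(5, 5, 5)):
    grid = np.zeros(shape)
    grid[i, j, k] = 1
    return VolumeImage(grid, np.eye(4))


def test_single_voxel_roi_closed_and_centered():
    mesh = roi_cluster_mesh(single_voxel_volume(), 1)
    assert mesh.n_faces > 0
    np.testing.assert_allclose(mesh.vertices.mean(axis=0), [2, 2, 2], atol=0.5)
    # closed surface: every undirected edge borders exactly two faces
    from collections import Counter

    cnt = Counter()
    for a, b, c in mesh.faces:
        for e in ((a, b), (b, c), (c, a)):
            cnt[tuple(sorted(e))] += 1
    assert set(cnt.values()) == {2}


def test_absent_label_gives_empty_mesh():
    mesh = roi_cluster_mesh(single_voxel_volume(), 9)
    assert mesh.n_vertices == 0 and mesh.n_faces == 0


def test_two_disjoint_clusters_two_components():
    grid = np.zeros((7, 7, 7))
    grid[1, 1, 1] = 1
    grid[5, 5, 5] = 1
    mesh = roi_cluster_mesh(VolumeImage(grid, np.eye(4)), 1)
    # count connected components by face-adjacency traversal
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    for a, b, c in mesh.faces:
        g.add_edges_from([(a, b), (b, c), (c, a)])
    assert nx.number_connected_components(g) == 2


def test_non_integer_volume_rejected():
    grid = np.full((3, 3, 3), 0.4)
    with pytest.raises(ValidationError, match="integer"):
        roi_cluster_mesh(VolumeImage(grid, np.eye(4)), 1)


def test_roi_mesh_respects_affine():
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = [10, 0, 0]
    grid = np.zeros((5, 5, 5))
    grid[2, 2, 2] = 1
    mesh = roi_cluster_mesh(VolumeImage(grid, aff), 1)
    np.testing.assert_allclose(mesh.vertices.mean(axis=0), [14, 4, 4], atol=1.0)


def ray_parity_inside(mesh, point, direction):
    """Independent oracle: odd number of ray/triangle crossings -> inside
    (Moller-Trumbore intersection, vectorized over faces)."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    d = np.asarray(direction, float)
    e1, e2 = v1 - v0, v2 - v0
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = point - v0
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = q @ d * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    return hits.sum() % 2 == 1


def test_roi_encloses_labeled_voxel_centers(rng):
    """Every labeled voxel center lies inside the ROI mesh (ray parity)."""
    for _ in range(10):
        grid = np.zeros((6, 6, 6))
        n_vox = int(rng.integers(1, 6))
        ijk = rng.integers(1, 5, size=(n_vox, 3))
        grid[tuple(ijk.T)] = 1
        vol = VolumeImage(grid, np.eye(4))
        mesh = roi_cluster_mesh(vol, 1)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for center in np.argwhere(grid == 1).astype(float):
            assert ray_parity_inside(mesh, center, direction)
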