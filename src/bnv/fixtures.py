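"""Deterministic synthetic inputs: toy surfaces, networks and volumes.

These generators stand in for anatomical surfaces, parcellation node
tables, association matrices and statistical volumes. They are first-class
package code: the same seed always yields the same arrays, and every
generator can also serialize its output to the on-disk formats for
end-to-end runs. Anatomical realism is explicitly not a goal — the shapes
only need to exercise the geometric and topological rules (hemisphere
divisibility, x-sign conventions, voxel/world transforms).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io_formats import (
    EdgeMatrix,
    NodeSet,
    SurfaceMesh,
    VolumeImage,
    write_edge_file,
    write_node_file,
    write_surface_nv,
    write_volume,
)


def _unit_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return v, f


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One loop of midpoint subdivision, re-projected to the unit sphere."""
    cache: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = (np.asarray(verts[a]) + np.asarray(verts[b])) / 2
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.asarray(verts), np.asarray(out, dtype=int)


def _blob(n_min: int, radius: float, center, rng: np.random.Generator) -> SurfaceMesh:
    verts, faces = _unit_icosahedron()
    while len(verts) < n_min:
        verts, faces = _subdivide(verts, faces)
    # mild radial jitter keeps the blob convex-ish but non-spherical
    bump = 1.0 + 0.1 * rng.standard_normal(len(verts))
    verts = verts * (radius * bump[:, None]) + np.asarray(center, dtype=float)
    return SurfaceMesh(verts, faces)


def make_two_hemisphere_surface(
    n_per_side: int = 12, gap_mm: float = 10.0, seed: int = 0
) -> SurfaceMesh:
    """Two disjoint convex blobs at x = +/-(gap/2 + extent).

    The result is hemisphere-divisible by construction. ``gap_mm = 0`` is
    the merged variant: one blob straddling x = 0, which is not divisible.
    """
    if n_per_side < 4:
        raise ParameterError("n_per_side must be >= 4")
    if gap_mm < 0:
        raise ParameterError("gap_mm must be >= 0")
    rng = np.random.default_rng(seed)
    radius = 30.0
    if gap_mm == 0:
        return _blob(n_per_side, radius, (0.0, 0.0, 0.0), rng)
    offset = gap_mm / 2 + radius * 1.2  # 1.2 covers the radial jitter
    left = _blob(n_per_side, radius, (-offset, 0.0, 0.0), rng)
    right = _blob(n_per_side, radius, (offset, 0.0, 0.0), rng)
    verts = np.vstack([left.vertices, right.vertices])
    faces = np.vstack([left.faces, right.faces + left.n_vertices])
    return SurfaceMesh(verts, faces)


def make_toy_network(
    n_nodes: int = 12,
    n_modules: int = 3,
    density: float = 0.3,
    seed: int = 0,
    symmetric: bool = True,
) -> tuple[NodeSet, EdgeMatrix]:
    """A small labeled network split across the two hemispheres.

    Coordinates land in x < 0 and x > 0 halves; column 4 carries integer
    module indices in [1, n_modules]; column 5 is proportional to node
    degree. Exactly round(density * n(n-1)/2) upper-triangle weights are
    nonzero (mirrored when symmetric).
    """
    if not 2 <= n_nodes <= 200:
        raise ParameterError("n_nodes must lie in [2, 200]")
    if not 0 < density <= 1:
        raise ParameterError("density must lie in (0, 1]")
    if n_modules < 1:
        raise ParameterError("n_modules must be >= 1")
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    x = np.concatenate(
        [-rng.uniform(20, 60, half), rng.uniform(20, 60, n_nodes - half)]
    )
    coords = np.column_stack([x, rng.uniform(-60, 60, n_nodes), rng.uniform(-40, 50, n_nodes)])
    modules = rng.integers(1, n_modules + 1, n_nodes).astype(float)

    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    k = int(np.floor(density * len(pairs) + 0.5))
    chosen = rng.permutation(len(pairs))[:k]
    w = np.zeros((n_nodes, n_nodes))
    for m in chosen:
        i, j = pairs[m]
        w[i, j] = rng.uniform(0.1, 1.0)
    if symmetric:
        w = w + w.T
    else:
        # add a reverse-direction weight somewhere to guarantee asymmetry
        w[1, 0] = w[0, 1] + 0.5
    degree = (w != 0).sum(axis=1).astype(float)
    sizes = 1.0 + degree  # strictly positive, degree-proportional
    nodes = NodeSet(coords, modules, sizes, [f"N{i + 1}" for i in range(n_nodes)])
    return nodes, EdgeMatrix(w)


def make_gradient_volume(
    shape: tuple[int, int, int] = (8, 8, 8),
    affine: np.ndarray | None = None,
    pattern: str = "axis_gradient",
    seed: int = 0,
    constant: float = 1.0,
    n_labels: int = 2,
) -> VolumeImage:
    """Synthetic volume: ``constant``, ``axis_gradient`` with
    value(i,j,k) = i + 10j + 100k, or ``labels`` (disjoint integer-labeled
    blocks on a zero background, labels 1..n_labels)."""
    if min(shape) < 2:
        raise ParameterError("volume shape must be at least 2 in every axis")
    if affine is None:
        affine = np.eye(4)
    if pattern == "constant":
        grid = np.full(shape, float(constant))
    elif pattern == "axis_gradient":
        i, j, k = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        grid = (i + 10 * j + 100 * k).astype(float)
    elif pattern == "labels":
        rng = np.random.default_rng(seed)
        grid = np.zeros(shape)
        for label in range(1, n_labels + 1):
            sz = [max(1, s // 4) for s in shape]
            corner = [int(rng.integers(0, s - z + 1)) for s, z in zip(shape, sz)]
            grid[
                corner[0]: corner[0] + sz[0],
                corner[1]: corner[1] + sz[1],
                corner[2]: corner[2] + sz[2],
            ] = label
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")
    return VolumeImage(grid, affine)


def write_fixture_set(
    directory: str | Path,
    seed: int = 0,
    n_nodes: int = 10,
    density: float = 0.4,
) -> dict[str, Path]:
    """Emit a matching surface/node/edge/volume set as real files for
    end-to-end runs. Returns {kind: path}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    surface = make_two_hemisphere_surface(seed=seed)
    nodes, edges = make_toy_network(n_nodes=n_nodes, density=density, seed=seed)
    volume = make_gradient_volume(pattern="labels", seed=seed)
    paths = {
        "surface": directory / "fixture_surface.nv",
        "node": directory / "fixture_nodes.node",
        "edge": directory / "fixture_edges.edge",
        "volume": directory / "fixture_volume.nii",
    }
    write_surface_nv(surface, paths["surface"])
    write_node_file(nodes, paths["node"])
    write_edge_file(edges, paths["edge"])
    write_volume(volume, paths["volume"])
    return paths
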