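"""Sphere, cylinder and arrow glyph meshes for ball-and-stick rendering.

Nodes are unit lat/long spheres scaled and translated into place; edges are
canonical z-aligned cylinders rotated onto the segment between their two
nodes by an axis-angle rotation (axis = cross product of the z unit vector
and the segment direction, angle = their included angle) and then
translated. Directed edges get a cone head on the target end.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError
from .io_formats import SurfaceMesh


class DetailLevel(str, Enum):
    """Mesh sampling detail for node spheres and edge cylinders.

    ``node_n`` is the sphere grid parameter (an n-by-n patch grid);
    ``edge_n`` is the number of circumferential samples on a cylinder.
    """

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"

    @property
    def node_n(self) -> int:
        return {"high": 100, "moderate": 50, "low": 20}[self.value]

    @property
    def edge_n(self) -> int:
        return {"high": 20, "moderate": 10, "low": 5}[self.value]


@dataclass
class GlyphMesh:
    """A small triangulated glyph (node sphere, edge cylinder or arrow)."""

    vertices: np.ndarray      # (n, 3) mm
    faces: np.ndarray         # (m, 3) int
    provenance: str           # node_sphere | edge_cylinder | arrow

    def as_surface(self) -> SurfaceMesh:
        return SurfaceMesh(self.vertices, self.faces)


def _grid_faces(n_rows: int, n_cols: int, wrap_cols: bool = False) -> np.ndarray:
    """Triangulate an (n_rows x n_cols) point grid into quads split in two."""
    faces = []
    cols = n_cols if wrap_cols else n_cols - 1
    for i in range(n_rows - 1):
        for j in range(cols):
            a = i * n_cols + j
            b = i * n_cols + (j + 1) % n_cols
            c = (i + 1) * n_cols + j
            d = (i + 1) * n_cols + (j + 1) % n_cols
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=int).reshape(-1, 3)


def sphere_mesh(center, r: float, n: int = 20) -> GlyphMesh:
    """Latitude/longitude sphere of radius ``r`` at ``center``.

    Grid point (i, j), i, j in {0..n}: latitude phi = -pi/2 + pi*i/n,
    longitude theta = 2*pi*j/n. (n+1)^2 grid points; quads triangulated.
    Degenerate pole quads are kept as zero-area triangles for simplicity.
    """
    if r <= 0:
        raise ParameterError(f"sphere radius must be positive, got {r}")
    if n < 2:
        raise ParameterError(f"sphere grid parameter must be >= 2, got {n}")
    center = np.asarray(center, dtype=float)
    i = np.arange(n + 1)
    phi = -np.pi / 2 + np.pi * i / n          # latitude rows
    theta = 2 * np.pi * i / n                 # longitude columns
    ph, th = np.meshgrid(phi, theta, indexing="ij")
    pts = np.stack(
        [np.cos(ph) * np.cos(th), np.cos(ph) * np.sin(th), np.sin(ph)], axis=-1
    ).reshape(-1, 3)
    verts = pts * r + center
    faces = _grid_faces(n + 1, n + 1)
    return GlyphMesh(verts, faces, "node_sphere")


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the +z unit vector onto unit ``direction``.

    Axis = z x d, angle = arccos(z . d). When d is antiparallel to z the
    cross product vanishes; we then rotate about +x by pi (any axis in the
    xy-plane works — fixing x makes the output deterministic).
    """
    d = np.asarray(direction, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    c = float(np.clip(np.dot(z, d), -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    angle = np.arccos(c)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _ring(radius: float, n: int) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=-1)


def cylinder_mesh(a, b, t: float, n: int = 10) -> GlyphMesh:
    """Open cylinder of radius ``t`` from point ``a`` to point ``b``.

    Built as a canonical two-ring cylinder along +z of length ||b - a||,
    rotated by the axis-angle rule and translated to ``a``. A straight
    cylinder needs no intermediate rings, so the vertex budget goes to the
    circumference. Uncapped: node spheres visually cap edge ends.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if t <= 0:
        raise ParameterError(f"cylinder radius must be positive, got {t}")
    if n < 3:
        raise ParameterError(f"circumferential samples must be >= 3, got {n}")
    length = float(np.linalg.norm(b - a))
    if length < 1e-12:
        raise ParameterError("degenerate edge: endpoints coincide")
    ring = _ring(t, n)
    bottom = np.column_stack([ring, np.zeros(n)])
    top = np.column_stack([ring, np.full(n, length)])
    verts = np.vstack([bottom, top])
    R = _rotation_to((b - a) / length)
    verts = verts @ R.T + a
    faces = _grid_faces(2, n, wrap_cols=True)
    return GlyphMesh(verts, faces, "edge_cylinder")


#: directed-edge proportions: shaft covers the leading fraction of the
#: segment, the cone head the rest, with head base radius = head_radius_factor * t
ARROW_SHAFT_FRACTION = 0.8
ARROW_HEAD_RADIUS_FACTOR = 2.0


def arrow_mesh(a, b, t: float, n: int = 10) -> GlyphMesh:
    """Directed edge glyph: cylinder shaft over the first 80% of a->b plus a
    cone (base radius 2t) over the final 20%, apex at ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if t <= 0:
        raise ParameterError(f"arrow radius must be positive, got {t}")
    if n < 3:
        raise ParameterError(f"circumferential samples must be >= 3, got {n}")
    length = float(np.linalg.norm(b - a))
    if length < 1e-12:
        raise ParameterError("degenerate edge: endpoints coincide")
    d = (b - a) / length
    split = a + d * (ARROW_SHAFT_FRACTION * length)
    shaft = cylinder_mesh(a, split, t, n)

    # cone in canonical frame: base ring at z = split height, apex at z = length
    ring = _ring(ARROW_HEAD_RADIUS_FACTOR * t, n)
    base = np.column_stack([ring, np.full(n, ARROW_SHAFT_FRACTION * length)])
    apex = np.array([[0.0, 0.0, length]])
    cone_verts = np.vstack([base, apex]) @ _rotation_to(d).T + a
    apex_idx = n
    cone_faces = np.array([(k, (k + 1) % n, apex_idx) for k in range(n)], dtype=int)

    verts = np.vstack([shaft.vertices, cone_verts])
    faces = np.vstack([shaft.faces, cone_faces + len(shaft.vertices)])
    return GlyphMesh(verts, faces, "arrow")
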