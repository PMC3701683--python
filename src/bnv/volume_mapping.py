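"""Volume-to-surface mapping, sign filtering, colormaps and ROI isosurfaces.

Eight sampling rules assign each surface vertex a scalar from a 3-D image.
All of them start by taking the vertex's continuous voxel coordinate (the
inverse affine applied to its world position, no rounding):

``nearest_voxel``
    value at the per-axis round-half-up voxel.
``average_vertex``
    nearest_voxel followed by one smoothing pass over the mesh: each vertex
    becomes the mean of itself and its 1-ring neighbors.
``average_voxel`` / ``maximum_voxel`` / ``minimum_voxel``
    mean / max / min over the 3x3x3 voxel block around the nearest voxel,
    clipped at the volume borders.
``extremum_voxel``
    the block value of largest magnitude, sign preserved (positive wins a
    magnitude tie).
``gaussian``
    the whole volume convolved with a Gaussian kernel (sigma in voxels,
    truncated at 2 sigma), then nearest_voxel on the smoothed volume.
``interpolated``
    trilinear interpolation at the continuous voxel coordinate.

Vertices whose nearest voxel falls outside the grid get value 0 and are
flagged unmapped; unmapped vertices keep the surface base color and are
excluded from colormap range autoscaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib import colormaps as _mpl_colormaps
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .io_formats import SurfaceMesh, VertexValues, VolumeImage

MAPPING_ALGORITHMS = (
    "nearest_voxel",
    "average_vertex",
    "average_voxel",
    "gaussian",
    "interpolated",
    "maximum_voxel",
    "minimum_voxel",
    "extremum_voxel",
)


# ---------------------------------------------------------------------------
# coordinate transforms and sampling
# ---------------------------------------------------------------------------

def world_to_voxel(points, volume: VolumeImage) -> np.ndarray:
    """Continuous voxel coordinates of world-space point(s); no rounding."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(volume.affine)
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = (hom @ inv.T)[:, :3]
    return out[0] if np.asarray(points).ndim == 1 else out


def voxel_to_world(ijk, volume: VolumeImage) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(ijk, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = (hom @ volume.affine.T)[:, :3]
    return out[0] if np.asarray(ijk).ndim == 1 else out


def _nearest_index(coords: np.ndarray) -> np.ndarray:
    """Per-axis round-half-up to the nearest voxel index."""
    return np.floor(coords + 0.5).astype(int)


def _in_grid(idx: np.ndarray, shape) -> np.ndarray:
    return np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)


def _block_reduce(grid: np.ndarray, idx: np.ndarray, ok: np.ndarray, reducer) -> np.ndarray:
    """Apply ``reducer`` over each vertex's 3x3x3 block clipped at borders."""
    out = np.zeros(len(idx))
    shape = grid.shape
    for m in np.flatnonzero(ok):
        i, j, k = idx[m]
        block = grid[
            max(i - 1, 0): min(i + 2, shape[0]),
            max(j - 1, 0): min(j + 2, shape[1]),
            max(k - 1, 0): min(k + 2, shape[2]),
        ]
        out[m] = reducer(block)
    return out


def _extremum(block: np.ndarray) -> float:
    hi, lo = float(block.max()), float(block.min())
    return hi if abs(hi) >= abs(lo) else lo  # positive wins a magnitude tie


def map_volume_to_surface(
    mesh: SurfaceMesh,
    volume: VolumeImage,
    algo: str = "nearest_voxel",
    sigma: float = 1.0,
) -> VertexValues:
    """Assign each surface vertex a scalar from the volume (see module docs).

    ``sigma`` (voxels) only affects the ``gaussian`` algorithm.
    """
    if algo not in MAPPING_ALGORITHMS:
        raise ParameterError(
            f"unknown mapping algorithm {algo!r}; choose from {MAPPING_ALGORITHMS}"
        )
    coords = world_to_voxel(mesh.vertices, volume)
    coords = np.atleast_2d(coords)
    idx = _nearest_index(coords)
    ok = _in_grid(idx, volume.shape)
    unmapped = ~ok
    grid = volume.grid
    values = np.zeros(mesh.n_vertices)

    if algo in ("nearest_voxel", "average_vertex"):
        values[ok] = grid[tuple(idx[ok].T)]
        if algo == "average_vertex":
            nbrs = mesh.vertex_neighbors()
            smoothed = values.copy()
            for v in range(mesh.n_vertices):
                if unmapped[v]:
                    continue
                ring = [u for u in nbrs[v] if not unmapped[u]] + [v]
                smoothed[v] = values[ring].sum() / len(ring)
            values = smoothed
    elif algo == "average_voxel":
        values = _block_reduce(grid, idx, ok, lambda b: float(b.mean()))
    elif algo == "maximum_voxel":
        values = _block_reduce(grid, idx, ok, lambda b: float(b.max()))
    elif algo == "minimum_voxel":
        values = _block_reduce(grid, idx, ok, lambda b: float(b.min()))
    elif algo == "extremum_voxel":
        values = _block_reduce(grid, idx, ok, _extremum)
    elif algo == "gaussian":
        if sigma < 0:
            raise ParameterError("gaussian sigma must be non-negative")
        smoothed = ndimage.gaussian_filter(grid, sigma=sigma, truncate=2.0) if sigma > 0 else grid
        values[ok] = smoothed[tuple(idx[ok].T)]
    elif algo == "interpolated":
        # trilinear sampling at the continuous coordinate; clamp at borders
        vals = ndimage.map_coordinates(grid, coords.T, order=1, mode="nearest")
        values[ok] = vals[ok]
    return VertexValues(values, unmapped)


# ---------------------------------------------------------------------------
# sign filter
# ---------------------------------------------------------------------------

def apply_sign_filter(values: VertexValues, sign_filter: str = "both") -> VertexValues:
    """Keep only positive / only negative values, or pass through (``both``).

    Filtered-out vertices get value 0 and join the unmapped set, so they fall
    back to the surface base color.
    """
    if sign_filter == "both":
        return VertexValues(values.values.copy(), values.unmapped.copy())
    if sign_filter not in ("positive", "negative"):
        raise ParameterError(f"unknown sign filter {sign_filter!r}")
    v = values.values.copy()
    drop = (v < 0) if sign_filter == "positive" else (v > 0)
    v[drop] = 0.0
    return VertexValues(v, values.unmapped | drop)


# ---------------------------------------------------------------------------
# colormaps
# ---------------------------------------------------------------------------

def _sampled(name: str, n: int = 256) -> np.ndarray:
    cm = _mpl_colormaps[name]
    return np.asarray([cm(i / (n - 1))[:3] for i in range(n)], dtype=float)


def _cold(n: int = 256) -> np.ndarray:
    """Blue-to-cyan ramp ('cold' has no universal definition; this is ours)."""
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.zeros(n), t, np.ones(n)])


#: the 24 built-in colorbar presets (name -> n x 3 RGB rows in [0, 1])
COLORMAP_PRESETS: dict[str, np.ndarray] = {
    **{name: _sampled(name) for name in (
        "jet", "hsv", "hot", "winter", "summer", "spring", "autumn", "cool",
        "bone", "copper", "pink", "gray", "viridis", "plasma", "inferno",
        "magma", "cividis", "coolwarm", "RdBu", "PiYG", "Spectral", "YlOrRd",
        "GnBu",
    )},
    "cold": _cold(),
}
assert len(COLORMAP_PRESETS) == 24


def colormap_names() -> tuple[str, ...]:
    """Names of the built-in colorbar presets."""
    return tuple(COLORMAP_PRESETS)


@dataclass
class ColormapSpec:
    """A named preset or a custom n x 3 RGB table, plus range and sign filter."""

    name: Optional[str] = "jet"
    custom: Optional[np.ndarray] = None
    sign_filter: str = "both"
    display_range: Optional[tuple[float, float]] = None  # None = autoscale

    def table(self) -> np.ndarray:
        if self.custom is not None:
            tab = np.asarray(self.custom, dtype=float).reshape(-1, 3)
            if len(tab) < 2:
                raise ParameterError("custom colormap needs at least 2 RGB rows")
            return tab
        if self.name not in COLORMAP_PRESETS:
            raise ParameterError(
                f"unknown colormap {self.name!r}; presets: {sorted(COLORMAP_PRESETS)}"
            )
        return COLORMAP_PRESETS[self.name]


def read_custom_colormap(path) -> np.ndarray:
    """ASCII n x 3 rows of RGB values in [0, 1]."""
    tab = np.loadtxt(path, ndmin=2)
    if tab.ndim != 2 or tab.shape[1] != 3 or len(tab) < 2:
        raise ParameterError(f"{path}: custom colormap must be an n x 3 table, n >= 2")
    if tab.min() < 0 or tab.max() > 1:
        raise ParameterError(f"{path}: colormap entries must lie in [0, 1]")
    return tab


def colorize(
    values: VertexValues,
    spec: ColormapSpec,
    base_color=(0.75, 0.75, 0.75),
) -> np.ndarray:
    """RGB per vertex: clamp to the display range, map linearly through the
    color table with piecewise-linear interpolation between rows. Unmapped
    vertices get the surface base color."""
    tab = spec.table()
    v = values.values
    mapped = ~values.unmapped
    if spec.display_range is not None:
        lo, hi = spec.display_range
        if not lo < hi:
            raise ParameterError("display range must satisfy lo < hi")
    elif mapped.any():
        lo, hi = float(v[mapped].min()), float(v[mapped].max())
        if hi - lo < 1e-300:
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = 0.0, 1.0
    t = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    pos = t * (len(tab) - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, len(tab) - 1)
    frac = (pos - i0)[:, None]
    rgb = tab[i0] * (1 - frac) + tab[i1] * frac
    rgb[values.unmapped] = np.asarray(base_color, dtype=float)
    return rgb


# ---------------------------------------------------------------------------
# ROI isosurfaces
# ---------------------------------------------------------------------------

def roi_cluster_mesh(
    volume: VolumeImage, index: int, smoothing: str = "none"
) -> SurfaceMesh:
    """Triangulated boundary of the voxels labeled ``index``.

    The binary mask (grid == index) is zero-padded, an isosurface is taken
    at level 0.5 in voxel space, and the vertices are pushed through the
    affine into world coordinates. An absent label yields an empty mesh.
    ``smoothing='light'`` applies one pass of Laplacian vertex averaging.
    """
    from skimage import measure

    grid = volume.grid
    if not np.allclose(grid, np.round(grid)):
        raise ValidationError(
            "ROI construction needs an integer-labeled volume; round it first"
        )
    if smoothing not in ("none", "light"):
        raise ParameterError(f"unknown smoothing {smoothing!r}; use none or light")
    mask = (np.round(grid).astype(int) == int(index)).astype(float)
    if not mask.any():
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    padded = np.pad(mask, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset
    if smoothing == "light":
        tmp = SurfaceMesh(verts, faces)
        nbrs = tmp.vertex_neighbors()
        sm = verts.copy()
        for i, ring in enumerate(nbrs):
            if ring:
                sm[i] = (verts[list(ring)].sum(axis=0) + verts[i]) / (len(ring) + 1)
        verts = sm
    world = voxel_to_world(verts, volume)
    return SurfaceMesh(world, faces)
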