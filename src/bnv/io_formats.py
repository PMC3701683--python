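"""Readers, writers and validators for the tool's file formats.

On-disk conventions
-------------------
``.nv`` surface
    ASCII. Line 1: vertex count. Next ``nVertices`` lines: ``x y z`` in mm.
    Next line: face count. Next ``nFaces`` lines: ``i j k`` triangle vertex
    indices, **1-based** on disk. In memory faces are **0-based** numpy
    arrays; this is the single conversion point.
``.node``
    6 whitespace-separated columns per node: ``x y z color size label``.
    A ``-`` in column 6 means the node has no label.
``.edge``
    An N x N whitespace-separated real matrix (association/adjacency
    weights). The diagonal is carried but ignored downstream.
Volumes
    NIfTI-1 (``.nii``) or Analyze 7.5 (``.img``/``.hdr``) via nibabel.

Blank lines and lines starting with ``#`` are ignored in all ASCII formats.
Both the ASCII hyphen and the typographic minus sign are accepted as the
no-label sentinel; the hyphen is what we write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ClassificationError,
    CombinationError,
    FormatError,
    UnsupportedInputError,
    ValidationError,
)

#: tolerance factor for deciding a matrix is symmetric (text round-trip noise)
SYMMETRY_RTOL = 1e-8

_NO_LABEL_SENTINELS = {"-", "−", "–"}  # hyphen, minus sign, en dash


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface in world (mm) coordinates.

    ``vertices`` is (n, 3) float; ``faces`` is (m, 3) int, 0-based.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("surface vertices contain non-finite coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError(
                    f"face index out of range: valid range is [0, {len(self.vertices) - 1}]"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def vertex_neighbors(self) -> list[set[int]]:
        """1-ring adjacency: for each vertex, the set of vertices sharing an edge."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.faces:
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        return nbrs


@dataclass
class NodeSet:
    """Per-node coordinates plus the color/size/label columns of a node table."""

    coords: np.ndarray            # (n, 3) mm
    color_value: np.ndarray       # (n,) column 4
    size_value: np.ndarray        # (n,) column 5
    labels: list[Optional[str]]   # column 6; None = unlabeled

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.color_value = np.asarray(self.color_value, dtype=float).ravel()
        self.size_value = np.asarray(self.size_value, dtype=float).ravel()
        n = len(self.coords)
        if not (len(self.color_value) == len(self.size_value) == len(self.labels) == n):
            raise ValidationError("node fields have unequal lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("node coordinates contain non-finite values")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class EdgeMatrix:
    """Square association matrix; symmetry is detected, not assumed."""

    weights: np.ndarray
    symmetric: bool = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"edge matrix must be square, got shape {w.shape}")
        self.weights = w
        scale = max(1.0, float(np.abs(w).max()) if w.size else 1.0)
        self.symmetric = bool(np.abs(w - w.T).max() <= SYMMETRY_RTOL * scale) if w.size else True

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class VolumeImage:
    """3-D scalar grid plus an invertible voxel-index -> world(mm) affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValidationError(f"volume grid must be 3-D, got shape {self.grid.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("volume affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]


@dataclass
class VertexValues:
    """One scalar per surface vertex, plus a mask of vertices that got no value."""

    values: np.ndarray
    unmapped: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.unmapped is None:
            self.unmapped = np.zeros(len(self.values), dtype=bool)
        else:
            self.unmapped = np.asarray(self.unmapped, dtype=bool).ravel()
        if len(self.unmapped) != len(self.values):
            raise ValidationError("unmapped mask length differs from value length")

    def __len__(self) -> int:
        return len(self.values)


class FileKind(str, Enum):
    SURFACE = "surface"
    NODE = "node"
    EDGE = "edge"
    VOLUME = "volume"
    VERTEX_VECTOR = "vertex_vector"
    CONFIG = "config"
    IMAGE_OUT = "image_out"
    VIDEO_OUT = "video_out"


_SUFFIX_KIND = {
    ".nv": FileKind.SURFACE,
    ".node": FileKind.NODE,
    ".edge": FileKind.EDGE,
    ".nii": FileKind.VOLUME,
    ".img": FileKind.VOLUME,
    ".hdr": FileKind.VOLUME,
    ".gz": FileKind.VOLUME,  # .nii.gz convenience
    ".txt": FileKind.VERTEX_VECTOR,
    ".yaml": FileKind.CONFIG,
    ".yml": FileKind.CONFIG,
    ".png": FileKind.IMAGE_OUT,
    ".tif": FileKind.IMAGE_OUT,
    ".tiff": FileKind.IMAGE_OUT,
    ".bmp": FileKind.IMAGE_OUT,
    ".jpg": FileKind.IMAGE_OUT,
    ".jpeg": FileKind.IMAGE_OUT,
    ".eps": FileKind.IMAGE_OUT,
    ".avi": FileKind.VIDEO_OUT,
    ".mp4": FileKind.VIDEO_OUT,
    ".gif": FileKind.VIDEO_OUT,
}

#: The accepted input-file combinations. Loading any other subset of
#: {surface, node, edge, volume} is an error.
VALID_COMBINATIONS: tuple[frozenset[FileKind], ...] = (
    frozenset({FileKind.SURFACE}),
    frozenset({FileKind.NODE}),
    frozenset({FileKind.SURFACE, FileKind.NODE}),
    frozenset({FileKind.NODE, FileKind.EDGE}),
    frozenset({FileKind.SURFACE, FileKind.NODE, FileKind.EDGE}),
    frozenset({FileKind.SURFACE, FileKind.VOLUME}),
    frozenset({FileKind.SURFACE, FileKind.NODE, FileKind.VOLUME}),
    frozenset({FileKind.SURFACE, FileKind.NODE, FileKind.EDGE, FileKind.VOLUME}),
)


# ---------------------------------------------------------------------------
# ASCII helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-blank, non-comment lines with their 1-based file line numbers."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            out.append((i, s))
    return out


def _parse_floats(path, lineno: int, text: str, expect: int) -> list[float]:
    parts = text.split()
    if len(parts) != expect:
        raise FormatError(
            f"{path}:{lineno}: expected {expect} fields, found {len(parts)}"
        )
    try:
        return [float(p) for p in parts]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None


# ---------------------------------------------------------------------------
# surface (.nv)
# ---------------------------------------------------------------------------

def read_surface_nv(path: str | Path) -> SurfaceMesh:
    """Read an ASCII ``.nv`` surface. Faces are converted to 0-based indices."""
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty surface file")
    pos = 0

    def take() -> tuple[int, str]:
        nonlocal pos
        if pos >= len(lines):
            raise FormatError(f"{path}: truncated file (ran out of lines)")
        item = lines[pos]
        pos += 1
        return item

    lineno, head = take()
    try:
        n_vert = int(float(head.split()[0]))
    except ValueError:
        raise FormatError(f"{path}:{lineno}: vertex count is not a number") from None
    verts = np.empty((n_vert, 3), dtype=float)
    for i in range(n_vert):
        lineno, text = take()
        verts[i] = _parse_floats(path, lineno, text, 3)

    lineno, head = take()
    try:
        n_face = int(float(head.split()[0]))
    except ValueError:
        raise FormatError(f"{path}:{lineno}: face count is not a number") from None
    faces = np.empty((n_face, 3), dtype=int)
    for i in range(n_face):
        lineno, text = take()
        vals = _parse_floats(path, lineno, text, 3)
        faces[i] = [int(v) - 1 for v in vals]  # 1-based on disk
    if pos != len(lines):
        raise FormatError(
            f"{path}: {len(lines) - pos} unexpected trailing line(s); "
            f"header declared {n_vert} vertices and {n_face} faces"
        )
    try:
        return SurfaceMesh(verts, faces)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_surface_nv(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a surface as ASCII ``.nv`` (faces re-encoded 1-based)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{mesh.n_vertices}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        fh.write(f"{mesh.n_faces}\n")
        for a, b, c in mesh.faces:
            fh.write(f"{a + 1} {b + 1} {c + 1}\n")


# ---------------------------------------------------------------------------
# nodes (.node)
# ---------------------------------------------------------------------------

def read_node_file(path: str | Path) -> NodeSet:
    coords, colors, sizes, labels = [], [], [], []
    for lineno, text in _data_lines(path):
        parts = text.split()
        if len(parts) != 6:
            raise FormatError(
                f"{path}:{lineno}: node lines need 6 columns, found {len(parts)}"
            )
        nums = _parse_floats(path, lineno, " ".join(parts[:5]), 5)
        coords.append(nums[:3])
        colors.append(nums[3])
        sizes.append(nums[4])
        labels.append(None if parts[5] in _NO_LABEL_SENTINELS else parts[5])
    return NodeSet(
        np.asarray(coords, dtype=float).reshape(-1, 3),
        np.asarray(colors, dtype=float),
        np.asarray(sizes, dtype=float),
        labels,
    )


def write_node_file(nodes: NodeSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (x, y, z), c, s, lab in zip(
            nodes.coords, nodes.color_value, nodes.size_value, nodes.labels
        ):
            fh.write(f"{x:.6f}\t{y:.6f}\t{z:.6f}\t{c:.6f}\t{s:.6f}\t{lab or '-'}\n")


# ---------------------------------------------------------------------------
# edges (.edge)
# ---------------------------------------------------------------------------

def read_edge_file(path: str | Path) -> EdgeMatrix:
    rows = []
    width = None
    for lineno, text in _data_lines(path):
        parts = text.split()
        if width is None:
            width = len(parts)
        elif len(parts) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
            )
        rows.append(_parse_floats(path, lineno, text, len(parts)))
    if not rows:
        raise FormatError(f"{path}: empty edge file")
    mat = np.asarray(rows, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(
            f"{path}: edge matrix must be square, got {mat.shape[0]}x{mat.shape[1]}"
        )
    return EdgeMatrix(mat)


def write_edge_file(matrix: EdgeMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.weights, fmt="%.8g", delimiter="\t")


# ---------------------------------------------------------------------------
# volumes and vertex vectors
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeImage:
    """Load a NIfTI or Analyze volume. Singleton trailing dims are squeezed;
    genuine 4-D time series are rejected."""
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot read as NIfTI/Analyze ({exc})") from None
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim > 3:
        raise UnsupportedInputError(
            f"{path}: {data.ndim}-D volume with {data.shape[3]} time points; "
            "only single 3-D volumes are supported"
        )
    if data.ndim < 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeImage(np.asarray(data, dtype=float), np.asarray(img.affine))


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    import nibabel as nib

    nib.Nifti1Image(volume.grid.astype(np.float64), volume.affine).to_filename(str(path))


def read_vertex_vector(path: str | Path, mesh: SurfaceMesh) -> VertexValues:
    """Read an n x 1 text vector of per-vertex scalars for ``mesh``."""
    vals = [_parse_floats(path, lineno, text, 1)[0] for lineno, text in _data_lines(path)]
    if len(vals) != mesh.n_vertices:
        raise ValidationError(
            f"{path}: vector has {len(vals)} values but the surface has "
            f"{mesh.n_vertices} vertices"
        )
    return VertexValues(np.asarray(vals))


# ---------------------------------------------------------------------------
# classification and combination validation
# ---------------------------------------------------------------------------

def detect_file_kind(path: str | Path) -> FileKind:
    """Classify a path by suffix (``x.nii.gz`` counts as a volume)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".gz":
        inner = Path(p.stem).suffix.lower()
        if inner == ".nii":
            return FileKind.VOLUME
        raise ClassificationError(
            f"{path}: unsupported compressed suffix '{inner}.gz'"
        )
    kind = _SUFFIX_KIND.get(suffix)
    if kind is None:
        supported = ", ".join(sorted(k for k in _SUFFIX_KIND if k != ".gz"))
        raise ClassificationError(
            f"{path}: unknown suffix '{suffix}'; supported: {supported}"
        )
    return kind


def validate_combination(kinds: Sequence[FileKind] | set[FileKind]) -> frozenset[FileKind]:
    """Check that a set of input kinds is one of the accepted combinations.

    Returns the normalized frozenset on success; raises
    :class:`CombinationError` otherwise. For ``{surface, volume}`` whether
    the volume is surface-mapped or drawn as ROI clusters is a configuration
    choice, not a different combination.
    """
    ks = frozenset(kinds)
    extra = ks - {FileKind.SURFACE, FileKind.NODE, FileKind.EDGE, FileKind.VOLUME}
    if extra:
        raise CombinationError(f"non-drawable kinds in combination: {sorted(k.value for k in extra)}")
    if ks not in VALID_COMBINATIONS:
        valid = "; ".join(
            "{" + ", ".join(sorted(k.value for k in c)) + "}" for c in VALID_COMBINATIONS
        )
        raise CombinationError(
            "invalid input combination {"
            + ", ".join(sorted(k.value for k in ks))
            + "}; accepted: "
            + valid
        )
    return ks


def is_valid_combination(kinds) -> bool:
    try:
        validate_combination(kinds)
        return True
    except CombinationError:
        return False
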