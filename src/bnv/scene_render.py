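"""Scene assembly and offscreen export.

A :class:`Scene` is a renderer-independent inventory: an ordered list of
panels, each a named camera (azimuth/elevation) plus the drawable meshes
assigned to it. Rendering is done offscreen with matplotlib's 3-D backend;
the Scene itself never depends on the backend, so layout logic can be
tested without producing pixels.

Camera conventions (the views are named, the angles are ours):

========== ======================= =====================
panel      looks along              (azim, elev) degrees
========== ======================= =====================
left       -x (left lateral)        (180, 0)
right      +x (right lateral)       (0, 0)
dorsal     -z from above            (-90, 90)
ventral    +z from below            (-90, -90)
anterior   -y from the front        (90, 0)
posterior  +y from behind           (-90, 0)
========== ======================= =====================

Medial views look from the midline outward (left-medial shares the right
camera and vice versa, with the opposite hemisphere's meshes removed).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, LayoutError, ParameterError
from .geometry import DetailLevel, arrow_mesh, cylinder_mesh, sphere_mesh
from .io_formats import SurfaceMesh
from .network_style import StyledEdge, StyledNode

RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")
VECTOR_SUFFIXES = (".eps",)
VIDEO_SUFFIXES = (".gif", ".avi", ".mp4")

#: defaults reproducing the standard rotation video: 360 frames at 30 FPS
#: (12 s) with 735 x 534 pixel frames, one degree of azimuth per frame.
VIDEO_DEFAULT_FPS = 30
VIDEO_DEFAULT_DEGREES_PER_FRAME = 1.0
VIDEO_DEFAULT_SIZE = (735, 534)

_NAMED_VIEWS = {
    "left": (180.0, 0.0),
    "right": (0.0, 0.0),
    "dorsal": (-90.0, 90.0),
    "ventral": (-90.0, -90.0),
    "anterior": (90.0, 0.0),
    "posterior": (-90.0, 0.0),
    # single-view shortcuts
    "sagittal": (180.0, 0.0),
    "axial": (-90.0, 90.0),
    "coronal": (90.0, 0.0),
}

MATERIALS = ("shiny", "dull", "metal")
SHADINGS = ("flat", "faceted", "interp")
LIGHTINGS = ("flat", "gouraud", "phong")
LIGHT_DIRECTIONS = ("headlight", "right", "left")
LAYOUTS = ("single", "medium", "full")

#: named material/lighting options -> distinct, deterministic shading
#: parameters (ambient, diffuse, specular weights). Contract-level mapping:
#: each option is distinct; photometric identity with any other renderer is
#: not a goal.
MATERIAL_PARAMS = {
    "shiny": {"ambient": 0.3, "diffuse": 0.6, "specular": 0.9},
    "dull": {"ambient": 0.4, "diffuse": 0.8, "specular": 0.0},
    "metal": {"ambient": 0.25, "diffuse": 0.3, "specular": 1.0},
}
LIGHT_DIRECTION_VECTORS = {
    "headlight": None,  # follows the camera
    "right": (1.0, 0.0, 0.5),
    "left": (-1.0, 0.0, 0.5),
}


@dataclass
class DisplayConfig:
    """Global display properties: layout, appearance, detail and image size."""

    layout: str = "full"
    single_view: str | tuple[float, float] = "sagittal"
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    surface_color: tuple[float, float, float] = (0.75, 0.75, 0.75)
    surface_opacity: float = 1.0
    material: str = "shiny"
    shading: str = "interp"
    lighting: str = "phong"
    light_direction: str = "headlight"
    detail: DetailLevel = DetailLevel.MODERATE
    width_px: int = 800
    height_px: int = 600
    dpi: int = 100
    fallback_nondivisible: bool = False  # medium on a non-divisible surface

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ParameterError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")
        if self.material not in MATERIALS:
            raise ParameterError(f"material must be one of {MATERIALS}")
        if self.shading not in SHADINGS:
            raise ParameterError(f"shading must be one of {SHADINGS}")
        if self.lighting not in LIGHTINGS:
            raise ParameterError(f"lighting must be one of {LIGHTINGS}")
        if self.light_direction not in LIGHT_DIRECTIONS:
            raise ParameterError(f"light_direction must be one of {LIGHT_DIRECTIONS}")
        if not 0.0 <= self.surface_opacity <= 1.0:
            raise ParameterError("surface opacity must lie in [0, 1]")
        if isinstance(self.detail, str):
            self.detail = DetailLevel(self.detail)

    @classmethod
    def with_physical_size(
        cls, width: float, height: float, unit: str = "inch", dpi: int = 100, **kw
    ) -> "DisplayConfig":
        """Specify the image in physical units; px = inches * DPI."""
        if unit == "cm":
            width, height = width / 2.54, height / 2.54
        elif unit != "inch":
            raise ParameterError(f"unit must be 'inch' or 'cm', got {unit!r}")
        return cls(width_px=round(width * dpi), height_px=round(height * dpi), dpi=dpi, **kw)


@dataclass
class Drawable:
    """One mesh ready to draw: geometry plus flat or per-vertex color."""

    vertices: np.ndarray
    faces: np.ndarray
    color: np.ndarray          # (3,) flat or (n_vertices, 3) per-vertex
    opacity: float = 1.0
    kind: str = "surface"      # surface | node | edge | roi

    def transformed(self, offset=None) -> "Drawable":
        if offset is None:
            return self
        return replace(self, vertices=self.vertices + np.asarray(offset, dtype=float))


@dataclass
class Panel:
    name: str
    azim: float
    elev: float
    drawables: list[Drawable] = field(default_factory=list)


@dataclass
class Scene:
    panels: list[Panel]
    config: DisplayConfig

    def inventory(self) -> list[tuple[str, float, float, list[tuple[str, int, int]]]]:
        """Backend-independent summary: per panel, (name, azim, elev,
        [(kind, n_vertices, n_faces), ...]). Byte-identical for equal scenes."""
        return [
            (
                p.name,
                p.azim,
                p.elev,
                [(d.kind, len(d.vertices), len(d.faces)) for d in p.drawables],
            )
            for p in self.panels
        ]


# ---------------------------------------------------------------------------
# hemisphere partition
# ---------------------------------------------------------------------------

def is_hemisphere_divisible(mesh: SurfaceMesh) -> tuple[bool, np.ndarray, np.ndarray]:
    """Whether the surface splits cleanly at the midsagittal plane (x = 0).

    Divisible iff no face mixes strictly-negative-x and strictly-positive-x
    vertices. Returns (divisible, left_face_mask, right_face_mask); faces
    are assigned by centroid x sign (centroid at exactly 0 goes left).
    An empty mesh is vacuously divisible.
    """
    if mesh.n_faces == 0:
        empty = np.zeros(0, dtype=bool)
        return True, empty, empty
    x = mesh.vertices[:, 0]
    fx = x[mesh.faces]                       # (m, 3)
    mixes = np.any(fx < 0, axis=1) & np.any(fx > 0, axis=1)
    divisible = not bool(mixes.any())
    cx = fx.mean(axis=1)
    left = cx <= 0
    return divisible, left, ~left


def _submesh(mesh: SurfaceMesh, face_mask: np.ndarray) -> SurfaceMesh:
    faces = mesh.faces[face_mask]
    return SurfaceMesh(mesh.vertices, faces)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _glyph_drawables(
    nodes: Optional[Sequence[StyledNode]],
    edges: Optional[Sequence[StyledEdge]],
    detail: DetailLevel,
) -> list[Drawable]:
    out: list[Drawable] = []
    if nodes:
        for nd in nodes:
            if not nd.visible:
                continue
            g = sphere_mesh(nd.center, nd.radius, detail.node_n)
            out.append(Drawable(g.vertices, g.faces, np.asarray(nd.color, float), kind="node"))
    if edges and nodes:
        for e in edges:
            i, j = e.endpoints
            a, b = nodes[i].center, nodes[j].center
            builder = arrow_mesh if e.directed else cylinder_mesh
            g = builder(a, b, max(e.radius, 1e-6), detail.edge_n)
            out.append(Drawable(g.vertices, g.faces, np.asarray(e.color, float), kind="edge"))
    return out


def _side_of(points: np.ndarray) -> np.ndarray:
    """-1 left, +1 right, by x sign (0 counts as left for panel assignment)."""
    return np.where(points[:, 0] > 0, 1, -1)


def build_scene(
    surface: Optional[SurfaceMesh] = None,
    nodes: Optional[Sequence[StyledNode]] = None,
    edges: Optional[Sequence[StyledEdge]] = None,
    vertex_colors: Optional[np.ndarray] = None,
    roi_meshes: Optional[Sequence[SurfaceMesh]] = None,
    config: Optional[DisplayConfig] = None,
) -> Scene:
    """Assemble panels per the layout rules.

    single -> 1 panel; medium -> 4 (lateral + medial per hemisphere, needs a
    divisible surface unless ``fallback_nondivisible``); full -> 6 panels on
    a non-divisible surface (left, right, dorsal, ventral, anterior,
    posterior) or 8 on a divisible one (per-hemisphere lateral and medial
    plus dorsal, ventral, anterior, posterior). Node and edge glyphs are
    assigned to hemisphere panels by x sign; whole-brain panels get
    everything.
    """
    config = config or DisplayConfig()
    if surface is None and not nodes and not roi_meshes:
        raise ParameterError("scene needs at least one drawable element")

    surf_drawable = None
    if surface is not None:
        color: np.ndarray
        if vertex_colors is not None:
            color = np.asarray(vertex_colors, dtype=float)
            if len(color) != surface.n_vertices:
                raise ParameterError("vertex color count differs from vertex count")
        else:
            color = np.asarray(config.surface_color, dtype=float)
        surf_drawable = Drawable(
            surface.vertices, surface.faces, color, config.surface_opacity, "surface"
        )

    glyphs = _glyph_drawables(nodes, edges, config.detail)
    rois = [
        Drawable(m.vertices, m.faces, np.asarray((0.9, 0.3, 0.3)), 1.0, "roi")
        for m in (roi_meshes or [])
        if m.n_faces > 0
    ]
    everything = ([surf_drawable] if surf_drawable else []) + rois + glyphs

    if config.layout == "single":
        if isinstance(config.single_view, str):
            if config.single_view not in _NAMED_VIEWS:
                raise ParameterError(
                    f"unknown view {config.single_view!r}; named views: {sorted(_NAMED_VIEWS)}"
                )
            azim, elev = _NAMED_VIEWS[config.single_view]
            name = config.single_view
        else:
            azim, elev = config.single_view
            name = "custom"
        return Scene([Panel(name, azim, elev, everything)], config)

    divisible, left_faces, right_faces = (
        is_hemisphere_divisible(surface) if surface is not None else (True, None, None)
    )

    def hemi_drawables(side: int) -> list[Drawable]:
        """Drawables for one hemisphere: its surface faces + its glyphs."""
        items: list[Drawable] = []
        if surf_drawable is not None and left_faces is not None:
            mask = left_faces if side < 0 else right_faces
            sub = _submesh(SurfaceMesh(surf_drawable.vertices, surf_drawable.faces), mask)
            items.append(replace(surf_drawable, vertices=sub.vertices, faces=sub.faces))
        elif surf_drawable is not None:
            items.append(surf_drawable)
        for d in rois + glyphs:
            centroid = d.vertices.mean(axis=0) if len(d.vertices) else np.zeros(3)
            if (centroid[0] > 0) == (side > 0) or centroid[0] == 0:
                items.append(d)
        return items

    if config.layout == "medium":
        if surface is not None and not divisible and not config.fallback_nondivisible:
            raise LayoutError(
                "medium layout needs a hemisphere-divisible surface "
                "(set fallback_nondivisible to draw the whole brain in each panel)"
            )
        use_hemi = surface is None or divisible
        L = hemi_drawables(-1) if use_hemi else everything
        R = hemi_drawables(+1) if use_hemi else everything
        panels = [
            Panel("left_lateral", *_NAMED_VIEWS["left"], L),
            Panel("left_medial", *_NAMED_VIEWS["right"], L),
            Panel("right_lateral", *_NAMED_VIEWS["right"], R),
            Panel("right_medial", *_NAMED_VIEWS["left"], R),
        ]
        return Scene(panels, config)

    # full layout
    whole = [
        Panel("dorsal", *_NAMED_VIEWS["dorsal"], everything),
        Panel("ventral", *_NAMED_VIEWS["ventral"], everything),
        Panel("anterior", *_NAMED_VIEWS["anterior"], everything),
        Panel("posterior", *_NAMED_VIEWS["posterior"], everything),
    ]
    if surface is not None and not divisible:
        panels = [
            Panel("left", *_NAMED_VIEWS["left"], everything),
            Panel("right", *_NAMED_VIEWS["right"], everything),
        ] + whole
    else:
        L, R = hemi_drawables(-1), hemi_drawables(+1)
        panels = [
            Panel("left_lateral", *_NAMED_VIEWS["left"], L),
            Panel("left_medial", *_NAMED_VIEWS["right"], L),
            Panel("right_lateral", *_NAMED_VIEWS["right"], R),
            Panel("right_medial", *_NAMED_VIEWS["left"], R),
        ] + whole
    return Scene(panels, config)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _panel_grid(n: int) -> tuple[int, int]:
    return {1: (1, 1), 4: (2, 2), 6: (2, 3), 8: (2, 4)}.get(n, (1, max(n, 1)))


def _draw_panel(ax, panel: Panel, config: DisplayConfig) -> None:
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    mat = MATERIAL_PARAMS[config.material]
    all_pts = []
    for d in panel.drawables:
        if len(d.faces) == 0:
            continue
        tris = d.vertices[d.faces]
        coll = Poly3DCollection(tris, alpha=d.opacity)
        if d.color.ndim == 2:
            coll.set_facecolor(d.color[d.faces].mean(axis=1))
        else:
            coll.set_facecolor(np.clip(d.color * (mat["ambient"] + mat["diffuse"]), 0, 1))
        if config.shading == "faceted":
            coll.set_edgecolor("k")
            coll.set_linewidth(0.1)
        else:
            coll.set_edgecolor("none")
        ax.add_collection3d(coll)
        all_pts.append(d.vertices)
    if all_pts:
        pts = np.vstack(all_pts)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        c = (lo + hi) / 2
        half = float((hi - lo).max()) / 2 or 1.0
        ax.set_xlim(c[0] - half, c[0] + half)
        ax.set_ylim(c[1] - half, c[1] + half)
        ax.set_zlim(c[2] - half, c[2] + half)
    ax.view_init(elev=panel.elev, azim=panel.azim)
    ax.set_axis_off()
    ax.set_box_aspect((1, 1, 1))


def _render_figure(scene: Scene, width_px: int, height_px: int, dpi: int):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(width_px / dpi, height_px / dpi), dpi=dpi)
    fig.patch.set_facecolor(scene.config.background)
    rows, cols = _panel_grid(len(scene.panels))
    for k, panel in enumerate(scene.panels, start=1):
        ax = fig.add_subplot(rows, cols, k, projection="3d")
        ax.set_facecolor(scene.config.background)
        _draw_panel(ax, panel, scene.config)
    fig.subplots_adjust(left=0, right=1, bottom=0, top=1, wspace=0, hspace=0)
    return fig


def _figure_to_array(fig) -> np.ndarray:
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())
    return buf[..., :3].copy()


def render_image(scene: Scene, path, config: Optional[DisplayConfig] = None) -> str:
    """Render the scene offscreen and write it at exactly the requested pixel
    dimensions. Rasters go through an RGB buffer (so every raster format the
    Pillow side supports works); EPS is written by the vector backend with
    the 3-D content rasterized into the container."""
    config = config or scene.config
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix not in RASTER_SUFFIXES + VECTOR_SUFFIXES:
        raise FormatError(
            f"unsupported image suffix {suffix!r}; "
            f"supported: {', '.join(RASTER_SUFFIXES + VECTOR_SUFFIXES)}"
        )
    import matplotlib.pyplot as plt

    fig = _render_figure(scene, config.width_px, config.height_px, config.dpi)
    try:
        if suffix in VECTOR_SUFFIXES:
            fig.savefig(str(path), format="eps", dpi=config.dpi)
        else:
            from PIL import Image

            arr = _figure_to_array(fig)
            if arr.shape[:2] != (config.height_px, config.width_px):
                img = Image.fromarray(arr).resize((config.width_px, config.height_px))
            else:
                img = Image.fromarray(arr)
            img.save(str(path), dpi=(config.dpi, config.dpi))
    finally:
        plt.close(fig)
    return str(path)


def video_plan(
    fps: int = VIDEO_DEFAULT_FPS,
    degrees_per_frame: float = VIDEO_DEFAULT_DEGREES_PER_FRAME,
) -> tuple[int, float]:
    """(frame count, duration in seconds) of one full 360-degree rotation."""
    if fps <= 0:
        raise ParameterError("fps must be positive")
    if degrees_per_frame <= 0 or not math.isclose(
        360 / degrees_per_frame, round(360 / degrees_per_frame)
    ):
        raise ParameterError(
            f"degrees_per_frame must divide 360, got {degrees_per_frame}"
        )
    n_frames = round(360 / degrees_per_frame)
    return n_frames, n_frames / fps


def render_video(
    scene: Scene,
    path,
    fps: int = VIDEO_DEFAULT_FPS,
    degrees_per_frame: float = VIDEO_DEFAULT_DEGREES_PER_FRAME,
    size: tuple[int, int] = VIDEO_DEFAULT_SIZE,
) -> str:
    """One full clockwise azimuthal rotation of a single-panel scene.

    Defaults give 360 frames at 30 FPS (a 12 s video) with 735 x 534 frames.
    ``.gif`` is always writable; ``.avi``/``.mp4`` need an ffmpeg-backed
    imageio plugin and raise a clear error when none is present.
    """
    import imageio.v2 as imageio
    import matplotlib.pyplot as plt
    from PIL import Image

    if len(scene.panels) != 1:
        raise ParameterError("rotation video needs a single-panel scene")
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix not in VIDEO_SUFFIXES:
        raise FormatError(
            f"unsupported video suffix {suffix!r}; supported: {', '.join(VIDEO_SUFFIXES)}"
        )
    n_frames, _ = video_plan(fps, degrees_per_frame)
    width, height = size
    base = scene.panels[0]
    frames = []
    for k in range(n_frames):
        azim = base.azim - k * degrees_per_frame  # clockwise seen from above
        panel = Panel(base.name, azim, base.elev, base.drawables)
        fig = _render_figure(Scene([panel], scene.config), width, height, scene.config.dpi)
        try:
            arr = _figure_to_array(fig)
        finally:
            plt.close(fig)
        if arr.shape[:2] != (height, width):
            arr = np.asarray(Image.fromarray(arr).resize((width, height)))
        frames.append(arr)
    if suffix == ".gif":
        imageio.mimwrite(str(path), frames, duration=1000.0 / fps, loop=0)
    else:
        try:
            writer = imageio.get_writer(str(path), fps=fps)
        except Exception as exc:
            raise FormatError(
                f"cannot write {suffix} (no ffmpeg backend available: {exc}); "
                "use .gif instead"
            ) from None
        with writer:
            for frame in frames:
                writer.append_data(frame)
    return str(path)
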