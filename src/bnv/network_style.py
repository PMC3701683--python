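"""Node/edge styling: selection, sizing, coloring, edge extraction, and the
nodal-strength (FCS) hub statistic.

Conventions adopted where the interface leaves room:

* every "higher than threshold" rule is a strict ``>``;
* hemisphere membership is the sign of the world x coordinate (x < 0 is the
  left hemisphere, the MNI convention); nodes at exactly x = 0 belong to
  both hemispheres and therefore never satisfy "crossing";
* the sparsity edge count is k = round(s * N(N-1)/2) with round-half-up,
  ties at the k-th weight broken by (smaller i, then smaller j);
* when both absolute-value and sparsity options are on, the absolute value
  is applied first and the top-k is taken over |w|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from matplotlib import colormaps as _mpl_colormaps

from .errors import ParameterError, ValidationError
from .io_formats import EdgeMatrix, NodeSet

#: default "proper ranges" for automatic size scaling (mm)
DEFAULT_NODE_RADIUS_RANGE = (1.0, 5.0)
DEFAULT_EDGE_RADIUS_RANGE = (0.3, 1.5)

NODE_SIZE_MODES = ("auto", "raw", "equal")
NODE_COLOR_MODES = ("uniform", "colormap", "modular", "binarized")
EDGE_SIZE_MODES = ("auto", "raw", "equal")
EDGE_COLOR_MODES = (
    "uniform",
    "colormap",
    "binarized_weight",
    "binarized_distance",
    "node_linked",
)


@dataclass
class StyledNode:
    center: np.ndarray
    radius: float
    color: tuple[float, float, float]
    label: Optional[str]
    visible: bool = True


@dataclass
class StyledEdge:
    endpoints: tuple[int, int]
    weight: float
    radius: float = 0.0
    color: tuple[float, float, float] = (0.3, 0.3, 0.3)
    directed: bool = False


# ---------------------------------------------------------------------------
# node styling
# ---------------------------------------------------------------------------

def select_nodes(nodes: NodeSet, by: str = "all", threshold: float = 0.0) -> np.ndarray:
    """Visibility flags: a node is shown iff its value is strictly greater
    than the threshold (``by`` chooses column 4 or 5; ``all`` shows every node)."""
    if by == "all":
        return np.ones(len(nodes), dtype=bool)
    if by == "color_value":
        values = nodes.color_value
    elif by == "size_value":
        values = nodes.size_value
    else:
        raise ParameterError(f"unknown node selector {by!r}; use all/color_value/size_value")
    if not np.isfinite(threshold):
        raise ParameterError("node selection threshold must be finite")
    return values > threshold


def _affine_scale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-300:
        return np.full(len(values), 0.5 * (lo + hi))
    return lo + (values - vmin) * (hi - lo) / (vmax - vmin)


def scale_node_sizes(
    nodes: NodeSet,
    mode: str = "auto",
    equal_radius: float = 2.0,
    radius_range: tuple[float, float] = DEFAULT_NODE_RADIUS_RANGE,
) -> np.ndarray:
    """Sphere radii per node.

    ``auto`` maps the size column affinely onto ``radius_range`` (a constant
    column maps to the range midpoint); ``raw`` uses the column verbatim;
    ``equal`` ignores the column.
    """
    if mode not in NODE_SIZE_MODES:
        raise ParameterError(f"unknown node size mode {mode!r}")
    lo, hi = radius_range
    if not lo < hi:
        raise ParameterError(f"radius range must satisfy lo < hi, got {radius_range}")
    n = len(nodes)
    if mode == "equal":
        if equal_radius <= 0:
            raise ParameterError("equal radius must be positive")
        return np.full(n, float(equal_radius))
    if n == 0:
        return np.zeros(0)
    if mode == "raw":
        if np.any(nodes.size_value <= 0):
            raise ValidationError("raw size mode requires strictly positive size values")
        return nodes.size_value.astype(float).copy()
    return _affine_scale(nodes.size_value, lo, hi)


#: >=20 visually distinct colors for modular coloring (tab20 palette)
MODULAR_PALETTE: tuple[tuple[float, float, float], ...] = tuple(
    tuple(c[:3]) for c in _mpl_colormaps["tab20"].colors
)


def color_nodes(
    nodes: NodeSet,
    mode: str = "modular",
    uniform_color=(0.85, 0.2, 0.2),
    cmap: str = "jet",
    threshold: float = 0.0,
    low_color=(0.2, 0.4, 0.8),
    high_color=(0.85, 0.2, 0.2),
) -> np.ndarray:
    """RGB per node under one of the four node color modes.

    uniform: one color for all. colormap: color column mapped through a
    named colormap over its observed range (constant column -> midpoint
    color). modular: palette cycling keyed by integer module index.
    binarized: ``low_color`` for values <= threshold, ``high_color`` above.
    """
    n = len(nodes)
    if mode == "uniform":
        return np.tile(np.asarray(uniform_color, dtype=float), (n, 1))
    if mode == "colormap":
        cm = _mpl_colormaps[cmap]
        vals = nodes.color_value
        if n == 0:
            return np.zeros((0, 3))
        span = vals.max() - vals.min()
        norm = np.full(n, 0.5) if span < 1e-300 else (vals - vals.min()) / span
        return np.asarray([cm(v)[:3] for v in norm], dtype=float)
    if mode == "modular":
        vals = nodes.color_value
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("modular coloring requires integer module indices")
        idx = np.round(vals).astype(int)
        return np.asarray(
            [MODULAR_PALETTE[i % len(MODULAR_PALETTE)] for i in idx], dtype=float
        )
    if mode == "binarized":
        out = np.empty((n, 3))
        hi = nodes.color_value > threshold
        out[hi] = np.asarray(high_color, dtype=float)
        out[~hi] = np.asarray(low_color, dtype=float)
        return out
    raise ParameterError(f"unknown node color mode {mode!r}")


# ---------------------------------------------------------------------------
# edge extraction and styling
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_edges(
    matrix: EdgeMatrix,
    nodes: Optional[NodeSet] = None,
    mode: str = "value_threshold",
    threshold: float = 0.0,
    use_absolute: bool = False,
    interhemispheric_only: bool = False,
) -> list[StyledEdge]:
    """Extract drawable edges from the association matrix.

    Candidates are the upper-triangle off-diagonal pairs for a symmetric
    matrix, or every ordered off-diagonal pair for an asymmetric one (those
    edges are marked directed). ``value_threshold`` keeps weights strictly
    above the threshold; ``sparsity`` keeps the top-k weights with
    k = round(threshold * n_candidates). ``use_absolute`` ranks and
    thresholds on |w| (applied before either rule); the kept edge retains
    its signed weight. ``interhemispheric_only`` then drops pairs whose
    node x coordinates do not have strictly opposite signs.
    """
    w = matrix.weights
    n = matrix.n
    directed = not matrix.symmetric
    if directed:
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    weights = np.array([w[i, j] for i, j in pairs], dtype=float)
    ranked = np.abs(weights) if use_absolute else weights

    if mode == "value_threshold":
        keep = [k for k in range(len(pairs)) if ranked[k] > threshold]
    elif mode == "sparsity":
        if not 0 < threshold <= 1:
            raise ParameterError(f"sparsity must lie in (0, 1], got {threshold}")
        k = min(_round_half_up(threshold * len(pairs)), len(pairs))
        # sort by descending weight; ties by (smaller i, smaller j)
        order = sorted(range(len(pairs)), key=lambda m: (-ranked[m], pairs[m]))
        keep = sorted(order[:k])
    else:
        raise ParameterError(f"unknown edge extraction mode {mode!r}")

    if interhemispheric_only:
        if nodes is None:
            raise ParameterError("interhemispheric filtering requires node coordinates")
        x = nodes.coords[:, 0]
        keep = [m for m in keep if x[pairs[m][0]] * x[pairs[m][1]] < 0]

    return [
        StyledEdge(endpoints=pairs[m], weight=float(weights[m]), directed=directed)
        for m in keep
    ]


def scale_edge_sizes(
    edges: Sequence[StyledEdge],
    mode: str = "auto",
    equal_radius: float = 0.5,
    radius_range: tuple[float, float] = DEFAULT_EDGE_RADIUS_RANGE,
) -> np.ndarray:
    """Cylinder radii per edge; same auto/raw/equal semantics as node sizes."""
    if mode not in EDGE_SIZE_MODES:
        raise ParameterError(f"unknown edge size mode {mode!r}")
    lo, hi = radius_range
    if not lo < hi:
        raise ParameterError(f"radius range must satisfy lo < hi, got {radius_range}")
    weights = np.array([e.weight for e in edges], dtype=float)
    if mode == "equal":
        if equal_radius <= 0:
            raise ParameterError("equal radius must be positive")
        radii = np.full(len(weights), float(equal_radius))
    elif len(weights) == 0:
        radii = np.zeros(0)
    elif mode == "raw":
        if np.any(weights <= 0):
            raise ValidationError("raw edge size mode requires strictly positive weights")
        radii = weights.copy()
    else:
        radii = _affine_scale(weights, lo, hi)
    for e, r in zip(edges, radii):
        e.radius = float(r)
    return radii


def color_edges(
    edges: Sequence[StyledEdge],
    nodes: Optional[NodeSet] = None,
    mode: str = "uniform",
    uniform_color=(0.35, 0.35, 0.35),
    cmap: str = "jet",
    threshold: float = 0.0,
    distance_threshold: float = 90.0,
    low_color=(0.2, 0.4, 0.8),
    high_color=(1.0, 0.55, 0.1),
    node_colors: Optional[np.ndarray] = None,
) -> np.ndarray:
    """RGB per edge under one of the five edge color modes.

    ``binarized_distance`` splits at a Euclidean node-distance threshold
    (e.g. 90 mm flags long-range connections); ``node_linked`` copies the
    endpoint color when both endpoints match and averages the two endpoint
    RGBs otherwise.
    """
    m = len(edges)
    if mode == "uniform":
        return _assign(edges, np.tile(np.asarray(uniform_color, dtype=float), (m, 1)))
    if mode == "colormap":
        cm = _mpl_colormaps[cmap]
        vals = np.array([e.weight for e in edges], dtype=float)
        if m == 0:
            return np.zeros((0, 3))
        span = vals.max() - vals.min()
        norm = np.full(m, 0.5) if span < 1e-300 else (vals - vals.min()) / span
        return _assign(edges, np.asarray([cm(v)[:3] for v in norm], dtype=float))
    if mode == "binarized_weight":
        out = np.empty((m, 3))
        for k, e in enumerate(edges):
            out[k] = high_color if e.weight > threshold else low_color
        return _assign(edges, out)
    if mode == "binarized_distance":
        if nodes is None:
            raise ParameterError("binarized_distance coloring requires node coordinates")
        out = np.empty((m, 3))
        for k, e in enumerate(edges):
            i, j = e.endpoints
            d = float(np.linalg.norm(nodes.coords[i] - nodes.coords[j]))
            out[k] = high_color if d > distance_threshold else low_color
        return _assign(edges, out)
    if mode == "node_linked":
        if node_colors is None:
            raise ParameterError("node_linked coloring requires node colors")
        node_colors = np.asarray(node_colors, dtype=float)
        out = np.empty((m, 3))
        for k, e in enumerate(edges):
            i, j = e.endpoints
            ci, cj = node_colors[i], node_colors[j]
            out[k] = ci if np.allclose(ci, cj) else 0.5 * (ci + cj)
        return _assign(edges, out)
    raise ParameterError(f"unknown edge color mode {mode!r}")


def _assign(edges: Sequence[StyledEdge], colors: np.ndarray) -> np.ndarray:
    for e, c in zip(edges, colors):
        e.color = tuple(float(v) for v in c)
    return colors


# ---------------------------------------------------------------------------
# nodal strength / hubs
# ---------------------------------------------------------------------------

#: hubs are nodes whose z-scored strength strictly exceeds this cutoff
HUB_Z_CUTOFF = 1.0


def nodal_strength(matrix: EdgeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nodal strength (functional connectivity strength), z-scores and hub flags.

    strength_i = sum over j != i of w_ij; z = (strength - mean) / SD with the
    sample SD (divisor N-1); hub iff z strictly exceeds ``HUB_Z_CUTOFF``.
    A zero SD (all strengths equal) yields z = 0 everywhere and no hubs.
    """
    if matrix.n < 2:
        raise ValidationError("nodal strength needs at least 2 nodes (SD undefined)")
    w = matrix.weights.copy()
    np.fill_diagonal(w, 0.0)
    strength = w.sum(axis=1)
    sd = strength.std(ddof=1)
    z = np.zeros_like(strength) if sd < 1e-300 else (strength - strength.mean()) / sd
    hubs = z > HUB_Z_CUTOFF
    return strength, z, hubs
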