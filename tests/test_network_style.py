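"""Node/edge styling rules, edge extraction, and the nodal-strength statistic."""

import numpy as np
import pytest

from bnv import (
    EdgeMatrix,
    NodeSet,
    ParameterError,
    ValidationError,
    color_edges,
    color_nodes,
    extract_edges,
    nodal_strength,
    scale_edge_sizes,
    scale_node_sizes,
    select_nodes,
)
from bnv.network_style import StyledEdge


def nodes_with(size=None, color=None, x=None):
    n = len(next(v for v in (size, color, x) if v is not None)) if any(
        v is not None for v in (size, color, x)
    ) else 3
    size = [1.0] * n if size is None else size
    color = [1.0] * n if color is None else color
    x = [0.0] * n if x is None else x
    coords = np.column_stack([x, np.zeros(len(size)), np.zeros(len(size))])
    return NodeSet(coords, color, size, [None] * len(size))


# ---------------------------------------------------------------------------
# selection and sizing
# ---------------------------------------------------------------------------

def test_selection_is_strictly_greater():
    n = nodes_with(size=[1.0, 2.0, 3.0])
    assert select_nodes(n, "size_value", 2.0).tolist() == [False, False, True]
    assert select_nodes(n, "all").all()
    # threshold at the max shows nothing
    assert not select_nodes(n, "size_value", 3.0).any()


def test_selection_unknown_selector():
    with pytest.raises(ParameterError):
        select_nodes(nodes_with(), "degree", 0.0)


def test_auto_size_affine_map():
    n = nodes_with(size=[1.0, 2.0, 3.0])
    np.testing.assert_allclose(
        scale_node_sizes(n, "auto", radius_range=(1, 5)), [1, 3, 5]
    )


def test_constant_sizes_map_to_midpoint():
    n = nodes_with(size=[4.0, 4.0])
    np.testing.assert_allclose(scale_node_sizes(n, "auto", radius_range=(1, 5)), [3, 3])


def test_equal_and_raw_modes():
    n = nodes_with(size=[1.0, 2.0])
    np.testing.assert_allclose(scale_node_sizes(n, "equal", equal_radius=2.0), [2, 2])
    np.testing.assert_allclose(scale_node_sizes(n, "raw"), [1, 2])
    with pytest.raises(ValidationError):
        scale_node_sizes(nodes_with(size=[0.0, 1.0]), "raw")


def test_auto_size_monotone(rng):
    vals = rng.uniform(0, 10, 30)
    n = nodes_with(size=vals)
    radii = scale_node_sizes(n, "auto")
    order = np.argsort(vals)
    assert (np.diff(radii[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# node colors
# ---------------------------------------------------------------------------

def test_modular_coloring_keys_by_index():
    n = nodes_with(color=[1.0, 2.0, 1.0])
    c = color_nodes(n, "modular")
    assert np.allclose(c[0], c[2]) and not np.allclose(c[0], c[1])


def test_modular_requires_integers():
    with pytest.raises(ValidationError):
        color_nodes(nodes_with(color=[1.5, 2.0]), "modular")


def test_binarized_and_uniform_and_degenerate_colormap():
    n = nodes_with(color=[-1.0, 2.0])
    c = color_nodes(n, "binarized", threshold=0.0)
    assert not np.allclose(c[0], c[1])
    u = color_nodes(n, "uniform", uniform_color=(0.1, 0.2, 0.3))
    assert np.allclose(u, [[0.1, 0.2, 0.3]] * 2)
    const = color_nodes(nodes_with(color=[2.0, 2.0]), "colormap", cmap="jet")
    assert np.allclose(const[0], const[1])


# ---------------------------------------------------------------------------
# edge extraction
# ---------------------------------------------------------------------------

def upper_matrix(n, upper):
    w = np.zeros((n, n))
    w[np.triu_indices(n, 1)] = upper
    return EdgeMatrix(w + w.T)


def test_sparsity_keeps_top_k():
    m = upper_matrix(4, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    edges = extract_edges(m, mode="sparsity", threshold=0.5)
    assert len(edges) == 3  # k = round(0.5 * 6)
    assert sorted(e.weight for e in edges) == [0.7, 0.8, 0.9]


def test_value_threshold_strict_and_absolute():
    w = np.array([[0, -1.0], [-1.0, 0]])
    m = EdgeMatrix(w)
    assert extract_edges(m, mode="value_threshold", threshold=0.0) == []
    kept = extract_edges(m, mode="value_threshold", threshold=0.0, use_absolute=True)
    assert len(kept) == 1 and kept[0].weight == -1.0  # sign survives ranking


def test_interhemispheric_filter():
    n = nodes_with(x=[-10.0, -5.0, 5.0])
    m = upper_matrix(3, [1.0, 1.0, 1.0])
    edges = extract_edges(
        m, n, mode="value_threshold", threshold=0.0, interhemispheric_only=True
    )
    assert sorted(e.endpoints for e in edges) == [(0, 2), (1, 2)]


def test_midline_node_never_crosses():
    n = nodes_with(x=[0.0, 5.0])
    m = upper_matrix(2, [1.0])
    assert (
        extract_edges(m, n, mode="value_threshold", threshold=0.0,
                      interhemispheric_only=True)
        == []
    )


def test_asymmetric_matrix_gives_directed_edges():
    w = np.array([[0, 1.0], [0, 0]])
    edges = extract_edges(EdgeMatrix(w), mode="value_threshold", threshold=0.5)
    assert len(edges) == 1 and edges[0].directed and edges[0].endpoints == (0, 1)


def test_sparsity_bounds():
    m = upper_matrix(3, [1.0, 2.0, 3.0])
    for bad in (0.0, 1.5, -0.2):
        with pytest.raises(ParameterError):
            extract_edges(m, mode="sparsity", threshold=bad)


def brute_force_sparsity(weights, s, use_absolute=False):
    """Independent oracle: sort all candidate pairs, take top-k."""
    n = weights.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    key = (lambda p: (-abs(weights[p]), p)) if use_absolute else (
        lambda p: (-weights[p], p)
    )
    k = int(np.floor(s * len(pairs) + 0.5))
    return sorted(sorted(pairs, key=key)[:k])


def test_sparsity_matches_brute_force_including_ties(rng):
    for _ in range(100):
        n = int(rng.integers(6, 13))
        upper = rng.choice([0.1, 0.2, 0.3, 0.5], size=n * (n - 1) // 2)  # many ties
        m = upper_matrix(n, upper)
        s = float(rng.uniform(0.05, 1.0))
        got = sorted(e.endpoints for e in extract_edges(m, mode="sparsity", threshold=s))
        assert got == brute_force_sparsity(m.weights, s)


def test_sparsity_edge_count_exact(rng):
    n = 10
    m = upper_matrix(n, rng.uniform(size=45))
    for s in (0.1, 0.33, 0.5, 1.0):
        k = int(np.floor(s * 45 + 0.5))
        assert len(extract_edges(m, mode="sparsity", threshold=s)) == k


# ---------------------------------------------------------------------------
# edge sizing and coloring
# ---------------------------------------------------------------------------

def make_edges(weights):
    return [StyledEdge((0, i + 1), w) for i, w in enumerate(weights)]


def test_edge_auto_size_and_midpoint():
    e = make_edges([1.0, 3.0])
    np.testing.assert_allclose(
        scale_edge_sizes(e, "auto", radius_range=(0.5, 1.5)), [0.5, 1.5]
    )
    single = make_edges([2.0])
    np.testing.assert_allclose(
        scale_edge_sizes(single, "auto", radius_range=(0.5, 1.5)), [1.0]
    )
    np.testing.assert_allclose(scale_edge_sizes(e, "equal", equal_radius=0.3), [0.3, 0.3])


def test_edge_distance_binarization():
    # nodes 100 mm apart exceed the 90 mm long-range threshold
    n = nodes_with(x=[0.0, 100.0, 10.0])
    edges = [StyledEdge((0, 1), 1.0), StyledEdge((0, 2), 1.0)]
    c = color_edges(edges, n, "binarized_distance", distance_threshold=90.0,
                    high_color=(1.0, 0.55, 0.1), low_color=(0.2, 0.4, 0.8))
    np.testing.assert_allclose(c[0], [1.0, 0.55, 0.1])
    np.testing.assert_allclose(c[1], [0.2, 0.4, 0.8])


def test_edge_node_linked_coloring():
    edges = [StyledEdge((0, 1), 1.0), StyledEdge((0, 2), 1.0)]
    node_colors = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    c = color_edges(edges, None, "node_linked", node_colors=node_colors)
    np.testing.assert_allclose(c[0], [1, 0, 0])        # endpoints agree
    np.testing.assert_allclose(c[1], [0.5, 0, 0.5])    # mean of the two


def test_edge_binarized_weight():
    edges = make_edges([0.4, 0.6])
    c = color_edges(edges, None, "binarized_weight", threshold=0.5)
    assert not np.allclose(c[0], c[1])


# ---------------------------------------------------------------------------
# nodal strength / hubs
# ---------------------------------------------------------------------------

def test_nodal_strength_hand_case():
    """w12=1, w13=2, w23=3 -> strengths (3,4,5); sample SD = 1 -> z = (-1,0,1);
    no hubs because the cutoff is strict."""
    m = upper_matrix(3, [1.0, 2.0, 3.0])
    s, z, hubs = nodal_strength(m)
    np.testing.assert_allclose(s, [3, 4, 5])
    np.testing.assert_allclose(z, [-1, 0, 1])
    assert not hubs.any()


def test_equal_strengths_define_z_zero():
    m = upper_matrix(3, [1.0, 1.0, 1.0])
    _, z, hubs = nodal_strength(m)
    np.testing.assert_allclose(z, 0.0)
    assert not hubs.any()


def test_hub_flags_shift_invariant(rng):
    n = 8
    w = rng.uniform(0.1, 1.0, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    _, _, hubs1 = nodal_strength(EdgeMatrix(w))
    shifted = w + 0.7
    np.fill_diagonal(shifted, 0)
    _, _, hubs2 = nodal_strength(EdgeMatrix(shifted))
    np.testing.assert_array_equal(hubs1, hubs2)


def test_nodal_strength_permutation_equivariance(rng):
    n = 7
    w = rng.uniform(size=(n, n))
    w = w + w.T
    np.fill_diagonal(w, 0)
    perm = rng.permutation(n)
    s, _, _ = nodal_strength(EdgeMatrix(w))
    sp, _, _ = nodal_strength(EdgeMatrix(w[np.ix_(perm, perm)]))
    np.testing.assert_allclose(sp, s[perm])


def test_nodal_strength_needs_two_nodes():
    with pytest.raises(ValidationError):
        nodal_strength(EdgeMatrix(np.zeros((1, 1))))


def test_diagonal_ignored():
    w = np.array([[5.0, 1.0], [1.0, 7.0]])
    s, _, _ = nodal_strength(EdgeMatrix(w))
    np.testing.assert_allclose(s, [1.0, 1.0])
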