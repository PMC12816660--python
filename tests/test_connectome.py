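"""FBC construction, graph metrics vs an exhaustive oracle, hub consensus, TDI."""

import itertools

import numpy as np
import pandas as pd
import pytest

from convergemap.connectome import (FbcMatrix, NodeAtlas, build_fbc,
                                    composite_hubs, consensus_top_edges,
                                    node_metrics, population_tdi, tdi)
from convergemap.images import VoxelImage
from convergemap.streamlines import StreamlineSet


def _brute_force_betweenness(w):
    """Betweenness by exhaustive simple-path enumeration (graphs <= 12 nodes).

    Edge length = 1/weight; shortest paths found by enumerating every simple
    path per pair; counts of paths through each interior node, normalized by
    (n-1)(n-2)/2.
    """
    n = w.shape[0]
    adj = [[j for j in range(n) if w[i, j] > 0] for i in range(n)]

    def all_paths(s, t):
        paths = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                paths.append((path, length))
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb], length + 1.0 / w[node, nb]))
        return paths

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        dmin = min(l for _, l in paths)
        shortest = [p for p, l in paths if abs(l - dmin) < 1e-12]
        through = np.zeros(n)
        for p in shortest:
            for v in p[1:-1]:
                through[v] += 1
        bc += through / len(shortest)
    return bc / ((n - 1) * (n - 2) / 2.0)


def _fbc(values, subject_id=""):
    n = values.shape[0]
    return FbcMatrix(values, list(range(1, n + 1)), subject_id)


# --- build_fbc --------------------------------------------------------------

def _two_node_atlas():
    labels = np.zeros((10, 4, 4), dtype=int)
    labels[0, 1, 1] = 1
    labels[9, 1, 1] = 2
    return NodeAtlas(VoxelImage(labels), [1, 2], names={1: "A", 2: "B"})


def test_fbc_sums_mu_scaled_weights():
    atlas = _two_node_atlas()
    lines = [np.array([[0.0, 1, 1], [9.0, 1, 1]])] * 3
    sset = StreamlineSet(lines, np.array([0.5, 0.25, 0.25]), mu=2.0)
    m = build_fbc(sset, atlas)
    assert m.values[0, 1] == pytest.approx(2.0)
    assert m.values[1, 0] == pytest.approx(2.0)


def test_fbc_empty_set_is_zero_matrix():
    m = build_fbc(StreamlineSet([], np.array([]), mu=1.0), _two_node_atlas())
    assert np.all(m.values == 0)


def test_fbc_conservation(connectome_cohort):
    """Every assigned streamline is counted exactly once: total FBC = mu * sum(weights)."""
    sets, atlas, _ = connectome_cohort
    s = sets[0]
    m = build_fbc(s, atlas)
    assert m.total() == pytest.approx(s.mu * s.weights.sum(), rel=1e-12)


def test_fbc_unassigned_endpoints_excluded():
    atlas = _two_node_atlas()
    lines = [np.array([[0.0, 1, 1], [9.0, 1, 1]]),
             np.array([[5.0, 3, 3], [6.0, 3, 3]])]  # both endpoints unlabelled
    m = build_fbc(StreamlineSet(lines, np.array([1.0, 5.0]), mu=1.0), atlas)
    assert m.total() == pytest.approx(1.0)


# --- node metrics -----------------------------------------------------------

def test_three_node_path_betweenness():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    met = node_metrics(_fbc(w))
    assert met["betweenness"].tolist() == [0.0, 1.0, 0.0]
    assert met["strength"].tolist() == [1.0, 2.0, 1.0]
    assert met["degree"].tolist() == [1.0, 2.0, 1.0]


def test_complete_graph_betweenness_zero():
    n = 5
    w = np.ones((n, n)) - np.eye(n)
    met = node_metrics(_fbc(w))
    assert np.allclose(met["betweenness"], 0.0)


@pytest.mark.parametrize("seed,n", [(0, 8), (1, 10), (2, 12), (3, 12), (4, 11)])
def test_betweenness_matches_exhaustive_oracle(seed, n):
    rng = np.random.default_rng(seed)
    w = np.triu((rng.random((n, n)) < 0.35) * rng.uniform(0.5, 3.0, (n, n)), k=1)
    w = w + w.T
    met = node_metrics(_fbc(w))
    oracle = _brute_force_betweenness(w)
    assert np.allclose(met["betweenness"].to_numpy(), oracle, atol=1e-9)


def test_zscore_idempotent():
    from convergemap.connectome import _zscore_across_nodes
    x = np.random.default_rng(3).normal(size=50)
    z = _zscore_across_nodes(x)
    assert np.allclose(_zscore_across_nodes(z), z, atol=1e-12)


# --- consensus hubs and edges ----------------------------------------------

def test_identical_matrices_give_binary_consensus(rng):
    w = np.triu((rng.random((10, 10)) < 0.5) * 1.0, k=1)
    w = w + w.T
    cohort = [_fbc(w, f"s{i}") for i in range(4)]
    rep = composite_hubs(cohort)
    assert set(rep.consensus["consensus_fraction"]) <= {0.0, 1.0}


def test_hub_recovery_exact(fbc_cohort):
    mats, atlas, truth = fbc_cohort
    rep = composite_hubs(mats)
    assert rep.hubs == truth["hubs"]


def test_infinite_threshold_gives_no_hubs(fbc_cohort):
    mats, _, _ = fbc_cohort
    rep = composite_hubs(mats, z_threshold=np.inf)
    assert rep.hubs == []


def test_top_edge_recovery_exact(fbc_cohort):
    mats, atlas, truth = fbc_cohort
    rep = composite_hubs(mats)
    edges = consensus_top_edges(mats, rep.hubs, classes=atlas.classes)
    found = sorted(tuple(sorted((r.hub, r.partner))) for r in edges.itertuples())
    assert found == truth["top_edges"]


def test_dominant_edge_always_selected(rng):
    n = 8
    base = np.triu(np.ones((n, n)), k=1)
    base[0, 1] = 10.0
    w = base + base.T
    np.fill_diagonal(w, 0)
    cohort = [_fbc(w, f"s{i}") for i in range(4)]
    edges = consensus_top_edges(cohort, hubs=[1])
    assert {(r.hub, r.partner) for r in edges.itertuples()} == {(1, 2)}


def test_uniform_weights_select_nothing(rng):
    n = 8
    w = np.ones((n, n)) - np.eye(n)
    cohort = [_fbc(w, f"s{i}") for i in range(4)]
    edges = consensus_top_edges(cohort, hubs=[1])
    assert len(edges) == 0


def test_sparse_hub_skipped_with_warning(caplog):
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = 1.0  # hub 1 has a single connection
    cohort = [_fbc(w, f"s{i}") for i in range(3)]
    edges = consensus_top_edges(cohort, hubs=[1])
    assert len(edges) == 0


# --- TDI --------------------------------------------------------------------

def test_tdi_straight_row_deposits_weight_mu_once_per_voxel():
    grid = VoxelImage(np.zeros((6, 6, 6)))
    sset = StreamlineSet([np.array([[0.0, 2, 2], [5.0, 2, 2]])],
                         np.array([0.7]), mu=2.0)
    m = tdi(sset, grid)
    row = m.density.data[:, 2, 2]
    assert np.allclose(row, 0.7 * 2.0)
    assert m.density.data.sum() == pytest.approx(6 * 0.7 * 2.0)


def test_tdi_zmap_scale_invariant():
    grid = VoxelImage(np.zeros((6, 6, 6)))
    lines = [np.array([[0.0, 1, 1], [5.0, 1, 1]]), np.array([[0.0, 4, 4], [5.0, 4, 4]])]
    a = tdi(StreamlineSet(lines, np.array([1.0, 3.0])), grid)
    b = tdi(StreamlineSet(lines, np.array([2.0, 6.0])), grid)
    assert np.allclose(a.zmap.data, b.zmap.data, atol=1e-12)
    # z-map mean is ~0 over the grid
    assert abs(a.zmap.data.mean()) < 1e-12


def test_tdi_core_mask_contains_only_heavy_bundle():
    """Two parallel bundles at 10:1 weight: only the heavy one survives Z > 2."""
    grid = VoxelImage(np.zeros((16, 16, 16)))
    heavy = [np.array([[0.0, 4, 8], [15.0, 4, 8]])]
    light = [np.array([[0.0, 12, 8], [15.0, 12, 8]])]
    sset = StreamlineSet(heavy + light, np.array([10.0, 1.0]))
    core = tdi(sset, grid).core_mask(z_cut=2.0)
    assert core.data[:, 4, 8].all()
    assert not core.data[:, 12, 8].any()
    assert core.data.sum() == 16


def test_population_tdi_is_voxelwise_mean():
    grid = VoxelImage(np.zeros((4, 4, 4)))
    a = grid.with_data(np.full((4, 4, 4), 1.0))
    b = grid.with_data(np.full((4, 4, 4), 3.0))
    assert np.allclose(population_tdi([a, b]).data, 2.0)


def test_fbc_matrix_invariants_enforced():
    with pytest.raises(ValueError):
        _fbc(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        _fbc(np.array([[1.0, 0.0], [0.0, 0.0]]))  # nonzero diagonal
    with pytest.raises(ValueError):
        _fbc(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative
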