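"""Binary-graph metrics against enumeration, Floyd–Warshall, and networkx."""

import itertools

import networkx as nx
import numpy as np
import pytest

import seasonfc as sf
from seasonfc.graph import AdjacencyMatrix, square_fc_matrices


def adj_from_edges(n, edges):
    m = np.zeros((n, n), dtype=int)
    for i, j in edges:
        m[i, j] = m[j, i] = 1
    return AdjacencyMatrix(m, [f"n{i}" for i in range(n)])


def complete(n):
    return adj_from_edges(n, itertools.combinations(range(n), 2))


def path(n):
    return adj_from_edges(n, [(i, i + 1) for i in range(n - 1)])


# --- independent oracles -----------------------------------------------------

def floyd_warshall_oracle(adj):
    n = adj.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.matrix == 1] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triplet_transitivity_oracle(adj):
    m = adj.matrix
    n = adj.n_nodes
    closed = total = 0
    for i, j, k in itertools.permutations(range(n), 3):
        if m[i, j] and m[j, k]:
            total += 1
            if m[k, i]:
                closed += 1
    return closed, total


# --- worked examples ---------------------------------------------------------

def test_threshold_binarize_semantics():
    vals = np.array([[1.0, 0.1, 0.3], [0.1, 1.0, -0.5], [0.3, -0.5, 1.0]])
    adj = sf.threshold_binarize(vals, tau=0.2)
    assert adj.matrix.tolist() == [[0, 0, 1], [0, 0, 0], [1, 0, 0]]
    adj_abs = sf.threshold_binarize(vals, tau=0.2, mode="absolute")
    assert adj_abs.matrix[1, 2] == 1 and adj_abs.matrix[0, 1] == 0
    assert np.all(np.diag(adj_abs.matrix) == 0)  # unit diagonal never an edge
    with pytest.raises(ValueError):
        sf.threshold_binarize(np.ones((2, 3)))
    with pytest.raises(ValueError):
        sf.threshold_binarize(vals, mode="weighted")


@pytest.mark.parametrize(
    "graph, expected",
    [(complete(4), 1.0), (path(4), 0.5)],
)
def test_density_examples(graph, expected):
    assert sf.density(graph) == pytest.approx(expected)


@pytest.mark.parametrize(
    "graph, expected",
    [
        (complete(3), 1.0),
        (adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]), 0.75),
    ],
)
def test_transitivity_examples(graph, expected):
    assert sf.transitivity(graph) == pytest.approx(expected)
    closed, total = triplet_transitivity_oracle(graph)
    assert sf.transitivity(graph) == pytest.approx(closed / total)


def test_transitivity_no_closed_triplets():
    assert sf.transitivity(path(3)) == pytest.approx(0.0)


def test_transitivity_zero_denominator_policy():
    lonely_edge = adj_from_edges(4, [(0, 1)])
    with pytest.raises(ValueError):
        sf.transitivity(lonely_edge)
    assert sf.transitivity(lonely_edge, zero_denominator="zero") == 0.0


def test_shortest_paths_examples():
    d = sf.shortest_path_matrix(path(3))
    assert d[0, 2] == 2.0
    disconnected = adj_from_edges(4, [(0, 1), (2, 3)])
    d2 = sf.shortest_path_matrix(disconnected)
    assert np.isinf(d2[0, 2])


@pytest.mark.parametrize(
    "graph, expected",
    [
        (complete(4), 1.0),
        (path(3), 5.0 / 6.0),
        (adj_from_edges(4, [(0, 1), (2, 3)]), 1.0 / 3.0),
    ],
)
def test_global_efficiency_examples(graph, expected):
    assert sf.global_efficiency(graph) == pytest.approx(expected)


@pytest.mark.parametrize(
    "graph, expected",
    [
        (complete(4), 1.0),
        (path(3), 4.0 / 3.0),
        (adj_from_edges(4, [(0, 1), (2, 3)]), 1.0),  # unreachable pairs excluded
    ],
)
def test_characteristic_path_length_examples(graph, expected):
    assert sf.characteristic_path_length(graph) == pytest.approx(expected)


def test_characteristic_path_length_needs_an_edge():
    with pytest.raises(ValueError):
        sf.characteristic_path_length(adj_from_edges(3, []))


def test_metric_domain_errors():
    one = AdjacencyMatrix(np.zeros((1, 1), dtype=int), ["n0"])
    with pytest.raises(ValueError):
        sf.density(one)
    with pytest.raises(ValueError):
        sf.global_efficiency(one)


def test_adjacency_validation():
    with pytest.raises(ValueError):
        AdjacencyMatrix(np.array([[0, 1], [0, 0]]), ["a", "b"])  # asymmetric
    with pytest.raises(ValueError):
        AdjacencyMatrix(np.array([[1, 0], [0, 0]]), ["a", "b"])  # diagonal
    with pytest.raises(ValueError):
        AdjacencyMatrix(np.array([[0, 2], [2, 0]]), ["a", "b"])  # non-binary


def _random_graphs(n_graphs=200, seed=42):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(4, 13))
        p = rng.choice([0.2, 0.5, 0.8])
        m = (rng.random((n, n)) < p).astype(int)
        m = np.triu(m, 1)
        yield AdjacencyMatrix(m + m.T, [f"n{i}" for i in range(n)])


def test_random_graphs_match_networkx_and_oracles():
    checked_transitivity = 0
    for adj in _random_graphs():
        g = nx.from_numpy_array(adj.matrix)
        assert sf.density(adj) == pytest.approx(nx.density(g), abs=1e-12)
        assert sf.global_efficiency(adj) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12
        )
        d = sf.shortest_path_matrix(adj)
        assert np.array_equal(d, floyd_warshall_oracle(adj))
        closed, total = triplet_transitivity_oracle(adj)
        if total > 0:
            assert sf.transitivity(adj) == pytest.approx(closed / total, abs=1e-12)
            assert sf.transitivity(adj) == pytest.approx(nx.transitivity(g), abs=1e-12)
            checked_transitivity += 1
        if adj.n_edges > 0:
            iu = np.triu_indices(adj.n_nodes, 1)
            finite = d[iu][np.isfinite(d[iu])]
            assert sf.characteristic_path_length(adj) == pytest.approx(
                finite.mean(), abs=1e-12
            )
    assert checked_transitivity > 150


def test_edge_addition_monotonicity(rng):
    for _ in range(30):
        n = int(rng.integers(4, 10))
        m = (rng.random((n, n)) < 0.4).astype(int)
        m = np.triu(m, 1)
        adj = AdjacencyMatrix(m + m.T, [f"n{i}" for i in range(n)])
        absent = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if adj.matrix[i, j] == 0]
        if not absent or adj.n_edges == 0:
            continue
        i, j = absent[int(rng.integers(len(absent)))]
        d_before = sf.shortest_path_matrix(adj)
        m2 = adj.matrix.copy()
        m2[i, j] = m2[j, i] = 1
        adj2 = AdjacencyMatrix(m2, adj.labels)
        assert sf.density(adj2) > sf.density(adj)
        assert sf.global_efficiency(adj2) >= sf.global_efficiency(adj) - 1e-12
        if np.isfinite(d_before[i, j]):
            assert sf.characteristic_path_length(adj2) <= (
                sf.characteristic_path_length(adj) + 1e-12
            )


def test_metrics_invariant_under_relabeling(rng):
    for adj in itertools.islice(_random_graphs(seed=9), 20):
        if adj.n_edges == 0:
            continue
        perm = rng.permutation(adj.n_nodes)
        m = adj.matrix[np.ix_(perm, perm)]
        permuted = AdjacencyMatrix(m, [adj.labels[i] for i in perm])
        for metric in (sf.density, sf.global_efficiency,
                       sf.characteristic_path_length):
            assert metric(adj) == pytest.approx(metric(permuted), abs=1e-12)


def test_union_matrix_block_structure(small_cohort):
    subj = small_cohort.subjects[0]
    filtered = sf.normalize_unit_variance(sf.bandpass_filter(subj.series))
    mats = square_fc_matrices(filtered)
    gm_n = sum(t == "GM" for t in filtered.tissue)
    union = mats["union"].values
    assert np.allclose(union[:gm_n, :gm_n], mats["gm_gm"].values, atol=1e-12)
    assert np.allclose(union[gm_n:, gm_n:], mats["wm_wm"].values, atol=1e-12)
    cross = sf.pearson_fc(filtered.select_tissue("GM"), filtered.select_tissue("WM"))
    assert np.allclose(union[:gm_n, gm_n:], cross.values, atol=1e-12)


def test_graph_metrics_for_subject_matches_stepwise(small_cohort):
    subj = small_cohort.subjects[1]
    filtered = sf.normalize_unit_variance(sf.bandpass_filter(subj.series))
    got = sf.graph_metrics_for_subject(filtered, tau=0.2, mode="absolute",
                                       zero_denominator="zero")
    for kind, fc in square_fc_matrices(filtered).items():
        adj = sf.threshold_binarize(fc, tau=0.2, mode="absolute")
        assert got[kind].density == pytest.approx(sf.density(adj))
        assert got[kind].global_efficiency == pytest.approx(sf.global_efficiency(adj))
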