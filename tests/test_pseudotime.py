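import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mstraj._stats import spearman_pairs
from mstraj.graph import CellStateGraph
from mstraj.matrix import ExpressionMatrix
from mstraj.preprocess import QcThresholds, correlation_filter_genes, normalize, qc_filter_cells
from mstraj.pseudotime import (
    cell_positions,
    ensemble_profiles,
    k_shortest_paths,
    pick_endpoints,
    resample_path,
)
from mstraj.simulate import TrajectoryConfig, simulate_trajectory


def _graph(edges):
    """edges: iterable of (a, b, w)."""
    nodes = sorted({x for a, b, _ in edges for x in (a, b)})
    df = pd.DataFrame([(a, b, w, 1.0) for a, b, w in edges],
                      columns=["a", "b", "weight", "frequency"])
    return CellStateGraph(nodes, df)


def _brute_force_paths(edges, start, end):
    """Oracle: all simple paths sorted by (total weight, node sequence)."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    out = []
    for p in nx.all_simple_paths(g, start, end):
        cost = sum(g[u][v]["weight"] for u, v in zip(p[:-1], p[1:]))
        out.append((cost, p))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


class TestKShortestPaths:
    def test_diamond_graph_order(self):
        edges = [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.5),
                 ("b", "t", 1.5)]
        pe = k_shortest_paths(_graph(edges), "s", "t", K=2)
        assert pe.paths == [["s", "a", "t"], ["s", "b", "t"]]
        assert pe.costs == pytest.approx([2.0, 3.0])

    def test_exhaustion_warns(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0)]
        with pytest.warns(UserWarning, match="only 1 simple paths"):
            pe = k_shortest_paths(_graph(edges), "a", "c", K=5)
        assert len(pe) == 1
        assert pe.exhausted

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        # exact oracle equivalence on random small graphs
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        names = [f"n{i:02d}" for i in range(n)]
        edges = []
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                edges.append((names[i], names[j], float(rng.random()) + 0.01))
        g = nx.Graph([(a, b) for a, b, _ in edges])
        if "n00" not in g or f"n{n-1:02d}" not in g or not nx.has_path(
                g, "n00", f"n{n-1:02d}"):
            pytest.skip("disconnected sample")
        oracle = _brute_force_paths(edges, "n00", f"n{n-1:02d}")
        K = min(len(oracle), 25)
        pe = k_shortest_paths(_graph(edges), "n00", f"n{n-1:02d}", K=K,
                              tie_break="lex")
        for got_cost, got_path, (exp_cost, exp_path) in zip(
                pe.costs, pe.paths, oracle[:K]):
            assert got_cost == pytest.approx(exp_cost)
            assert got_path == exp_path

    def test_tie_break_lexicographic(self):
        # two equal-cost routes: lexicographically smaller sequence first
        edges = [("s", "a", 1.0), ("s", "b", 1.0), ("a", "t", 1.0),
                 ("b", "t", 1.0)]
        pe = k_shortest_paths(_graph(edges), "s", "t", K=2, tie_break="lex")
        assert pe.paths == [["s", "a", "t"], ["s", "b", "t"]]

    def test_disconnected_raises(self):
        edges = [("a", "b", 1.0), ("c", "d", 1.0)]
        with pytest.raises(ValueError, match="disconnected"):
            k_shortest_paths(_graph(edges), "a", "d", K=1)

    def test_invalid_k(self):
        edges = [("a", "b", 1.0)]
        with pytest.raises(ValueError, match="K must be"):
            k_shortest_paths(_graph(edges), "a", "b", K=0)

    def test_spur_budget_guard(self):
        edges = [(f"n{i}", f"n{j}", 1.0 + 0.01 * i * j)
                 for i, j in itertools.combinations(range(8), 2)]
        with pytest.raises(RuntimeError, match="budget"):
            k_shortest_paths(_graph(edges), "n0", "n7", K=200,
                             max_spur_searches=3)


class TestResamplePath:
    def test_identity_when_length_matches(self, rng):
        v = rng.random((3, 41))
        np.testing.assert_allclose(resample_path(v, 41), v)

    def test_two_node_linear_interpolation(self):
        v = np.array([[0.0, 1.0]])
        np.testing.assert_allclose(resample_path(v, 5),
                                   [[0.0, 0.25, 0.5, 0.75, 1.0]])

    def test_l_too_small(self):
        with pytest.raises(ValueError, match="L must be"):
            resample_path(np.zeros((1, 3)), 1)

    def test_path_too_short(self):
        with pytest.raises(ValueError, match="length >= 2"):
            resample_path(np.zeros((1, 1)), 5)

    def test_weight_positions_respected(self):
        # all axis length sits on the second edge
        v = np.array([[0.0, 0.0, 1.0]])
        out = resample_path(v, 5, positions=np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(out, [[0.0, 0.25, 0.5, 0.75, 1.0]])

    @given(st.integers(2, 30), st.integers(2, 50), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_output_bounded_by_input(self, n, L, seed):
        v = np.random.default_rng(seed).random((2, n))
        out = resample_path(v, L)
        assert out.shape == (2, L)
        assert out.min() >= v.min() - 1e-12
        assert out.max() <= v.max() + 1e-12
        np.testing.assert_allclose(out[:, 0], v[:, 0])
        np.testing.assert_allclose(out[:, -1], v[:, -1])


class TestEnsembleProfiles:
    def _matrix(self, rng, cells):
        values = rng.random((4, len(cells))) + 0.1
        return ExpressionMatrix(values, [f"g{i}" for i in range(4)], cells,
                                layer="lognorm")

    def test_single_path_mean_equals_resampled(self, rng):
        cells = ["a", "b", "c", "d"]
        m = self._matrix(rng, cells)
        from mstraj.pseudotime import PathEnsemble
        pe = PathEnsemble(paths=[cells], costs=[1.0], K=1, start="a", end="d")
        prof = ensemble_profiles(pe, m, L=9)
        expected = resample_path(m.values, 9)
        np.testing.assert_allclose(prof.mean_profile.to_numpy(), expected)
        np.testing.assert_allclose(prof.dispersion.to_numpy(), 0.0, atol=1e-12)

    def test_identical_paths_zero_dispersion(self, rng):
        cells = ["a", "b", "c"]
        m = self._matrix(rng, cells)
        from mstraj.pseudotime import PathEnsemble
        pe = PathEnsemble(paths=[cells, cells], costs=[1.0, 1.0], K=2,
                          start="a", end="c")
        prof = ensemble_profiles(pe, m, L=5)
        np.testing.assert_allclose(prof.dispersion.to_numpy(), 0.0, atol=1e-12)

    def test_mean_invariant_to_path_order(self, rng):
        cells = ["a", "b", "c", "d", "e"]
        m = self._matrix(rng, cells)
        from mstraj.pseudotime import PathEnsemble
        p1 = ["a", "b", "e"]
        p2 = ["a", "c", "d", "e"]
        pe_fwd = PathEnsemble(paths=[p1, p2], costs=[1.0, 1.0], K=2,
                              start="a", end="e")
        pe_rev = PathEnsemble(paths=[p2, p1], costs=[1.0, 1.0], K=2,
                              start="a", end="e")
        np.testing.assert_allclose(
            ensemble_profiles(pe_fwd, m, L=7).mean_profile.to_numpy(),
            ensemble_profiles(pe_rev, m, L=7).mean_profile.to_numpy())

    def test_edge_usage_totals(self):
        from mstraj.pseudotime import PathEnsemble
        pe = PathEnsemble(paths=[["a", "b", "c"], ["a", "c"]],
                          costs=[1.0, 2.0], K=2, start="a", end="c")
        usage = pe.edge_usage()
        assert usage["n_paths"].sum() == 3  # 2 edges + 1 edge

    def test_empty_ensemble_rejected(self, rng):
        from mstraj.pseudotime import PathEnsemble
        m = self._matrix(rng, ["a", "b"])
        pe = PathEnsemble(paths=[], costs=[], K=1, start="a", end="b")
        with pytest.raises(ValueError, match="empty"):
            ensemble_profiles(pe, m)


class TestPseudotimeRecovery:
    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_rank_recovery_on_synthetic_data(self, seed):
        from mstraj.graph import cell_distance, consensus_mst
        from mstraj.modules import detect_modules, select_modules

        cfg = TrajectoryConfig(seed=seed)
        m, truth = simulate_trajectory(cfg)
        m, _ = qc_filter_cells(m, QcThresholds(min_total_counts=1))
        f = normalize(m)
        f = f.subset_genes(correlation_filter_genes(f))
        ms = select_modules(detect_modules(f))
        genes = ms.selected_genes()
        d = cell_distance(f, genes)
        g = consensus_mst(d, n_trees=200, mode="gene_resample", seed=seed,
                          matrix=f, genes=genes)
        mod = truth.module_of_gene
        early = [x for x in f.gene_ids if mod[x] == "0"]
        late = [x for x in f.gene_ids if mod[x] == "2"]
        start, end = pick_endpoints(f, early, late, graph=g)
        pe = k_shortest_paths(g, start, end, K=2000, tie_break="fast")
        pos = cell_positions(pe)
        lat = truth.latent_time[pos.index]
        ok = lat.notna()
        rho = spearman_pairs(pos[ok].to_numpy(), lat[ok].to_numpy())
        assert abs(rho) >= 0.8
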