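"""Markov clustering, modularity, inflation tuning and cluster selection."""

import networkx as nx
import numpy as np
import pytest

from stressweave import clustering
from stressweave.clustering import ClusterSolution, MCLConfig
from stressweave.errors import ParameterError


def q_brute(graph: nx.Graph, partition: dict) -> float:
    """Independent pairwise-sum modularity oracle."""
    w = {
        frozenset((u, v)): d.get("enhanced_score", 1.0)
        for u, v, d in graph.edges(data=True)
        if u != v
    }
    nodes = list(graph.nodes)
    two_m = 2 * sum(w.values())
    k = {
        n: sum(wt for pair, wt in w.items() if n in pair) for n in nodes
    }
    q = 0.0
    for i in nodes:
        for j in nodes:
            if partition[i] != partition[j]:
                continue
            a = w.get(frozenset((i, j)), 0.0) if i != j else 0.0
            q += a - k[i] * k[j] / two_m
    return q / two_m


class TestMCL:
    def test_two_disjoint_triangles_recovered_exactly(self, two_triangles):
        sol = clustering.mcl(two_triangles, MCLConfig(weight=None))
        assert sorted(sol.clusters().values()) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_clique_is_one_cluster(self):
        sol = clustering.mcl(nx.complete_graph(5), MCLConfig(weight=None))
        assert sol.n_clusters == 1

    def test_never_merges_disconnected_components(self):
        # connected-components oracle on random small graphs
        rng = np.random.default_rng(0)
        for trial in range(15):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            g.add_edges_from((i + 12, j + 12) for i, j in
                             nx.gnp_random_graph(8, 0.4, seed=trial).edges)
            g.add_nodes_from(range(20))
            comp_of = {}
            for ci, comp in enumerate(sorted(nx.connected_components(g), key=min)):
                for n in comp:
                    comp_of[n] = ci
            sol = clustering.mcl(g, MCLConfig(weight=None))
            for cluster in sol.clusters().values():
                assert len({comp_of[int(n)] for n in cluster}) == 1

    def test_partition_invariant_under_relabeling(self, two_cliques):
        sol = clustering.mcl(two_cliques, MCLConfig(weight=None))
        mapping = {n: f"z{n}" for n in two_cliques.nodes}
        relabeled = nx.relabel_nodes(two_cliques, mapping)
        sol2 = clustering.mcl(relabeled, MCLConfig(weight=None))
        groups1 = sorted(sorted(mapping[n] for n in c) for c in sol.clusters().values())
        groups2 = sorted(sorted(c) for c in sol2.clusters().values())
        assert groups1 == groups2

    def test_partition_invariant_under_weight_scaling(self, two_triangles):
        g1 = two_triangles.copy()
        g2 = two_triangles.copy()
        for g, scale in ((g1, 1.0), (g2, 7.5)):
            for _, _, d in g.edges(data=True):
                d["enhanced_score"] = scale
        s1 = clustering.mcl(g1)
        s2 = clustering.mcl(g2)
        assert s1.partition == s2.partition
        assert clustering.modularity(g1, s1.partition) == pytest.approx(
            clustering.modularity(g2, s2.partition)
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ParameterError):
            clustering.mcl(nx.Graph())

    def test_nonconvergence_flagged(self):
        # a long path needs several expansion/inflation rounds to settle
        g = nx.path_graph(10)
        with pytest.warns(UserWarning, match="did not converge"):
            sol = clustering.mcl(g, MCLConfig(max_iterations=1, weight=None))
        assert not sol.converged

    @pytest.mark.parametrize(
        "kwargs", [{"inflation": 1.0}, {"expansion": 1}, {"pruning": 0.5},
                   {"tolerance": 0.0}]
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ParameterError):
            MCLConfig(**kwargs)


class TestModularity:
    def test_one_community_is_zero(self, two_cliques):
        part = {n: 0 for n in two_cliques.nodes}
        assert clustering.modularity(two_cliques, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_cliques_half(self, two_cliques):
        part = {n: (0 if int(n[1:]) < 5 else 1) for n in two_cliques.nodes}
        assert clustering.modularity(two_cliques, part) == pytest.approx(0.5)

    def test_singletons_on_triangle(self):
        g = nx.complete_graph(3)
        part = {n: n for n in g.nodes}
        assert clustering.modularity(g, part) == pytest.approx(-1 / 3)
        assert q_brute(g, part) == pytest.approx(-1 / 3)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=trial)
            if g.number_of_edges() == 0:
                continue
            for _, _, d in g.edges(data=True):
                d["enhanced_score"] = float(rng.uniform(0.1, 1.0))
            part = {n: int(rng.integers(3)) for n in g.nodes}
            assert clustering.modularity(g, part) == pytest.approx(
                q_brute(g, part), abs=1e-12
            )

    def test_empty_edge_set_is_zero_with_warning(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.warns(UserWarning, match="empty"):
            assert clustering.modularity(g, {"a": 0, "b": 1}) == 0.0

    def test_uncovered_nodes_rejected(self, two_triangles):
        with pytest.raises(ParameterError):
            clustering.modularity(two_triangles, {"a": 0})


class TestTuneInflation:
    def test_single_grid_point_returned(self, two_triangles):
        r, sol = clustering.tune_inflation(two_triangles, (2.0,))
        assert r == 2.0

    def test_tie_broken_toward_smaller_inflation(self, two_cliques):
        r, sol = clustering.tune_inflation(two_cliques, (1.5, 2.0, 4.0))
        # every grid point yields the identical 2-clique partition
        assert r == 1.5
        assert sol.n_clusters == 2
        assert sol.modularity == pytest.approx(0.5)

    def test_empty_grid_rejected(self, two_triangles):
        with pytest.raises(ParameterError):
            clustering.tune_inflation(two_triangles, ())

    def test_returned_q_is_grid_maximum(self, planted_dataset):
        from stressweave import enhance

        graph = enhance.build_enhanced_graph(
            planted_dataset.edges, planted_dataset.fold_changes
        )
        grid = (1.4, 2.0, 3.0)
        _, best = clustering.tune_inflation(graph, grid)
        for r in grid:
            sol = clustering.mcl(graph, MCLConfig(inflation=r))
            assert clustering.modularity(graph, sol.partition) <= best.modularity + 1e-12


class TestClusterSelection:
    def make_solution(self, fc_by_cluster):
        partition, log2fc = {}, {}
        for cid, values in fc_by_cluster.items():
            for i, v in enumerate(values):
                gene = f"c{cid}g{i}"
                partition[gene] = cid
                log2fc[gene] = v
        sol = ClusterSolution(partition=partition, inflation=2.0)
        clustering.annotate_solution(sol, log2fc)
        return sol

    def test_coherent_up_cluster_kept(self):
        sol = self.make_solution({0: list(np.linspace(0.5, 2.0, 25))})
        assert clustering.filter_clusters(sol) == [0]
        assert sol.stats[0].direction == "up"

    def test_mixed_signs_rejected(self):
        sol = self.make_solution({0: list(np.linspace(-1.0, 1.0, 25))})
        assert clustering.filter_clusters(sol) == []
        assert sol.stats[0].direction == "mixed"

    def test_small_cluster_rejected_despite_coherence(self):
        sol = self.make_solution({0: list(np.linspace(-2.0, -0.5, 15))})
        assert sol.stats[0].direction == "down"
        assert clustering.filter_clusters(sol) == []  # needs > 20 genes

    def test_whisker_outlier_does_not_veto(self):
        # 24 tightly negative values plus one extreme positive outlier:
        # the outlier lies beyond Q3 + 1.5*IQR so the trimmed cluster is
        # still coherently down-regulated
        values = list(np.linspace(-1.2, -0.8, 24)) + [5.0]
        sol = self.make_solution({0: values})
        assert sol.stats[0].direction == "down"
        assert clustering.filter_clusters(sol) == [0]

    def test_stats_required(self):
        sol = ClusterSolution(partition={"a": 0}, inflation=2.0)
        with pytest.raises(ParameterError):
            clustering.filter_clusters(sol)
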