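"""Signed multi-omics network assembly and anchor extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stressweave import integration
from stressweave.association import AssociationRecord
from stressweave.errors import ParameterError


def gene_table(rows):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "cluster"])
    df["fermentation_ethanol"] = False
    df["ros_redox"] = False
    return df


def perturbation_table(rows):
    return pd.DataFrame(rows, columns=["pathway", "direction", "fold_enrichment", "fdr"])


EMPTY_VARIANTS = pd.DataFrame(columns=["variant", "gene", "consequence", "tier", "zygosity"])


class TestEdgeSign:
    @pytest.mark.parametrize(
        "lfc,direction,expected",
        [(1.0, "up", 1), (-0.5, "up", -1), (-2.0, "down", 1), (0.3, "down", -1)],
    )
    def test_sign_agreement(self, lfc, direction, expected):
        assert integration.edge_sign(lfc, direction) == expected

    def test_zero_fold_change_undefined(self):
        with pytest.raises(ParameterError):
            integration.edge_sign(0.0, "up")

    def test_direction_vocabulary(self):
        with pytest.raises(ParameterError):
            integration.edge_sign(1.0, "sideways")


class TestAssemble:
    def test_empty_inputs_give_empty_network(self):
        net = integration.assemble(
            gene_table([]), {}, perturbation_table([]), [], EMPTY_VARIANTS
        )
        assert net.number_of_nodes() == 0

    def test_single_gene_pathway_variant_example(self):
        genes = gene_table([("g1", 1.0, 0)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        var = pd.DataFrame(
            [{"variant": "chrI:5:A", "gene": "g1", "consequence": "missense_variant",
              "tier": "MODERATE", "zygosity": "homozygous"}]
        )
        net = integration.assemble(genes, {"P": {"g1"}}, pert, [], var)
        assert net.number_of_edges() == 2
        assert net.edges["chrI:5:A", "g1"]["weight"] == 0
        assert net.edges["g1", "P"]["weight"] == 1

    def test_hand_enumerated_fixture(self):
        # 5 genes / 2 pathways / 2 phenotypes / 2 variants
        genes = gene_table(
            [("g1", 1.0, 0), ("g2", -1.0, 0), ("g3", 2.0, 1),
             ("g4", -0.5, 1), ("g5", 1.5, 2)]
        )
        memberships = {"Pup": {"g1", "g2"}, "Pdown": {"g3", "g4"},
                       "Pnotsig": {"g5"}}
        pert = perturbation_table(
            [("Pup", "up", 2.0, 1e-3), ("Pdown", "down", 1.5, 1e-3),
             ("Pnotsig", "up", 3.0, 0.5)]  # fails the FDR cutoff
        )
        assoc = [
            AssociationRecord("g1", "qEthanol", 5.0, True, "+"),
            AssociationRecord("g3", "biomass", 4.0, True, "-"),
            AssociationRecord("g5", "qEthanol", -2.0, False, None),
        ]
        var = pd.DataFrame(
            [
                {"variant": "v1", "gene": "g1", "consequence": "stop_gained",
                 "tier": "HIGH", "zygosity": "het_with_ref"},
                {"variant": "v2", "gene": "g4", "consequence": "synonymous_variant",
                 "tier": "LOW", "zygosity": "homozygous"},
            ]
        )
        net = integration.assemble(
            genes, memberships, pert, assoc, var,
            phenotype_directions={"qEthanol": "up", "biomass": "down"},
        )
        expected = {
            ("g1", "Pup", 1), ("g2", "Pup", -1),     # up pathway
            ("g3", "Pdown", -1), ("g4", "Pdown", 1),  # down pathway
            ("g1", "qEthanol", 1), ("g3", "biomass", -1),
            ("v1", "g1", 0),                          # LOW variant v2 excluded
        }
        got = {(u, v, d["weight"]) for u, v, d in net.edges(data=True)}
        assert got == expected
        assert net.nodes["qEthanol"]["direction"] == "up"

    def test_dangling_references_reported_not_fatal(self):
        genes = gene_table([("g1", 1.0, 0)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        assoc = [AssociationRecord("ghost", "p", 3.0, True, "+")]
        net = integration.assemble(genes, {"P": {"g1", "ghost2"}}, pert, assoc, EMPTY_VARIANTS)
        assert len(net.graph["rejects"]) == 2

    def test_deterministic_under_input_row_order(self):
        genes = gene_table([("g1", 1.0, 0), ("g2", -1.0, 0), ("g3", 2.0, 1)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        memberships = {"P": {"g1", "g2", "g3"}}
        n1 = integration.assemble(genes, memberships, pert, [], EMPTY_VARIANTS)
        shuffled = genes.iloc[[2, 0, 1]].reset_index(drop=True)
        n2 = integration.assemble(shuffled, memberships, pert, [], EMPTY_VARIANTS)
        assert nx.utils.graphs_equal(n1, n2)

    def test_layer_directionality_invariants(self, planted_dataset):
        """Randomized synthetic assemblies respect the layer structure."""
        from stressweave import variants as vmod

        ds = planted_dataset
        genes = ds.fold_changes.rename(columns={"log2fc": "log2fc"})[["gene", "log2fc"]]
        genes["cluster"] = [ds.truth.gene_cluster[g] for g in genes["gene"]]
        rng = np.random.default_rng(11)
        genes["fermentation_ethanol"] = rng.random(len(genes)) < 0.1
        genes["ros_redox"] = rng.random(len(genes)) < 0.1
        assoc = [
            AssociationRecord(g, "qEthanol", 1.0, True, rng.choice(["+", "-"]))
            for g in rng.choice(genes["gene"], size=20, replace=False)
        ]
        var_table = vmod.gene_impact_table(ds.variant_records, ds.consequences)
        net = integration.assemble(
            genes, ds.terms, ds.perturbations, assoc, var_table,
            phenotype_directions=ds.phenotype_directions,
        )
        kinds = nx.get_node_attributes(net, "kind")
        for u, v, d in net.edges(data=True):
            assert d["weight"] in (-1, 0, 1)
            assert d["relation"] == integration.RELATIONS[d["weight"]]
            assert kinds[u] in ("variant", "gene")
            if kinds[u] == "variant":
                assert kinds[v] == "gene" and d["weight"] == 0
            else:
                assert kinds[v] in ("pathway", "phenotype")
                assert d["weight"] in (-1, 1)
        for n, kind in kinds.items():
            if kind == "variant":
                assert net.in_degree(n) == 0
            if kind in ("pathway", "phenotype"):
                assert net.out_degree(n) == 0


class TestAnchorExtraction:
    def fixture_network(self):
        genes = gene_table([(f"g{i}", 1.0, 0) for i in range(5)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        return integration.assemble(
            genes, {"P": {f"g{i}" for i in range(5)}}, pert, [], EMPTY_VARIANTS
        )

    def test_all_genes_anchored_is_identity(self):
        net = self.fixture_network()
        sub = integration.extract_anchor_subnetwork(net, {f"g{i}" for i in range(5)}, set())
        assert nx.utils.graphs_equal(net, sub)

    def test_no_anchors_is_empty_with_warning(self):
        net = self.fixture_network()
        with pytest.warns(UserWarning, match="empty anchor"):
            sub = integration.extract_anchor_subnetwork(net, set(), set())
        assert sub.number_of_edges() == 0

    def test_single_hub_keeps_only_its_edges(self):
        net = self.fixture_network()
        sub = integration.extract_anchor_subnetwork(net, {"g2"}, set())
        assert set(sub.edges) == {("g2", "P")}

    def test_idempotent(self):
        net = self.fixture_network()
        anchors = {"g1", "g3"}
        once = integration.extract_anchor_subnetwork(net, anchors, set())
        twice = integration.extract_anchor_subnetwork(once, anchors, set())
        assert nx.utils.graphs_equal(once, twice)


class TestTabulateModel:
    def test_two_edge_example_row(self):
        genes = gene_table([("g1", 1.0, 0)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        var = pd.DataFrame(
            [{"variant": "v1", "gene": "g1", "consequence": "missense_variant",
              "tier": "MODERATE", "zygosity": "homozygous"}]
        )
        net = integration.assemble(genes, {"P": {"g1"}}, pert, [], var)
        table = integration.tabulate_model(net)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["pathway_links"] == "P(+)" and row["has_variant"]

    def test_isolated_gene_excluded(self):
        genes = gene_table([("g1", 1.0, 0), ("lonely", 2.0, 1)])
        pert = perturbation_table([("P", "up", 2.0, 1e-4)])
        net = integration.assemble(genes, {"P": {"g1"}}, pert, [], EMPTY_VARIANTS)
        table = integration.tabulate_model(net)
        assert list(table["gene"]) == ["g1"]

    def test_signed_counts_conserve_gene_source_edges(self, planted_dataset):
        ds = planted_dataset
        genes = ds.fold_changes[["gene", "log2fc"]].copy()
        genes["cluster"] = [ds.truth.gene_cluster[g] for g in genes["gene"]]
        net = integration.assemble(
            genes, ds.terms, ds.perturbations, [], EMPTY_VARIANTS
        )
        table = integration.tabulate_model(net)
        gene_source_edges = sum(
            1 for u, v in net.edges if net.nodes[u]["kind"] == "gene"
        )
        assert int(table["n_positive"].sum() + table["n_negative"].sum()) == gene_source_edges
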