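import pandas as pd
import pytest

import implinet as im
from implinet.boolean_net import BooleanImplication, ImplicationNetwork, QuadrantCounts
from implinet.multilayer import (
    INTER,
    INTRA,
    KIND_CPG,
    KIND_GENE,
    LAYER_CH3,
    LAYER_MP,
    LAYER_MRNA,
    MLEdge,
    MLNode,
    MultiLayerNetwork,
)


def _implication(a, b, imp_type):
    c = QuadrantCounts(0, 10, 10, 0)
    return BooleanImplication(a, b, imp_type, c, ("ll",), {})


def _impl_net(edges):
    feats = sorted({e.source for e in edges} | {e.target for e in edges})
    return ImplicationNetwork(features=feats, edges=list(edges), params={})


class TestBuildLayer:
    def test_equivalent_becomes_two_directed_edges(self):
        ml = im.build_layer_from_implications(
            _impl_net([_implication("A", "B", "equivalent")]), LAYER_MRNA
        )
        assert len(ml.nodes) == 2
        assert len(ml.edges) == 2
        assert all(e.directed and e.kind == INTRA for e in ml.edges)

    def test_asymmetric_becomes_one_directed_edge(self):
        ml = im.build_layer_from_implications(
            _impl_net([_implication("A", "B", "low=>low")]), LAYER_MRNA
        )
        assert len(ml.edges) == 1
        assert ml.edges[0].source == "mRNA::A"

    def test_empty_implications_warn(self, caplog):
        with caplog.at_level("WARNING"):
            ml = im.build_layer_from_implications(_impl_net([]), LAYER_CH3)
        assert not ml.nodes and any("empty" in r.message for r in caplog.records)


class TestLoadMetapathway:
    def test_tsv_edge_list(self, tmp_path):
        p = tmp_path / "mp.tsv"
        p.write_text("source\ttarget\ng1\tg2\ng2\tg3\n")
        ml = im.load_metapathway(p)
        assert len(ml.nodes) == 3 and len(ml.edges) == 2

    def test_duplicate_edges_deduplicated(self, tmp_path, caplog):
        p = tmp_path / "mp.tsv"
        p.write_text("source\ttarget\ng1\tg2\ng1\tg2\n")
        with caplog.at_level("WARNING"):
            ml = im.load_metapathway(p)
        assert len(ml.edges) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_unresolved_ids_become_pathway_elements(self, tmp_path, caplog):
        p = tmp_path / "mp.tsv"
        p.write_text("source\ttarget\ng1\tpathX\n")
        with caplog.at_level("WARNING"):
            ml = im.load_metapathway(p, known_genes={"g1"})
        kinds = {n.entity_id: n.kind for n in ml.nodes.values()}
        assert kinds == {"g1": KIND_GENE, "pathX": "pathway_element"}

    def test_graphml_round_trip_counts(self, tmp_path):
        p = tmp_path / "mp.tsv"
        p.write_text("source\ttarget\ng1\tg2\ng2\tg3\ng3\tg1\n")
        ml = im.load_metapathway(p)
        out = tmp_path / "mp.graphml"
        im.export_graphml(ml, out)
        back = im.import_graphml(out)
        assert len(back.nodes) == len(ml.nodes)
        assert len(back.edges) == len(ml.edges)


def _three_layer(genes_per_layer, cpg_map=None):
    expr = MultiLayerNetwork("c")
    for g in genes_per_layer.get(LAYER_MRNA, []):
        expr.add_node(MLNode(LAYER_MRNA, g, KIND_GENE, gene_id=g))
    mp = MultiLayerNetwork("c")
    for g in genes_per_layer.get(LAYER_MP, []):
        mp.add_node(MLNode(LAYER_MP, g, KIND_GENE, gene_id=g))
    ch3 = MultiLayerNetwork("c")
    for p in genes_per_layer.get(LAYER_CH3, []):
        ch3.add_node(MLNode(LAYER_CH3, p, KIND_CPG))
    return im.assemble(expr, mp, ch3, cpg_to_gene=cpg_map or {})


class TestAssemble:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 3)])
    def test_inter_edge_count_per_layer_pair(self, k, expected):
        layers = {LAYER_MRNA: ["g"], LAYER_MP: ["g"], LAYER_CH3: ["cpg_g"]}
        if k == 2:
            layers.pop(LAYER_CH3)
        net = _three_layer(layers, cpg_map={"cpg_g": "g"})
        inter = [e for e in net.edges if e.kind == INTER]
        assert len(inter) == expected  # k layers -> k(k-1)/2 same-gene edges

    def test_gene_in_one_layer_no_inter_edges(self):
        net = _three_layer({LAYER_MRNA: ["g"]})
        assert all(e.kind != INTER for e in net.edges)

    def test_multiple_probes_fan_out(self):
        net = _three_layer(
            {LAYER_MP: ["g"], LAYER_CH3: ["p1", "p2"]},
            cpg_map={"p1": "g", "p2": "g"},
        )
        inter = [e for e in net.edges if e.kind == INTER]
        assert len(inter) == 2

    def test_unmapped_probe_kept_without_inter_edges(self, caplog):
        with caplog.at_level("WARNING"):
            net = _three_layer({LAYER_MP: ["g"], LAYER_CH3: ["p1"]}, cpg_map={})
        assert "CH3::p1" in net.nodes
        assert all(e.kind != INTER for e in net.edges)

    def test_direct_mrna_ch3_edges_can_be_disabled(self):
        expr = MultiLayerNetwork("c")
        expr.add_node(MLNode(LAYER_MRNA, "g", KIND_GENE, gene_id="g"))
        ch3 = MultiLayerNetwork("c")
        ch3.add_node(MLNode(LAYER_CH3, "p", KIND_CPG))
        net = im.assemble(expr, MultiLayerNetwork("c"), ch3,
                          cpg_to_gene={"p": "g"}, include_mrna_ch3=False)
        assert all(e.kind != INTER for e in net.edges)


class TestNetworkInvariants:
    def test_dangling_edge_rejected(self):
        net = MultiLayerNetwork()
        net.add_node(MLNode(LAYER_MRNA, "a", KIND_GENE, gene_id="a"))
        with pytest.raises(ValueError, match="dangling"):
            net.add_edge(MLEdge("mRNA::a", "mRNA::zz", INTRA, True, "boolean_expr"))

    def test_cpg_only_in_ch3(self):
        net = MultiLayerNetwork()
        with pytest.raises(ValueError):
            net.add_node(MLNode(LAYER_MRNA, "p", KIND_CPG))

    def test_unregistered_annotation_rejected(self):
        net = MultiLayerNetwork()
        with pytest.raises(KeyError):
            net.add_node(
                MLNode(LAYER_MRNA, "a", KIND_GENE, annotations={"no_such_key": 1})
            )


class TestSerialization:
    def _toy(self):
        net = MultiLayerNetwork("GAIN")
        net.add_node(MLNode(LAYER_MRNA, "g1", KIND_GENE, "g1",
                            {"chromosome": "20", "de_label": "OVER_T", "log_fc": 1.5}))
        net.add_node(MLNode(LAYER_MP, "g1", KIND_GENE, "g1"))
        net.add_node(MLNode(LAYER_CH3, "cg1", KIND_CPG, "g1",
                            {"region_category": "TSS200", "chromosome": "20"}))
        net.add_edge(MLEdge("mRNA::g1", "MP::g1", INTER, False, "same_gene"))
        net.add_edge(MLEdge("MP::g1", "CH3::cg1", INTER, False, "same_gene"))
        return net

    def test_graphml_round_trip_lossless(self, tmp_path):
        net = self._toy()
        path = tmp_path / "net.graphml"
        im.export_graphml(net, path)
        back = im.import_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert [e.identity for e in back.edges] == [e.identity for e in net.edges]
        for key in net.nodes:
            assert back.nodes[key].annotations == net.nodes[key].annotations
            assert back.nodes[key].gene_id == net.nodes[key].gene_id

    def test_empty_network_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        im.export_graphml(MultiLayerNetwork(), path)
        assert not im.import_graphml(path).nodes

    def test_cypher_single_node_single_create(self, tmp_path):
        net = MultiLayerNetwork()
        net.add_node(MLNode(LAYER_MRNA, "g1", KIND_GENE, "g1"))
        path = tmp_path / "net.cypher"
        im.export_cypher(net, path)
        text = path.read_text()
        assert text.count("CREATE") == 1

    def test_cypher_inter_edge_emitted_twice(self, tmp_path):
        net = self._toy()
        path = tmp_path / "net.cypher"
        im.export_cypher(net, path)
        text = path.read_text()
        # 3 nodes + 2 undirected inter edges as 2 relationships each
        assert text.count("CREATE") == 3 + 4
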