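"""Heterogeneous three-layer network assembly and serialization.

A condition network has exactly three layers: ``mRNA`` (expression genes),
``MP`` (the metapathway — all KEGG pathways merged through their common
nodes, consumed here as a ready-made GraphML/TSV file), and ``CH3``
(methylation CpG probes).  Intra-layer edges are directed and come from the
Boolean implication networks (mRNA, CH3) or the metapathway file (MP).
Inter-layer edges are bidirectional and connect nodes in different layers
that represent the same gene; they are stored once and traversed both ways.

Nodes carry open annotation sets (chromosome, arm, CpG region category,
differential-expression label, transcription-factor flag, mutation status,
protein-expression status, ...) drawn from a declared key registry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .boolean_net import ImplicationNetwork

log = logging.getLogger(__name__)

LAYER_MRNA = "mRNA"
LAYER_MP = "MP"
LAYER_CH3 = "CH3"
LAYERS = (LAYER_MRNA, LAYER_MP, LAYER_CH3)

KIND_GENE = "gene"
KIND_CPG = "cpg_probe"
KIND_PATHWAY = "pathway_element"

INTRA = "intra"
INTER = "inter"
PROV_BOOL_EXPR = "boolean_expr"
PROV_BOOL_METH = "boolean_meth"
PROV_METAPATHWAY = "metapathway"
PROV_SAME_GENE = "same_gene"

#: declared annotation keys; extend with register_annotation()
ANNOTATION_REGISTRY: set[str] = {
    "chromosome",
    "arm",
    "region_category",
    "de_label",
    "log_fc",
    "tf",
    "mutation",
    "protein",
}


def register_annotation(key: str) -> None:
    """Declare a custom annotation key before attaching it to nodes."""
    ANNOTATION_REGISTRY.add(key)


def node_key(layer: str, entity_id: str) -> str:
    return f"{layer}::{entity_id}"


@dataclass
class MLNode:
    layer: str
    entity_id: str
    kind: str
    gene_id: str | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def key(self) -> str:
        return node_key(self.layer, self.entity_id)


@dataclass(frozen=True)
class MLEdge:
    source: str  # node key
    target: str  # node key
    kind: str  # intra | inter
    directed: bool
    provenance: str

    @property
    def identity(self) -> tuple:
        if not self.directed:
            a, b = sorted((self.source, self.target))
            return (a, b, self.kind, self.provenance, False)
        return (self.source, self.target, self.kind, self.provenance, True)


class MultiLayerNetwork:
    """Three named layers with annotated nodes and directed/bidirectional edges."""

    def __init__(self, condition: str = "", params: dict | None = None):
        self.condition = condition
        self.params = dict(params or {})
        self.nodes: dict[str, MLNode] = {}
        self._edges: dict[tuple, MLEdge] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node: MLNode) -> MLNode:
        if node.layer not in LAYERS:
            raise ValueError(f"unknown layer {node.layer!r}")
        if node.kind == KIND_CPG and node.layer != LAYER_CH3:
            raise ValueError("cpg_probe nodes are only allowed in the CH3 layer")
        for key in node.annotations:
            if key not in ANNOTATION_REGISTRY:
                raise KeyError(f"annotation key {key!r} not registered")
        existing = self.nodes.get(node.key)
        if existing is not None:
            existing.annotations.update(node.annotations)
            if existing.gene_id is None:
                existing.gene_id = node.gene_id
            return existing
        self.nodes[node.key] = node
        return node

    def add_edge(self, edge: MLEdge) -> bool:
        """Insert an edge; returns False (and logs) for duplicates."""
        if edge.source not in self.nodes or edge.target not in self.nodes:
            raise ValueError(f"dangling edge endpoint: {edge.source} -> {edge.target}")
        src, tgt = self.nodes[edge.source], self.nodes[edge.target]
        if edge.kind == INTRA and src.layer != tgt.layer:
            raise ValueError("intra edges must connect same-layer nodes")
        if edge.kind == INTER and src.layer == tgt.layer:
            raise ValueError("inter edges must connect different layers")
        if edge.identity in self._edges:
            log.debug("duplicate edge dropped: %s", edge.identity)
            return False
        self._edges[edge.identity] = edge
        return True

    # -- views -------------------------------------------------------------

    @property
    def edges(self) -> list[MLEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def layer_nodes(self, layer: str) -> list[MLNode]:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return [n for n in self.nodes.values() if n.layer == layer]

    def ch3_gene_groups(self) -> dict[str, list[str]]:
        """Gene-level grouping of CH3 probes (probe keys per owning gene)."""
        groups: dict[str, list[str]] = {}
        for n in self.layer_nodes(LAYER_CH3):
            gene = n.gene_id if n.gene_id else n.entity_id
            groups.setdefault(gene, []).append(n.key)
        return {g: sorted(ks) for g, ks in sorted(groups.items())}

    def annotation_keys(self) -> set[str]:
        keys: set[str] = set()
        for n in self.nodes.values():
            keys.update(n.annotations)
        return keys

    def to_digraph(self) -> nx.DiGraph:
        """Directed view for traversal: inter edges appear in both directions."""
        g = nx.DiGraph()
        for key, n in self.nodes.items():
            g.add_node(key, node=n)
        for e in self.edges:
            g.add_edge(e.source, e.target, eid=e.identity, edge=e)
            if not e.directed:
                g.add_edge(e.target, e.source, eid=e.identity, edge=e)
        return g


# -- layer builders ---------------------------------------------------------


def build_layer_from_implications(
    net: ImplicationNetwork, layer: str, condition: str = ""
) -> MultiLayerNetwork:
    """Intra-layer network from Boolean implications (mRNA or CH3 layer).

    One node per feature appearing in at least one implication.  Symmetric
    implications (equivalent/opposite) become two directed intra edges, one
    per orientation; asymmetric ones a single directed edge.
    """
    if layer not in (LAYER_MRNA, LAYER_CH3):
        raise ValueError("implication layers are mRNA or CH3")
    prov = PROV_BOOL_EXPR if layer == LAYER_MRNA else PROV_BOOL_METH
    kind = KIND_GENE if layer == LAYER_MRNA else KIND_CPG
    ml = MultiLayerNetwork(condition=condition, params=dict(net.params))
    if not net.edges:
        log.warning("no implications for layer %s; empty layer", layer)
        return ml
    for fid in sorted(net.edge_features):
        gene = fid if layer == LAYER_MRNA else None
        ml.add_node(MLNode(layer=layer, entity_id=fid, kind=kind, gene_id=gene))
    for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
        s, t = node_key(layer, e.source), node_key(layer, e.target)
        ml.add_edge(MLEdge(s, t, INTRA, True, prov))
        if e.symmetric:
            ml.add_edge(MLEdge(t, s, INTRA, True, prov))
    return ml


def load_metapathway(path, known_genes=None, condition: str = "") -> MultiLayerNetwork:
    """MP layer from a GraphML or two-column TSV edge-list file.

    Node ids that resolve to gene ids (membership in ``known_genes``, or all
    ids when no set is given) become gene nodes; the rest are kept as
    pathway elements with a warning.  Duplicate edges are deduplicated.
    """
    path = str(path)
    if path.endswith(".graphml"):
        g = nx.read_graphml(path)
        pairs = [(str(u), str(v)) for u, v in g.edges()]
        ids = [str(n) for n in g.nodes()]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"metapathway edge list needs 2 columns: {path}")
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        ids = sorted({i for p in pairs for i in p})
    ml = MultiLayerNetwork(condition=condition)
    unresolved = 0
    for nid in sorted(set(ids)):
        if known_genes is not None and nid not in known_genes:
            unresolved += 1
            ml.add_node(MLNode(LAYER_MP, nid, KIND_PATHWAY, gene_id=None))
        else:
            ml.add_node(MLNode(LAYER_MP, nid, KIND_GENE, gene_id=nid))
    if unresolved:
        log.warning("%d metapathway node(s) unresolved; kept as pathway elements", unresolved)
    dups = 0
    for u, v in pairs:
        added = ml.add_edge(
            MLEdge(node_key(LAYER_MP, u), node_key(LAYER_MP, v), INTRA, True, PROV_METAPATHWAY)
        )
        dups += 0 if added else 1
    if dups:
        log.warning("%d duplicate metapathway edge(s) deduplicated", dups)
    return ml


def assemble(
    expr: MultiLayerNetwork,
    mp: MultiLayerNetwork,
    ch3: MultiLayerNetwork,
    cpg_to_gene: dict[str, str] | None = None,
    gene_annotations: pd.DataFrame | None = None,
    probe_annotations: pd.DataFrame | None = None,
    de_labels: dict[str, tuple[str, float]] | None = None,
    dm_labels: dict[str, tuple[str, float]] | None = None,
    node_annotations: pd.DataFrame | None = None,
    include_mrna_ch3: bool = True,
    condition: str = "",
) -> MultiLayerNetwork:
    """Merge the three partial layers and insert same-gene inter-layer edges.

    Inter edges connect every pair of nodes in different layers that share a
    gene id (all three layer pairs; the direct mRNA-CH3 pair can be switched
    off).  CpG probes are resolved to their owning gene via ``cpg_to_gene``;
    probes without a mapping keep their node but get no inter edges.
    Annotation tables (indexed by gene id / probe id) are attached to nodes;
    custom ``node_annotations`` columns must be registered keys.
    """
    ml = MultiLayerNetwork(condition=condition)
    ml.params = {**expr.params, "include_mrna_ch3": include_mrna_ch3}
    for part in (expr, mp, ch3):
        for key in sorted(part.nodes):
            n = part.nodes[key]
            ml.add_node(
                MLNode(n.layer, n.entity_id, n.kind, n.gene_id, dict(n.annotations))
            )
        for e in part.edges:
            ml.add_edge(e)
    # resolve CpG probes to genes
    unmapped = 0
    for n in ml.layer_nodes(LAYER_CH3):
        if n.gene_id is None and cpg_to_gene is not None:
            gene = cpg_to_gene.get(n.entity_id)
            if gene is None:
                unmapped += 1
            else:
                n.gene_id = gene
    if unmapped:
        log.warning("%d CH3 probe(s) without a gene mapping; no inter edges", unmapped)
    # same-gene inter-layer edges
    by_layer: dict[str, dict[str, list[str]]] = {}
    for layer in LAYERS:
        genes: dict[str, list[str]] = {}
        for n in ml.layer_nodes(layer):
            if n.gene_id:
                genes.setdefault(n.gene_id, []).append(n.key)
        by_layer[layer] = genes
    pairs = [(LAYER_MRNA, LAYER_MP), (LAYER_MP, LAYER_CH3)]
    if include_mrna_ch3:
        pairs.append((LAYER_MRNA, LAYER_CH3))
    for la, lb in pairs:
        shared = set(by_layer[la]) & set(by_layer[lb])
        for gene in sorted(shared):
            for ka in sorted(by_layer[la][gene]):
                for kb in sorted(by_layer[lb][gene]):
                    ml.add_edge(MLEdge(ka, kb, INTER, False, PROV_SAME_GENE))
    # annotations
    if gene_annotations is not None:
        for n in ml.nodes.values():
            if n.gene_id and n.gene_id in gene_annotations.index:
                row = gene_annotations.loc[n.gene_id]
                for col in ("chromosome", "arm"):
                    if col in gene_annotations.columns and pd.notna(row[col]):
                        n.annotations[col] = str(row[col])
    if probe_annotations is not None:
        for n in ml.layer_nodes(LAYER_CH3):
            if n.entity_id in probe_annotations.index:
                row = probe_annotations.loc[n.entity_id]
                for col in ("chromosome", "arm", "region_category"):
                    if col in probe_annotations.columns and pd.notna(row[col]):
                        n.annotations[col] = str(row[col])
    if de_labels:
        for n in ml.layer_nodes(LAYER_MRNA):
            if n.entity_id in de_labels:
                lab, lfc = de_labels[n.entity_id]
                n.annotations["de_label"] = lab
                n.annotations["log_fc"] = float(lfc)
    if dm_labels:
        for n in ml.layer_nodes(LAYER_CH3):
            if n.entity_id in dm_labels:
                lab, lfc = dm_labels[n.entity_id]
                n.annotations["de_label"] = lab
                n.annotations["log_fc"] = float(lfc)
    if node_annotations is not None:
        for col in node_annotations.columns:
            if col not in ANNOTATION_REGISTRY:
                raise KeyError(f"annotation key {col!r} not registered")
        for n in ml.nodes.values():
            ref = n.gene_id or n.entity_id
            if ref in node_annotations.index:
                for col in node_annotations.columns:
                    val = node_annotations.loc[ref, col]
                    if pd.notna(val):
                        n.annotations[col] = val
    return ml


# -- serialization ----------------------------------------------------------

_ANN_PREFIX = "ann_"


def export_graphml(net: MultiLayerNetwork, path) -> None:
    """Write the network as GraphML (each edge stored once, inter undirected)."""
    g = nx.DiGraph()
    g.graph["condition"] = net.condition
    g.graph["params"] = json.dumps(net.params, sort_keys=True)
    for key in sorted(net.nodes):
        n = net.nodes[key]
        attrs = {
            "layer": n.layer,
            "kind": n.kind,
            "gene_id": n.gene_id if n.gene_id is not None else "",
        }
        for k, v in sorted(n.annotations.items()):
            attrs[_ANN_PREFIX + k] = v
        g.add_node(key, **attrs)
    for e in net.edges:
        g.add_edge(
            e.source,
            e.target,
            kind=e.kind,
            directed=e.directed,
            provenance=e.provenance,
        )
    nx.write_graphml(g, path)


def import_graphml(path) -> MultiLayerNetwork:
    """Read a network previously written by :func:`export_graphml`."""
    g = nx.read_graphml(path)
    net = MultiLayerNetwork(condition=g.graph.get("condition", ""))
    if "params" in g.graph:
        net.params = json.loads(g.graph["params"])
    for key in sorted(g.nodes):
        data = g.nodes[key]
        ann = {
            k[len(_ANN_PREFIX):]: v for k, v in data.items() if k.startswith(_ANN_PREFIX)
        }
        gene = data.get("gene_id") or None
        net.add_node(
            MLNode(data["layer"], key.split("::", 1)[1], data["kind"], gene, ann)
        )
    for u, v, data in g.edges(data=True):
        net.add_edge(
            MLEdge(u, v, data["kind"], bool(data["directed"]), data["provenance"])
        )
    return net


def export_cypher(net: MultiLayerNetwork, path) -> None:
    """Write a Cypher script of CREATE statements reproducing the network.

    One CREATE per node; relationships are created via MATCH on node keys,
    with inter edges emitted as two directed relationships.
    """

    def _props(d: dict) -> str:
        items = []
        for k, v in d.items():
            items.append(f"{k}: {json.dumps(v)}")
        return "{" + ", ".join(items) + "}"

    lines = []
    for key in sorted(net.nodes):
        n = net.nodes[key]
        props = {"key": key, "entity_id": n.entity_id, "kind": n.kind}
        if n.gene_id:
            props["gene_id"] = n.gene_id
        for k, v in sorted(n.annotations.items()):
            props[k] = v
        lines.append(f"CREATE (:{n.layer}:{n.kind} {_props(props)});")
    for e in net.edges:
        rel = e.provenance.upper()
        ends = [(e.source, e.target)]
        if not e.directed:
            ends.append((e.target, e.source))
        for u, v in ends:
            lines.append(
                f"MATCH (a {{key: {json.dumps(u)}}}), (b {{key: {json.dumps(v)}}}) "
                f"CREATE (a)-[:{rel} {{kind: {json.dumps(e.kind)}}}]->(b);"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
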