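"""Cross-layer path queries and GAIN-vs-DIS differential-node metrics.

The driver-force proxy for a chromosomal aberration is the percentage of
*differential nodes*: nodes present in one condition's multi-layer network
(e.g. GAIN-Chr20, tumors bearing the broad chromosome-20 copy-number gain)
but absent from the other's (DIS-Chr20, disomic tumors).  Percentages are
taken per layer, with the denominator always the layer size of the network
whose differential set forms the numerator; an optional chromosome filter
restricts the numerator only.  Methylation nodes can be counted at probe
level or grouped to their owning gene (all CpG sites of a gene collapsed to
one node).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .data_io import REGION_CATEGORIES
from .multilayer import (
    ANNOTATION_REGISTRY,
    LAYER_CH3,
    LAYER_MRNA,
    LAYERS,
    MLNode,
    MultiLayerNetwork,
)

log = logging.getLogger(__name__)

GROUP_PROBE = "probe"
GROUP_GENE = "gene"


@dataclass(frozen=True)
class PathQuery:
    """A cross-layer path search specification.

    ``node_filter`` is a mapping of annotation key -> required value (every
    node on a path must satisfy it) or an arbitrary predicate over MLNode.
    ``max_len`` bounds the path length counted in edges.
    """

    start_layer: str = LAYER_MRNA
    end_layer: str = LAYER_CH3
    node_filter: object = None
    max_len: int = 6
    simple: bool = True

    def __post_init__(self):
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2")
        if self.start_layer not in LAYERS or self.end_layer not in LAYERS:
            raise ValueError("unknown start or end layer")


@dataclass(frozen=True)
class SubNetwork:
    """An induced sub-network (node keys + edge identities) of a parent net."""

    nodes: frozenset
    edges: frozenset
    provenance: dict = field(default_factory=dict, compare=False)


def chromosome_matches(node: MLNode, value: str) -> bool:
    """Match a node's chromosome annotation, with optional arm suffix.

    A filter value like ``"8q"`` matches nodes annotated either with
    chromosome ``"8q"`` directly or with chromosome ``"8"`` and arm ``"q"``;
    a bare value like ``"20"`` matches on the chromosome string alone.
    """
    chrom = str(node.annotations.get("chromosome", ""))
    arm = str(node.annotations.get("arm", ""))
    if chrom == value:
        return True
    if value and value[-1] in "pq":
        return chrom == value[:-1] and arm == value[-1]
    return False


def _predicate(net: MultiLayerNetwork, node_filter):
    if node_filter is None:
        return lambda n: True
    if callable(node_filter):
        return node_filter
    known = ANNOTATION_REGISTRY | net.annotation_keys() | {
        "layer",
        "kind",
        "gene_id",
        "entity_id",
    }
    for key in node_filter:
        if key not in known:
            raise KeyError(f"unknown annotation key in filter: {key!r}")

    def pred(n: MLNode) -> bool:
        for key, value in node_filter.items():
            if key == "chromosome":
                if not chromosome_matches(n, str(value)):
                    return False
            elif key in ("layer", "kind", "gene_id", "entity_id"):
                if getattr(n, key) != value:
                    return False
            elif n.annotations.get(key) != value:
                return False
        return True

    return pred


def find_paths(net: MultiLayerNetwork, q: PathQuery) -> SubNetwork:
    """Union of simple paths from the start layer to the end layer.

    Intra edges are traversed along their direction, inter edges both ways;
    every node on a path must pass the query's node filter.  The result is
    the induced sub-network of all nodes and edges traversed by at least one
    qualifying path of length <= ``max_len`` edges.
    """
    pred = _predicate(net, q.node_filter)
    g = net.to_digraph()
    allowed = [k for k in sorted(net.nodes) if pred(net.nodes[k])]
    sub = g.subgraph(allowed)
    sources = [k for k in allowed if net.nodes[k].layer == q.start_layer]
    targets = {k for k in allowed if net.nodes[k].layer == q.end_layer}
    nodes: set = set()
    edges: set = set()
    for s in sources:
        if s in targets:
            continue
        for path in nx.all_simple_paths(sub, s, targets, cutoff=q.max_len):
            nodes.update(path)
            for u, v in zip(path, path[1:]):
                edges.add(sub[u][v]["eid"])
    return SubNetwork(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        provenance={
            "start_layer": q.start_layer,
            "end_layer": q.end_layer,
            "max_len": q.max_len,
            "filter": q.node_filter if isinstance(q.node_filter, dict) else None,
            "condition": net.condition,
        },
    )


def subnetwork_difference(a: SubNetwork, b: SubNetwork) -> SubNetwork:
    """Nodes of ``a`` absent from ``b`` plus their surviving exclusive edges."""
    nodes = a.nodes - b.nodes
    edges = frozenset(
        e for e in a.edges - b.edges if e[0] in nodes and e[1] in nodes
    )
    return SubNetwork(nodes=frozenset(nodes), edges=edges, provenance={
        "difference_of": (a.provenance.get("condition"), b.provenance.get("condition")),
    })


def _layer_identities(
    net: MultiLayerNetwork, layer: str, grouping: str
) -> dict[str, list[MLNode]]:
    """Map node identity -> nodes, under probe- or gene-level grouping."""
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    if grouping not in (GROUP_PROBE, GROUP_GENE):
        raise ValueError(f"unknown grouping {grouping!r}")
    out: dict[str, list[MLNode]] = {}
    for n in net.layer_nodes(layer):
        if layer == LAYER_CH3 and grouping == GROUP_GENE:
            ident = n.gene_id if n.gene_id else n.entity_id
        else:
            ident = n.entity_id
        out.setdefault(ident, []).append(n)
    return out


def differential_nodes(
    gain: MultiLayerNetwork,
    dis: MultiLayerNetwork,
    layer: str,
    grouping: str = GROUP_PROBE,
) -> tuple[set, set]:
    """Identities exclusive to each condition's layer, under a grouping."""
    g = set(_layer_identities(gain, layer, grouping))
    d = set(_layer_identities(dis, layer, grouping))
    return g - d, d - g


def pct_differential(
    gain: MultiLayerNetwork,
    dis: MultiLayerNetwork,
    layer: str,
    grouping: str = GROUP_PROBE,
    chromosome: str | None = None,
    side: str = "gain",
) -> float:
    """Percentage of differential nodes in one condition's layer.

    100 * |differential identities (optionally restricted to a chromosome)|
    / |all identities in that condition's layer|.  The denominator is never
    chromosome-restricted.  Returns NaN for an empty layer.  Rounded to two
    decimals.
    """
    if side not in ("gain", "dis"):
        raise ValueError("side must be 'gain' or 'dis'")
    base, other = (gain, dis) if side == "gain" else (dis, gain)
    idents = _layer_identities(base, layer, grouping)
    if not idents:
        log.warning("empty %s layer in %s network", layer, side)
        return float("nan")
    diff = set(idents) - set(_layer_identities(other, layer, grouping))
    if chromosome is not None:
        diff = {
            i
            for i in diff
            if any(chromosome_matches(n, chromosome) for n in idents[i])
        }
    return round(100.0 * len(diff) / len(idents), 2)


def _probe_categories(node: MLNode) -> set[str]:
    raw = str(node.annotations.get("region_category", ""))
    return {c for c in raw.replace(",", ";").split(";") if c}


def cpg_region_pct(
    gain: MultiLayerNetwork,
    dis: MultiLayerNetwork,
    region_category: str,
    side: str = "gain",
) -> float:
    """Percentage of differential CpG probes annotated with a region category.

    Numerator: probe-level differential CH3 nodes carrying the category
    (probes with multiple categories count once per category); denominator:
    all CpG probes in that condition's CH3 layer.  Rounded to two decimals.
    """
    if region_category not in REGION_CATEGORIES:
        raise ValueError(f"unknown CpG region category {region_category!r}")
    base, other = (gain, dis) if side == "gain" else (dis, gain)
    idents = _layer_identities(base, LAYER_CH3, GROUP_PROBE)
    if not idents:
        return float("nan")
    diff = set(idents) - set(_layer_identities(other, LAYER_CH3, GROUP_PROBE))
    count = sum(
        1
        for i in diff
        if region_category in _probe_categories(idents[i][0])
    )
    return round(100.0 * count / len(idents), 2)


def differential_report(
    gain: MultiLayerNetwork,
    dis: MultiLayerNetwork,
    chromosome: str | None = None,
) -> dict:
    """Full GAIN/DIS differential-node report (JSON-serializable).

    Covers both directions: per-layer differential node sets, per-chromosome
    tallies, layer percentages at probe and gene grouping, and the CpG-region
    percentage table.  Denominators are each network's own layer sizes.
    """
    report: dict = {
        "conditions": {"gain": gain.condition, "dis": dis.condition},
        "chromosome_filter": chromosome,
        "layers": {},
        "cpg_region_pct": {},
    }
    for layer in LAYERS:
        gain_only, dis_only = differential_nodes(gain, dis, layer, GROUP_PROBE)
        entry = {
            "gain_differential": sorted(gain_only),
            "dis_differential": sorted(dis_only),
            "gain_total": len(_layer_identities(gain, layer, GROUP_PROBE)),
            "dis_total": len(_layer_identities(dis, layer, GROUP_PROBE)),
            "pct_gain": pct_differential(gain, dis, layer, GROUP_PROBE, side="gain"),
            "pct_dis": pct_differential(gain, dis, layer, GROUP_PROBE, side="dis"),
        }
        if chromosome is not None:
            entry["pct_gain_chromosome"] = pct_differential(
                gain, dis, layer, GROUP_PROBE, chromosome=chromosome, side="gain"
            )
            entry["pct_dis_chromosome"] = pct_differential(
                gain, dis, layer, GROUP_PROBE, chromosome=chromosome, side="dis"
            )
        tallies: dict[str, int] = {}
        idents = _layer_identities(gain, layer, GROUP_PROBE)
        for i in gain_only:
            chrom = str(idents[i][0].annotations.get("chromosome", "NA"))
            tallies[chrom] = tallies.get(chrom, 0) + 1
        entry["gain_differential_per_chromosome"] = dict(sorted(tallies.items()))
        report["layers"][layer] = entry
    report["layers"][LAYER_CH3 + "_gene"] = {
        "pct_gain": pct_differential(gain, dis, LAYER_CH3, GROUP_GENE, side="gain"),
        "pct_dis": pct_differential(gain, dis, LAYER_CH3, GROUP_GENE, side="dis"),
        "gain_total": len(_layer_identities(gain, LAYER_CH3, GROUP_GENE)),
        "dis_total": len(_layer_identities(dis, LAYER_CH3, GROUP_GENE)),
    }
    for cat in REGION_CATEGORIES:
        report["cpg_region_pct"][cat] = {
            "gain": cpg_region_pct(gain, dis, cat, side="gain"),
            "dis": cpg_region_pct(gain, dis, cat, side="dis"),
        }
    return report
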