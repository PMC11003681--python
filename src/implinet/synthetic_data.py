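"""Seeded synthetic cohorts with planted Boolean implication structure.

The generator emulates, at toy scale, paired expression/methylation cohorts
split into a condition bearing a broad chromosomal copy-number gain (GAIN)
and a disomic condition (DIS).  Every feature is bimodal: each sample sits in
a low or a high mode (two Gaussians separated by many noise SDs, so one-step
fits always succeed).  Implications are planted by a mode-occupancy
construction: the joint low/high quadrant labels of a planted pair are drawn
with exact cell counts that leave the type's sparse quadrant(s) empty, then
values are drawn around the corresponding modes.  An aberration block of
genes on a designated chromosome is co-activated (shared, balanced mode
vector) only in GAIN samples, so the GAIN network gains implication edges —
and hence differential nodes — that the DIS network lacks.

Expression values are emitted as raw TPM (inverse of the log2(TPM+1)
transform) and methylation values as beta values (inverse M-value
transform), so generated cohorts exercise the full input pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boolean_net import (
    EQUIVALENT,
    HIGH_HIGH,
    HIGH_LOW,
    IMPLICATION_TYPES,
    LOW_HIGH,
    LOW_LOW,
    OPPOSITE,
)
from .data_io import (
    EXPRESSION,
    METHYLATION,
    RAW,
    REGION_CATEGORIES,
    FeatureMatrix,
    m_to_beta,
)
from .multilayer import (
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
    node_key,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedPair:
    a: str
    b: str
    type: str


@dataclass
class PlantSpec:
    """Generator parameters; defaults are the package's study conditions."""

    n_genes: int = 60
    n_samples: int = 40  # per condition
    sigma: float = 0.25
    seed: int = 0
    planted_expression: list[PlantedPair] = field(default_factory=list)
    planted_methylation: list[PlantedPair] = field(default_factory=list)
    aberration_genes: list[str] = field(default_factory=list)
    aberration_probes: list[str] = field(default_factory=list)
    aberration_chromosome: str = "20"
    expr_modes: tuple[float, float] = (2.0, 8.0)  # log2(TPM+1) scale
    meth_modes: tuple[float, float] = (-3.0, 3.0)  # M-value scale
    n_probes: int = 40

    def validate(self) -> None:
        used: set[str] = set()
        for pair in self.planted_expression + self.planted_methylation:
            if pair.type not in IMPLICATION_TYPES:
                raise ValueError(f"unknown implication type {pair.type!r}")
            if pair.a == pair.b:
                raise ValueError("planted pair must reference distinct features")
            for f in (pair.a, pair.b):
                if f in used:
                    raise ValueError(f"overlapping plants on feature {f!r}")
                used.add(f)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class Cohort:
    expression: FeatureMatrix  # raw TPM
    methylation: FeatureMatrix  # raw beta
    sample_info: pd.Series
    comparison: pd.DataFrame
    gene_annotation: pd.DataFrame
    probe_annotation: pd.DataFrame
    truth: dict


def _gene_id(i: int) -> str:
    return f"G{i + 1:03d}"


def _probe_id(i: int) -> str:
    return f"cg{i + 1:05d}"


def default_spec(seed: int = 0) -> PlantSpec:
    """The default toy study: 60 genes, 40 samples per condition, sigma 0.25.

    Twelve expression pairs (all six types) and six methylation pairs are
    planted; eight genes on chromosome 20 form the aberration block, six of
    their promoter probes the methylation block.
    """
    genes = [_gene_id(i) for i in range(60)]
    types = [
        EQUIVALENT, EQUIVALENT, EQUIVALENT, EQUIVALENT,
        OPPOSITE, OPPOSITE,
        LOW_LOW, LOW_HIGH, HIGH_LOW, HIGH_HIGH,
        LOW_HIGH, HIGH_HIGH,
    ]
    planted_expr = [
        PlantedPair(genes[2 * i], genes[2 * i + 1], t) for i, t in enumerate(types)
    ]
    probes = [_probe_id(i) for i in range(40)]
    meth_types = [EQUIVALENT, EQUIVALENT, EQUIVALENT, OPPOSITE, LOW_HIGH, HIGH_LOW]
    planted_meth = [
        PlantedPair(probes[2 * i], probes[2 * i + 1], t)
        for i, t in enumerate(meth_types)
    ]
    return PlantSpec(
        seed=seed,
        planted_expression=planted_expr,
        planted_methylation=planted_meth,
        aberration_genes=genes[52:60],
        aberration_probes=probes[12:18],
    )


def _quadrant_template(imp_type: str, n: int) -> list[tuple[int, int]]:
    """Joint (state_a, state_b) labels with exact counts realizing a type.

    Symmetric types split n half/half over their two dense quadrants; the
    asymmetric types put round(0.475 n) in each of the two quadrants forming
    the sparse quadrant's margins (so its independence expectation exceeds
    the detection bound) and the remainder in the third dense quadrant.
    """
    half, rest = n // 2, n - n // 2
    big = int(round(0.475 * n))
    small = n - 2 * big
    if small < 0:
        raise ValueError(f"n={n} too small for an asymmetric plant")
    # states: 0 = low, 1 = high; cells as (a_state, b_state)
    if imp_type == EQUIVALENT:
        cells = {(0, 0): half, (1, 1): rest}
    elif imp_type == OPPOSITE:
        cells = {(0, 1): half, (1, 0): rest}
    elif imp_type == LOW_HIGH:  # sparse ll
        cells = {(0, 1): big, (1, 0): big, (1, 1): small}
    elif imp_type == LOW_LOW:  # sparse lh
        cells = {(0, 0): big, (1, 1): big, (1, 0): small}
    elif imp_type == HIGH_HIGH:  # sparse hl
        cells = {(1, 1): big, (0, 0): big, (0, 1): small}
    elif imp_type == HIGH_LOW:  # sparse hh
        cells = {(1, 0): big, (0, 1): big, (0, 0): small}
    else:
        raise ValueError(f"unknown implication type {imp_type!r}")
    out: list[tuple[int, int]] = []
    for cell, count in cells.items():
        out.extend([cell] * count)
    return out


def _balanced_vector(n: int, rng: np.random.Generator) -> np.ndarray:
    v = np.zeros(n, dtype=np.int8)
    v[: n // 2] = 1
    rng.shuffle(v)
    return v


def _states_for_condition(
    features: list[str],
    planted: list[PlantedPair],
    block: list[str],
    n: int,
    rng: np.random.Generator,
    block_shared: bool,
) -> np.ndarray:
    """(n_samples, n_features) low/high state matrix for one condition."""
    idx = {f: i for i, f in enumerate(features)}
    states = rng.integers(0, 2, size=(n, len(features)), dtype=np.int8)
    for pair in planted:
        joint = _quadrant_template(pair.type, n)
        order = rng.permutation(n)
        for pos, (sa, sb) in zip(order, joint):
            states[pos, idx[pair.a]] = sa
            states[pos, idx[pair.b]] = sb
    if block_shared and block:
        shared = _balanced_vector(n, rng)
        for f in block:
            states[:, idx[f]] = shared
    return states


def generate_cohort(spec: PlantSpec | None = None) -> Cohort:
    """Generate paired raw expression/methylation matrices for GAIN and DIS.

    All randomness flows from one generator seeded with ``spec.seed``; the
    same spec reproduces byte-identical cohorts.  The truth record lists
    every planted edge (present in both conditions) and the aberration block
    (GAIN-specific co-activation).
    """
    if spec is None:
        spec = default_spec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    probes = [_probe_id(i) for i in range(spec.n_probes)]
    for pair in spec.planted_expression:
        if pair.a not in genes or pair.b not in genes:
            raise ValueError(f"planted gene pair {pair} outside the gene list")
    n = spec.n_samples
    gain_samples = [f"GAIN_{i + 1:02d}" for i in range(n)]
    dis_samples = [f"DIS_{i + 1:02d}" for i in range(n)]

    def _values(features, planted, block, modes, block_probe=False):
        parts = []
        for cond, shared in (("GAIN", True), ("DIS", False)):
            states = _states_for_condition(
                features, planted, block if shared else [], n, rng, shared
            )
            vals = np.where(states == 1, modes[1], modes[0]).astype(float)
            vals = vals + rng.normal(0.0, spec.sigma, size=vals.shape)
            parts.append(vals)
        return np.vstack(parts)

    expr_log2 = _values(
        genes, spec.planted_expression, spec.aberration_genes, spec.expr_modes
    )
    meth_m = _values(
        probes, spec.planted_methylation, spec.aberration_probes, spec.meth_modes
    )
    samples = gain_samples + dis_samples
    tpm = np.maximum(np.power(2.0, expr_log2) - 1.0, 0.0)
    beta = m_to_beta(meth_m)

    # annotations: aberration genes on the designated chromosome, the rest
    # cycled over chromosomes 1..19
    block_set = set(spec.aberration_genes)
    chroms, arms = [], []
    c = 0
    for g in genes:
        if g in block_set:
            chroms.append(spec.aberration_chromosome)
        else:
            chroms.append(str(c % 19 + 1))
            c += 1
        arms.append("q")
    gene_annotation = pd.DataFrame(
        {"gene_id": genes, "chromosome": chroms, "arm": arms}
    ).set_index("gene_id")

    # probes: methylation-block probes sit on aberration-block genes
    # (promoter region); other probes cycle over the remaining genes
    probe_gene: dict[str, str] = {}
    block_probes = list(spec.aberration_probes)
    for p, g in zip(block_probes, spec.aberration_genes):
        probe_gene[p] = g
    others = [g for g in genes if g not in block_set]
    oi = 0
    for p in probes:
        if p not in probe_gene:
            probe_gene[p] = others[oi % len(others)]
            oi += 1
    regions = []
    ri = 0
    for p in probes:
        if p in set(block_probes):
            regions.append("TSS200")
        else:
            regions.append(REGION_CATEGORIES[ri % len(REGION_CATEGORIES)])
            ri += 1
    probe_annotation = pd.DataFrame(
        {
            "feature_id": probes,
            "gene_id": [probe_gene[p] for p in probes],
            "chromosome": [gene_annotation.loc[probe_gene[p], "chromosome"] for p in probes],
            "arm": ["q"] * len(probes),
            "region_category": regions,
        }
    ).set_index("feature_id")

    expression = FeatureMatrix(
        values=pd.DataFrame(tpm, index=samples, columns=genes),
        modality=EXPRESSION,
        scale=RAW,
        feature_meta=gene_annotation.reindex(genes),
    )
    methylation = FeatureMatrix(
        values=pd.DataFrame(beta, index=samples, columns=probes),
        modality=METHYLATION,
        scale=RAW,
        feature_meta=probe_annotation.reindex(probes),
    )
    sample_info = pd.Series(
        ["GAIN"] * n + ["DIS"] * n, index=samples, name="group"
    )
    comparison = pd.DataFrame({"GAIN_vs_DIS": [1, -1]}, index=["GAIN", "DIS"])
    truth = {
        "seed": spec.seed,
        "n_samples_per_condition": n,
        "sigma": spec.sigma,
        "planted_expression": [
            [p.a, p.b, p.type] for p in spec.planted_expression
        ],
        "planted_methylation": [
            [p.a, p.b, p.type] for p in spec.planted_methylation
        ],
        "aberration_genes": list(spec.aberration_genes),
        "aberration_probes": list(spec.aberration_probes),
        "aberration_chromosome": spec.aberration_chromosome,
    }
    return Cohort(
        expression=expression,
        methylation=methylation,
        sample_info=sample_info,
        comparison=comparison,
        gene_annotation=gene_annotation,
        probe_annotation=probe_annotation,
        truth=truth,
    )


def generate_toy_metapathway(cohort: Cohort | None = None) -> pd.DataFrame:
    """Deterministic small metapathway edge list over cohort gene ids.

    Chains the aberration-block genes and links planted genes pairwise so
    that cross-layer paths (mRNA -> MP -> CH3) exist in assembled networks.
    """
    if cohort is None:
        cohort = generate_cohort(default_spec())
    genes = list(cohort.gene_annotation.index)
    block = cohort.truth["aberration_genes"]
    edges = []
    for a, b in zip(block, block[1:]):
        edges.append((a, b))
    planted = [g for pair in cohort.truth["planted_expression"] for g in pair[:2]]
    for a, b in zip(planted, planted[1:]):
        edges.append((a, b))
    if planted and block:
        edges.append((planted[-1], block[0]))
    for g in genes[:6]:
        if block:
            edges.append((g, block[0]))
    return pd.DataFrame(edges, columns=["source", "target"]).drop_duplicates()


def generate_toy_gmt(cohort: Cohort | None = None) -> dict[str, list[str]]:
    """Twelve deterministic gene sets over the cohort's genes."""
    if cohort is None:
        cohort = generate_cohort(default_spec())
    genes = list(cohort.gene_annotation.index)
    block = list(cohort.truth["aberration_genes"])
    sets: dict[str, list[str]] = {"ABERRATION_BLOCK": block}
    for i in range(11):
        start = (i * 7) % max(len(genes) - 8, 1)
        sets[f"SET_{i + 1:02d}"] = genes[start : start + 8]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            fh.write("\t".join([name, "synthetic"] + list(sets[name])) + "\n")


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write a cohort in the TSV dialects the input readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "sample_info": outdir / "sample_info.tsv",
        "comparison": outdir / "comparison.tsv",
        "gene_annotation": outdir / "gene_annotation.tsv",
        "probe_annotation": outdir / "probe_annotation.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.values.T.to_csv(paths["expression"], sep="\t", index_label="feature_id")
    cohort.methylation.values.T.to_csv(paths["methylation"], sep="\t", index_label="feature_id")
    cohort.sample_info.rename_axis("sample_id").to_frame("group").to_csv(
        paths["sample_info"], sep="\t"
    )
    cohort.comparison.rename_axis("group").to_csv(paths["comparison"], sep="\t")
    cohort.gene_annotation.rename_axis("feature_id").to_csv(
        paths["gene_annotation"], sep="\t"
    )
    cohort.probe_annotation.to_csv(paths["probe_annotation"], sep="\t")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


# -- deterministic multilayer fixtures --------------------------------------


def _simple_net(condition: str, nodes: list[MLNode], edges: list[MLEdge]) -> MultiLayerNetwork:
    net = MultiLayerNetwork(condition=condition)
    for n in nodes:
        net.add_node(n)
    for e in edges:
        net.add_edge(e)
    return net


def _gene_node(layer: str, gene: str, chromosome: str) -> MLNode:
    kind = KIND_GENE if layer != LAYER_CH3 else KIND_CPG
    return MLNode(layer, gene, kind, gene_id=gene, annotations={"chromosome": chromosome})


def generate_toy_multilayer() -> dict:
    """Deterministic <= 30-node fixtures for path and differential queries.

    Path fixtures map name -> MultiLayerNetwork; condition fixtures map
    name -> (gain, dis) network pairs:

    - ``chr20_path``: exactly one mRNA->CH3 simple path (3 edges) under a
      chromosome-20 filter.
    - ``branching``: a larger mixed-chromosome graph exercising branching,
      dead ends and the direct mRNA-CH3 inter edge.
    - ``disjoint`` / ``nested`` / ``mixed`` / ``mixed_chr`` / ``mixed_cpg`` /
      ``gene_grouping``: condition pairs with hand-computable differential
      percentages (100%, 0%, 33.33%, 20% on chr20, 25% TSS200, 0% at gene
      grouping).
    """
    fixtures: dict = {}

    # one path: g1(mRNA) -inter- g1(MP) -> g2(MP) -inter- cpg_g2(CH3)
    n_m1 = _gene_node(LAYER_MRNA, "g1", "20")
    n_p1 = _gene_node(LAYER_MP, "g1", "20")
    n_p2 = _gene_node(LAYER_MP, "g2", "20")
    n_c2 = MLNode(LAYER_CH3, "cpg_g2", KIND_CPG, gene_id="g2",
                  annotations={"chromosome": "20", "region_category": "TSS200"})
    fixtures["chr20_path"] = _simple_net(
        "chr20_path",
        [n_m1, n_p1, n_p2, n_c2],
        [
            MLEdge(n_m1.key, n_p1.key, INTER, False, "same_gene"),
            MLEdge(n_p1.key, n_p2.key, INTRA, True, "metapathway"),
            MLEdge(n_p2.key, n_c2.key, INTER, False, "same_gene"),
        ],
    )

    # branching graph with mixed chromosomes and a chain exceeding short cutoffs
    nodes = [
        _gene_node(LAYER_MRNA, "a", "20"),
        _gene_node(LAYER_MRNA, "b", "8"),
        _gene_node(LAYER_MP, "a", "20"),
        _gene_node(LAYER_MP, "c", "20"),
        _gene_node(LAYER_MP, "d", "20"),
        _gene_node(LAYER_MP, "e", "3"),
        MLNode(LAYER_CH3, "cpg_c", KIND_CPG, "c", {"chromosome": "20", "region_category": "Body"}),
        MLNode(LAYER_CH3, "cpg_d", KIND_CPG, "d", {"chromosome": "20", "region_category": "TSS1500"}),
        MLNode(LAYER_CH3, "cpg_b", KIND_CPG, "b", {"chromosome": "8", "region_category": "Body"}),
    ]
    k = {n.entity_id + ":" + n.layer: n.key for n in nodes}
    edges = [
        MLEdge(k["a:mRNA"], k["a:MP"], INTER, False, "same_gene"),
        MLEdge(k["a:MP"], k["c:MP"], INTRA, True, "metapathway"),
        MLEdge(k["c:MP"], k["d:MP"], INTRA, True, "metapathway"),
        MLEdge(k["a:MP"], k["e:MP"], INTRA, True, "metapathway"),
        MLEdge(k["c:MP"], k["cpg_c:CH3"], INTER, False, "same_gene"),
        MLEdge(k["d:MP"], k["cpg_d:CH3"], INTER, False, "same_gene"),
        MLEdge(k["b:mRNA"], k["cpg_b:CH3"], INTER, False, "same_gene"),
        MLEdge(k["cpg_c:CH3"], k["cpg_d:CH3"], INTRA, True, "boolean_meth"),
    ]
    fixtures["branching"] = _simple_net("branching", nodes, edges)

    def _mrna_net(cond, gene_chrom: dict[str, str]):
        return _simple_net(
            cond, [_gene_node(LAYER_MRNA, g, c) for g, c in gene_chrom.items()], []
        )

    fixtures["disjoint"] = (
        _mrna_net("gain", {"A": "1", "B": "2"}),
        _mrna_net("dis", {"C": "1", "D": "2"}),
    )
    fixtures["nested"] = (
        _mrna_net("gain", {"A": "1", "B": "2"}),
        _mrna_net("dis", {"A": "1", "B": "2", "C": "3"}),
    )
    fixtures["mixed"] = (
        _mrna_net("gain", {"A": "1", "B": "2", "C": "3"}),
        _mrna_net("dis", {"B": "2", "C": "3", "D": "4"}),
    )
    # 10-gene layer, 3 differential of which 2 on chr20 -> 20% at chr20
    gain_chroms = {f"N{i:02d}": "1" for i in range(4, 11)}
    gain_chroms.update({"N01": "20", "N02": "20", "N03": "5"})
    fixtures["mixed_chr"] = (
        _mrna_net("gain", gain_chroms),
        _mrna_net("dis", {f"N{i:02d}": "1" for i in range(4, 11)}),
    )

    def _cpg(net_cond, probes):
        nodes = [
            MLNode(LAYER_CH3, p, KIND_CPG, gene_id=g,
                   annotations={"chromosome": "1", "region_category": r})
            for p, g, r in probes
        ]
        return _simple_net(net_cond, nodes, [])

    fixtures["mixed_cpg"] = (
        _cpg("gain", [("p1", "g1", "TSS200"), ("p2", "g1", "Body"),
                      ("p3", "g2", "TSS1500"), ("p4", "g2", "Body")]),
        _cpg("dis", [("p2", "g1", "Body"), ("p3", "g2", "TSS1500"),
                     ("p4", "g2", "Body")]),
    )
    fixtures["gene_grouping"] = (
        _cpg("gain", [("g1_p1", "g1", "TSS200"), ("g1_p2", "g1", "Body")]),
        _cpg("dis", [("g1_p3", "g1", "TSS1500")]),
    )
    return fixtures
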