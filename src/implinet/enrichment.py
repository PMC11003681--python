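"""Hypergeometric over-representation analysis on user-supplied gene sets.

Given a query gene set (e.g. the differential nodes of a condition network),
each named set of a GMT collection is tested for over-representation with the
upper-tail hypergeometric probability P(X >= k) for an overlap of k out of a
query of n, a set of K, and a universe of N genes, followed by
Benjamini-Hochberg adjustment across all sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a common universe."""

    sets: dict[str, frozenset]
    universe: frozenset

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        """Parse a GMT file (name, description, genes...), tab-separated."""
        sets: dict[str, frozenset] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                genes = frozenset(g for g in parts[2:] if g)
                if genes:
                    sets[parts[0]] = genes
        if universe is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets=sets, universe=frozenset(universe)).restrict()

    def restrict(self) -> "GeneSetCollection":
        """Drop genes outside the universe; empty sets are removed."""
        sets = {}
        for name, genes in self.sets.items():
            kept = genes & self.universe
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=self.universe)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # universe size
    p: float
    adjusted_p: float
    significant: bool
    genes: tuple
    gene_ratio: float
    gene_log_fc: dict = field(default_factory=dict, compare=False)


def ora(query, collection: GeneSetCollection, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Over-representation of a query gene set in every collection set.

    Query genes outside the universe are dropped with a warning.  Results are
    sorted by adjusted p, then name.  ``gene_ratio`` is overlap / query size.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    q = frozenset(query)
    dropped = q - collection.universe
    if dropped:
        log.warning("%d query gene(s) outside the universe dropped", len(dropped))
    q &= collection.universe
    N = len(collection.universe)
    n = len(q)
    names = sorted(collection.sets)
    pvals = []
    overlaps = []
    for name in names:
        s = collection.sets[name]
        k = len(q & s)
        overlaps.append(k)
        # upper tail P(X >= k); k = 0 gives p = 1
        pvals.append(float(hypergeom.sf(k - 1, N, len(s), n)) if n else 1.0)
    if not names:
        return []
    adj = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for name, k, p, ap in zip(names, overlaps, pvals, adj):
        results.append(
            EnrichmentResult(
                name=name,
                k=k,
                K=len(collection.sets[name]),
                n=n,
                N=N,
                p=p,
                adjusted_p=float(ap),
                significant=bool(ap <= alpha),
                genes=tuple(sorted(q & collection.sets[name])),
                gene_ratio=(k / n) if n else 0.0,
            )
        )
    results.sort(key=lambda r: (r.adjusted_p, r.name))
    return results


def combine_conditions(
    res_gain: list[EnrichmentResult],
    res_dis: list[EnrichmentResult],
    genes_gain,
    genes_dis,
    log_fc: dict[str, float] | None = None,
    cap: float = 2.0,
) -> list[EnrichmentResult]:
    """Combine two conditions' results, keeping only GAIN-exclusive genes.

    The union of significant set names from both conditions is reported, but
    each contributing-gene list is restricted to genes present in the GAIN
    query and absent from the DIS query.  Optional per-gene logFC values
    (e.g. vs a normal-tissue group) are attached, capped to +/- ``cap`` for
    heat-report export.
    """
    exclusive = frozenset(genes_gain) - frozenset(genes_dis)
    by_name = {r.name: r for r in res_gain}
    names = sorted(
        {r.name for r in res_gain if r.significant}
        | {r.name for r in res_dis if r.significant}
    )
    out = []
    for name in names:
        base = by_name.get(name)
        genes = tuple(g for g in (base.genes if base else ()) if g in exclusive)
        lfc = {}
        if log_fc:
            lfc = {
                g: float(np.clip(log_fc.get(g, 0.0), -cap, cap)) for g in genes
            }
        if base is not None:
            out.append(
                EnrichmentResult(
                    name=base.name,
                    k=base.k,
                    K=base.K,
                    n=base.n,
                    N=base.N,
                    p=base.p,
                    adjusted_p=base.adjusted_p,
                    significant=base.significant,
                    genes=genes,
                    gene_ratio=base.gene_ratio,
                    gene_log_fc=lfc,
                )
            )
    out.sort(key=lambda r: (r.adjusted_p, r.name))
    return out
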