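"""Boolean implication detection from sparse-quadrant statistics.

For every feature pair, samples are placed in a 2x2 low/high contingency
table (intermediate labels dropped).  A quadrant is *sparse* when its observed
count falls far below the independence expectation:

    s_stat     = (expected - observed) / sqrt(expected)
    error_rate = 1/2 * (observed / rowTotal + observed / colTotal)

with ``expected = rowTotal * colTotal / n_eff``.  A quadrant is declared
sparse when ``s_stat > s_threshold`` and ``error_rate < p_cutoff``.  The
sparse-quadrant pattern maps onto six implication types: one sparse quadrant
gives an asymmetric implication (e.g. sparse low-low means "A low => B high"),
the symmetric pairs {low-high, high-low} and {low-low, high-high} give the
equivalent (strong positive) and opposite (strong negative) types.

A permutation scheme estimates the false discovery rate: each permutation
shuffles every feature's values across samples independently, destroying
pairwise structure while preserving marginals; the FDR is the mean permuted
edge count over the observed edge count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import FeatureMatrix
from .stepminer import HIGH, LOW, StepFit, fit_step

log = logging.getLogger(__name__)

LOW_LOW = "low=>low"
LOW_HIGH = "low=>high"
HIGH_LOW = "high=>low"
HIGH_HIGH = "high=>high"
EQUIVALENT = "equivalent"
OPPOSITE = "opposite"
IMPLICATION_TYPES = (LOW_LOW, LOW_HIGH, HIGH_LOW, HIGH_HIGH, EQUIVALENT, OPPOSITE)
SYMMETRIC_TYPES = (EQUIVALENT, OPPOSITE)

#: quadrant ids: first letter = feature A level, second = feature B level
QUADRANTS = ("ll", "lh", "hl", "hh")

# single sparse quadrant -> asymmetric type (sparse ll means A low => B high)
_ASYMMETRIC = {"ll": LOW_HIGH, "lh": LOW_LOW, "hl": HIGH_HIGH, "hh": HIGH_LOW}


@dataclass(frozen=True)
class QuadrantCounts:
    """2x2 low/high contingency counts for a feature pair (A rows, B cols)."""

    a_ll: int
    a_lh: int
    a_hl: int
    a_hh: int

    @property
    def n_eff(self) -> int:
        return self.a_ll + self.a_lh + self.a_hl + self.a_hh

    def observed(self, quadrant: str) -> int:
        return getattr(self, f"a_{quadrant}")

    def margins(self, quadrant: str) -> tuple[int, int]:
        """(row total of A's level, column total of B's level) for a quadrant."""
        row = self.a_ll + self.a_lh if quadrant[0] == "l" else self.a_hl + self.a_hh
        col = self.a_ll + self.a_hl if quadrant[1] == "l" else self.a_lh + self.a_hh
        return row, col


@dataclass(frozen=True)
class SparsityResult:
    quadrant: str
    observed: int
    expected: float
    s_stat: float
    error_rate: float
    testable: bool = True


@dataclass(frozen=True)
class BooleanImplication:
    """A detected implication between two features (A = source, B = target)."""

    source: str
    target: str
    type: str
    counts: QuadrantCounts
    sparse_quadrants: tuple[str, ...]
    stats: dict[str, SparsityResult] = field(compare=False)

    @property
    def symmetric(self) -> bool:
        return self.type in SYMMETRIC_TYPES


@dataclass
class ImplicationNetwork:
    """All implications inferred over one modality's feature matrix."""

    features: list[str]
    edges: list[BooleanImplication]
    params: dict
    skipped: list[str] = field(default_factory=list)
    feature_meta: pd.DataFrame | None = None

    @property
    def edge_features(self) -> set[str]:
        return {e.source for e in self.edges} | {e.target for e in self.edges}


def quadrant_counts(labels_a, labels_b) -> QuadrantCounts:
    """Count low/high co-occurrences, dropping samples with an intermediate."""
    la = np.asarray(labels_a, dtype=object)
    lb = np.asarray(labels_b, dtype=object)
    if la.shape != lb.shape:
        raise ValueError("label vectors must have equal length")
    al = la == LOW
    ah = la == HIGH
    bl = lb == LOW
    bh = lb == HIGH
    return QuadrantCounts(
        a_ll=int((al & bl).sum()),
        a_lh=int((al & bh).sum()),
        a_hl=int((ah & bl).sum()),
        a_hh=int((ah & bh).sum()),
    )


def sparsity_test(c: QuadrantCounts, quadrant: str) -> SparsityResult:
    """Sparsity statistic and error rate for one quadrant of a count table."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    row, col = c.margins(quadrant)
    obs = c.observed(quadrant)
    if row == 0 or col == 0 or c.n_eff == 0:
        return SparsityResult(quadrant, obs, 0.0, float("nan"), float("nan"), False)
    expected = row * col / c.n_eff
    s_stat = (expected - obs) / math.sqrt(expected)
    error_rate = 0.5 * (obs / row + obs / col)
    return SparsityResult(quadrant, obs, expected, s_stat, error_rate, True)


def classify_pair(
    c: QuadrantCounts,
    s_threshold: float,
    p_cutoff: float,
    source: str = "A",
    target: str = "B",
) -> BooleanImplication | None:
    """Map the sparse-quadrant pattern of a count table onto the six types.

    Returns None when no quadrant (or a degenerate pattern of sparse
    quadrants, e.g. an entire empty row) is found.
    """
    if c.n_eff == 0:
        return None
    results = {q: sparsity_test(c, q) for q in QUADRANTS}
    sparse = tuple(
        q
        for q in QUADRANTS
        if results[q].testable
        and results[q].s_stat > s_threshold
        and results[q].error_rate < p_cutoff
    )
    spset = set(sparse)
    if len(sparse) == 1:
        imp_type = _ASYMMETRIC[sparse[0]]
    elif spset == {"lh", "hl"}:
        imp_type = EQUIVALENT
    elif spset == {"ll", "hh"}:
        imp_type = OPPOSITE
    else:
        return None
    return BooleanImplication(
        source=source,
        target=target,
        type=imp_type,
        counts=c,
        sparse_quadrants=sparse,
        stats={q: results[q] for q in sparse},
    )


def _label_codes(
    m: FeatureMatrix, margin: float
) -> tuple[list[str], np.ndarray, list[str], dict[str, StepFit]]:
    """Step-fit every feature and code labels as ints (0 low, 1 high, 2 mid)."""
    feats = sorted(m.feature_ids)
    arr = m.values[feats].to_numpy()
    codes = np.full((len(feats), arr.shape[0]), 2, dtype=np.int8)
    skipped: list[str] = []
    fits: dict[str, StepFit] = {}
    for i, fid in enumerate(feats):
        f = fit_step(arr[:, i])
        fits[fid] = f
        if f.degenerate:
            skipped.append(fid)
            continue
        x = arr[:, i]
        codes[i, x < f.threshold - margin] = 0
        codes[i, x > f.threshold + margin] = 1
    return feats, codes, skipped, fits


def infer_network(
    m: FeatureMatrix,
    s_threshold: float,
    p_cutoff: float = 0.01,
    margin: float = 0.5,
    min_group: int = 5,
) -> ImplicationNetwork:
    """Evaluate every unordered feature pair and collect implications.

    Features with a degenerate step fit, or with fewer than ``min_group``
    samples on either side of their threshold, are excluded from pair
    enumeration.  Symmetric implications are emitted once; asymmetric
    implications are emitted as a directed edge from the lexicographically
    smaller feature.  Edge order is lexicographic by (source, target).
    """
    feats, codes, skipped, _ = _label_codes(m, margin)
    keep_idx = []
    for i, fid in enumerate(feats):
        if fid in set(skipped):
            continue
        n_low = int((codes[i] == 0).sum())
        n_high = int((codes[i] == 1).sum())
        if n_low < min_group or n_high < min_group:
            skipped.append(fid)
            continue
        keep_idx.append(i)
    kept = [feats[i] for i in keep_idx]
    L = (codes[keep_idx] == 0).astype(np.float64)
    H = (codes[keep_idx] == 1).astype(np.float64)
    ll = L @ L.T
    lh = L @ H.T
    hl = H @ L.T
    hh = H @ H.T
    edges: list[BooleanImplication] = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            c = QuadrantCounts(
                int(ll[i, j]), int(lh[i, j]), int(hl[i, j]), int(hh[i, j])
            )
            imp = classify_pair(c, s_threshold, p_cutoff, kept[i], kept[j])
            if imp is not None:
                edges.append(imp)
    meta = None
    if m.feature_meta is not None:
        meta = m.feature_meta.reindex(kept)
    return ImplicationNetwork(
        features=kept,
        edges=edges,
        params={
            "s_threshold": s_threshold,
            "p_cutoff": p_cutoff,
            "margin": margin,
            "min_group": min_group,
        },
        skipped=sorted(skipped),
        feature_meta=meta,
    )


def estimate_fdr(
    m: FeatureMatrix,
    s_threshold: float,
    p_cutoff: float = 0.01,
    n_perm: int = 20,
    seed: int = 0,
    margin: float = 0.5,
    min_group: int = 5,
) -> float:
    """Permutation false-discovery rate for an inferred implication network.

    Each permutation shuffles every feature's values across samples
    independently; FDR = mean permuted edge count / observed edge count.
    Returns NaN when no edges are observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = len(infer_network(m, s_threshold, p_cutoff, margin, min_group).edges)
    if observed == 0:
        log.warning("no observed edges; permutation FDR undefined")
        return float("nan")
    rng = np.random.default_rng(seed)
    arr = m.values.to_numpy()
    counts = []
    for _ in range(n_perm):
        perm = np.empty_like(arr)
        for j in range(arr.shape[1]):
            perm[:, j] = rng.permutation(arr[:, j])
        pm = FeatureMatrix(
            values=pd.DataFrame(perm, index=m.values.index, columns=m.values.columns),
            modality=m.modality,
            scale=m.scale,
        )
        counts.append(len(infer_network(pm, s_threshold, p_cutoff, margin, min_group).edges))
    return float(np.mean(counts) / observed)


def edges_to_frame(net: ImplicationNetwork) -> pd.DataFrame:
    """Edge list table: source, target, type, per-quadrant stats, n_eff.

    Rows are sorted lexicographically by (source, target); the second stat
    pair is NaN for asymmetric (single sparse quadrant) implications.
    """
    rows = []
    for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
        stats = [e.stats[q] for q in e.sparse_quadrants]
        rows.append(
            {
                "source": e.source,
                "target": e.target,
                "type": e.type,
                "s_stat_1": stats[0].s_stat,
                "err_1": stats[0].error_rate,
                "s_stat_2": stats[1].s_stat if len(stats) > 1 else float("nan"),
                "err_2": stats[1].error_rate if len(stats) > 1 else float("nan"),
                "n_eff": e.counts.n_eff,
            }
        )
    cols = ["source", "target", "type", "s_stat_1", "err_1", "s_stat_2", "err_2", "n_eff"]
    return pd.DataFrame(rows, columns=cols)
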