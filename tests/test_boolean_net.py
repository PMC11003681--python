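import math

import numpy as np
import pandas as pd
import pytest

import implinet as im
from implinet.boolean_net import QUADRANTS
from tests.conftest import bimodal_matrix


def naive_infer(matrix, s_threshold, p_cutoff, margin=0.5, min_group=5):
    """All-pairs oracle: per-feature step fit + label vectors + classify_pair."""
    feats = sorted(matrix.feature_ids)
    labels = {}
    for fid in feats:
        v = matrix.values[fid].to_numpy()
        fit = im.fit_step(v)
        if fit.degenerate:
            continue
        lab = im.discretize(v, fit, margin)
        n_low = (lab == "low").sum()
        n_high = (lab == "high").sum()
        if n_low < min_group or n_high < min_group:
            continue
        labels[fid] = lab
    edges = []
    kept = [f for f in feats if f in labels]
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            c = im.quadrant_counts(labels[a], labels[b])
            imp = im.classify_pair(c, s_threshold, p_cutoff, a, b)
            if imp is not None:
                edges.append(imp)
    return edges


class TestQuadrantCounts:
    def test_intermediate_samples_dropped(self):
        a = ["low", "low", "high", "high", "intermediate"]
        b = ["low", "high", "low", "high", "low"]
        c = im.quadrant_counts(a, b)
        assert (c.a_ll, c.a_lh, c.a_hl, c.a_hh) == (1, 1, 1, 1)
        assert c.n_eff == 4

    def test_all_intermediate_gives_zeros(self):
        c = im.quadrant_counts(["intermediate"] * 3, ["low", "high", "low"])
        assert c.n_eff == 0

    def test_single_quadrant(self):
        c = im.quadrant_counts(["low"] * 3, ["high"] * 3)
        assert (c.a_ll, c.a_lh, c.a_hl, c.a_hh) == (0, 3, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            im.quadrant_counts(["low"], ["low", "high"])


class TestSparsityTest:
    def test_worked_example(self):
        # margins 50/50 over n=100, observed 5: expected 25, s = 20/5 = 4
        c = im.QuadrantCounts(5, 45, 45, 5)
        r = im.sparsity_test(c, "ll")
        assert r.expected == pytest.approx(25.0)
        assert r.s_stat == pytest.approx(4.0)
        assert r.error_rate == pytest.approx(0.1)

    def test_observed_equals_expected_zero_s(self):
        c = im.QuadrantCounts(25, 25, 25, 25)
        assert im.sparsity_test(c, "hh").s_stat == pytest.approx(0.0)

    def test_empty_quadrant(self):
        # margins 40/40 over n=100: expected 16, s = 16/4 = 4, error 0
        c = im.QuadrantCounts(0, 40, 40, 20)
        r = im.sparsity_test(c, "ll")
        assert r.expected == pytest.approx(16.0)
        assert r.s_stat == pytest.approx(4.0)
        assert r.error_rate == 0.0

    def test_zero_margin_untestable(self):
        c = im.QuadrantCounts(0, 0, 3, 3)
        assert not im.sparsity_test(c, "ll").testable


class TestClassifyPair:
    def test_single_sparse_quadrant_is_asymmetric(self):
        c = im.QuadrantCounts(0, 40, 40, 20)
        imp = im.classify_pair(c, s_threshold=3, p_cutoff=0.1)
        assert imp.type == "low=>high"
        assert imp.sparse_quadrants == ("ll",)

    def test_error_rate_bound_blocks_populated_quadrant(self):
        # at s=2 the hh quadrant clears the s bound (s≈2.67) but its error
        # rate 1/2(20/60+20/60)=0.33 fails p_cutoff=0.1, so the type stays
        # asymmetric
        c = im.QuadrantCounts(0, 40, 40, 20)
        imp = im.classify_pair(c, s_threshold=2, p_cutoff=0.1)
        assert imp.type == "low=>high"

    def test_two_opposite_sparse_quadrants_symmetric(self):
        c = im.QuadrantCounts(0, 40, 40, 20)
        imp = im.classify_pair(c, s_threshold=2, p_cutoff=0.4)
        assert imp.type == "opposite"
        assert set(imp.sparse_quadrants) == {"ll", "hh"}

    def test_uniform_counts_no_implication(self):
        c = im.QuadrantCounts(25, 25, 25, 25)
        assert im.classify_pair(c, 3, 0.1) is None

    def test_contrapositive_under_operand_swap(self):
        # A low => B high must become B low => A high when operands swap
        c = im.QuadrantCounts(0, 40, 40, 20)
        swapped = im.QuadrantCounts(c.a_ll, c.a_hl, c.a_lh, c.a_hh)
        fwd = im.classify_pair(c, 3, 0.1, "A", "B")
        rev = im.classify_pair(swapped, 3, 0.1, "B", "A")
        assert fwd.type == rev.type == "low=>high"

    def test_stored_stats_reproducible(self):
        c = im.QuadrantCounts(0, 40, 40, 20)
        imp = im.classify_pair(c, 3, 0.1)
        for q in imp.sparse_quadrants:
            again = im.sparsity_test(imp.counts, q)
            assert again == imp.stats[q]


class TestInferNetwork:
    def test_copied_feature_gives_equivalent_edge(self):
        rng = np.random.default_rng(7)
        m = bimodal_matrix(rng, 2, 20, copies={1: 0})
        net = im.infer_network(m, s_threshold=2.0, p_cutoff=0.1, min_group=3)
        assert len(net.edges) == 1
        assert net.edges[0].type == "equivalent"

    def test_independent_features_yield_few_edges(self):
        rng = np.random.default_rng(11)
        m = bimodal_matrix(rng, 10, 50)
        net = im.infer_network(m, s_threshold=3.0)
        assert len(net.edges) <= 1

    def test_single_feature_no_edges(self):
        rng = np.random.default_rng(1)
        m = bimodal_matrix(rng, 1, 20)
        assert im.infer_network(m, 3.0).edges == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        m = bimodal_matrix(rng, 10, 50, copies={4: 0, 7: 2})
        got = im.infer_network(m, s_threshold=2.5, p_cutoff=0.1)
        expected = naive_infer(m, s_threshold=2.5, p_cutoff=0.1)
        key = lambda e: (e.source, e.target)
        assert sorted(got.edges, key=key) == sorted(expected, key=key)
        assert len(got.edges) >= 2

    def test_raising_s_threshold_never_adds_edges(self):
        rng = np.random.default_rng(13)
        m = bimodal_matrix(rng, 8, 40, copies={3: 1})
        loose = {(e.source, e.target) for e in im.infer_network(m, 2.0, 0.1).edges}
        tight = {(e.source, e.target) for e in im.infer_network(m, 3.0, 0.1).edges}
        assert tight <= loose


class TestEstimateFdr:
    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(0)
        m = bimodal_matrix(rng, 4, 20)
        with pytest.raises(ValueError):
            im.estimate_fdr(m, 3.0, n_perm=0)

    def test_constant_matrix_undefined(self):
        m = im.FeatureMatrix(
            values=pd.DataFrame(
                np.ones((10, 3)), index=[f"s{i}" for i in range(10)], columns=list("abc")
            ),
            modality="expression",
            scale="log2tpm",
        )
        assert math.isnan(im.estimate_fdr(m, 3.0, n_perm=2))

    def test_seeded_runs_reproduce(self):
        rng = np.random.default_rng(2)
        m = bimodal_matrix(rng, 6, 30, copies={1: 0, 3: 2})
        a = im.estimate_fdr(m, 2.0, p_cutoff=0.1, n_perm=3, seed=9)
        b = im.estimate_fdr(m, 2.0, p_cutoff=0.1, n_perm=3, seed=9)
        assert a == b


def test_edge_table_sorted_and_complete(cohort_networks):
    gain, _ = cohort_networks
    frame = im.edges_to_frame(gain)
    assert len(frame) == len(gain.edges)
    pairs = list(zip(frame["source"], frame["target"]))
    assert pairs == sorted(pairs)
    sym = frame[frame["type"].isin(["equivalent", "opposite"])]
    assert sym["s_stat_2"].notna().all()
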