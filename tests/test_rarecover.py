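"""RareCover: window enumeration, union carriers, greedy vs exhaustive, permutation P."""

import numpy as np
import pytest

from extremeseq.core import MISSING
from extremeseq.rarecover import (
    LocusWindow,
    enumerate_windows,
    exhaustive_select,
    gene_wide_adjust,
    greedy_select,
    locus_permutation_p,
    union_carrier,
)
from extremeseq.rarecover import _carrier_minor, _greedy_stats, _label_permutations
from extremeseq.single_marker import _chi2_vectorized

from .conftest import make_matrix


def rare_matrix(carrier_columns, n_samples, positions=None):
    """Matrix of n_samples whose columns are het carriers at the given indices."""
    g = np.zeros((n_samples, len(carrier_columns)), dtype=np.int8)
    for j, col in enumerate(carrier_columns):
        for i in col:
            g[i, j] = 1
    return make_matrix(g, positions=positions)


class TestWindows:
    def test_anchoring_by_construction_rule(self):
        m = rare_matrix([[0], [1], [2]], 60, positions=[1000, 3000, 7000])
        wins = enumerate_windows(m, window_size=5000)
        assert [(w.start, [m.sites[j].pos for j in w.members]) for w in wins] == [
            (1000, [1000, 3000]),
            (3000, [3000, 7000]),
            (7000, [7000]),
        ]

    def test_maf_threshold_boundary_inclusive(self):
        # 60 samples: 12/120 alleles = 0.100 included, 13/120 = 0.108 excluded
        g = np.zeros((60, 2), dtype=np.int8)
        g[:12, 0] = 1
        g[:13, 1] = 1
        m = make_matrix(g, positions=[100, 200])
        wins = enumerate_windows(m, maf_threshold=0.1)
        members = {m.sites[j].pos for w in wins for j in w.members}
        assert members == {100}

    def test_no_rare_variants_empty(self):
        g = np.ones((10, 1), dtype=np.int8)  # MAF 0.5
        m = make_matrix(g)
        assert enumerate_windows(m, maf_threshold=0.1) == []

    def test_duplicate_member_sets_collapse_to_leftmost(self):
        m = rare_matrix([[0], [1]], 60, positions=[1000, 1000])
        wins = enumerate_windows(m, window_size=5000)
        assert len(wins) == 1 and wins[0].start == 1000

    def test_indels_excluded_by_default(self):
        g = np.zeros((40, 1), dtype=np.int8)
        g[0, 0] = 1
        m = make_matrix(g, var_class="indel")
        assert enumerate_windows(m) == []
        assert len(enumerate_windows(m, include_indels=True)) == 1


class TestUnionCarrier:
    def test_single_variant_equals_its_carrier_vector(self):
        m = rare_matrix([[0, 3]], 6)
        a, miss = union_carrier(m, [0])
        assert list(a) == [1, 0, 0, 1, 0, 0]
        assert miss == 0

    def test_hand_built_five_sample_union(self):
        g = np.array(
            [
                [1, 0],
                [0, 0],
                [MISSING, MISSING],
                [0, 2],
                [MISSING, 0],
            ],
            dtype=np.int8,
        )
        m = make_matrix(g)
        a, miss = union_carrier(m, [0, 1])
        # brute force per sample: any genotype > 0 among called members
        expected = [int(any(x > 0 for x in row if x != MISSING)) for row in g]
        assert list(a) == expected == [1, 0, 0, 1, 0]
        assert miss == 1  # sample 2 missing at every member

    def test_empty_subset_all_zero(self):
        m = rare_matrix([[0]], 4)
        a, miss = union_carrier(m, [])
        assert not a.any() and miss == 0

    def test_monotone_under_subset_growth(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(1, 0.1, (30, 6)).astype(np.int8)
        m = make_matrix(g)
        prev = np.zeros(30, dtype=np.uint8)
        for k in range(1, 7):
            a, _ = union_carrier(m, list(range(k)))
            assert (a >= prev).all()
            prev = a


class TestGreedy:
    def test_single_case_only_variant_selected(self):
        m = rare_matrix([[0, 1, 2]], 20)
        status = np.array([True] * 10 + [False] * 10)
        w = LocusWindow("g", 1000, 6000, [0])
        lv = greedy_select(w, m, status)
        assert lv.C == [0]
        assert lv.carrier_table == (3, 7, 0, 10)

    def test_spec_like_four_variant_instance_matches_exhaustive(self):
        # v1: 3 cases; v2: 2 other cases; v3: 2 controls; v4: 1 case + 1 control
        cols = [[0, 1, 2], [3, 4], [10, 11], [5, 12]]
        m = rare_matrix(cols, 20, positions=[100, 200, 300, 400])
        status = np.array([True] * 10 + [False] * 10)
        w = LocusWindow("g", 100, 5100, [0, 1, 2, 3])
        lv = greedy_select(w, m, status)
        assert lv.C == [0, 1]
        assert lv.carrier_table == (5, 5, 0, 10)
        a, b, c, d = (np.array([x], float) for x in lv.carrier_table)
        assert lv.stat == pytest.approx(float(_chi2_vectorized(a, b, c, d)[0]))
        ex = exhaustive_select(w, m, status)
        assert ex.stat == pytest.approx(lv.stat)
        assert ex.C == lv.C

    def test_duplicate_carrier_vectors_yield_single_member(self):
        cols = [[0, 1], [0, 1], [0, 1]]
        m = rare_matrix(cols, 20, positions=[100, 200, 300])
        status = np.array([True] * 10 + [False] * 10)
        w = LocusWindow("g", 100, 5100, [0, 1, 2])
        lv = greedy_select(w, m, status)
        assert lv.C == [0]  # leftmost; duplicates add no strict improvement

    def test_greedy_never_exceeds_exhaustive_and_stat_consistency(self):
        rng = np.random.default_rng(12)
        status = np.array([True] * 30 + [False] * 30)
        for _ in range(40):
            k = rng.integers(2, 7)
            g = rng.binomial(1, 0.08, (60, k)).astype(np.int8)
            m = make_matrix(g, positions=[100 * (j + 1) for j in range(k)])
            w = LocusWindow("g", 100, 5100, list(range(k)))
            lv = greedy_select(w, m, status)
            ex = exhaustive_select(w, m, status)
            assert lv.stat <= ex.stat + 1e-9

    def test_exhaustive_refuses_oversized_windows(self):
        g = np.zeros((4, 21), dtype=np.int8)
        g[0] = 1
        m = make_matrix(g, positions=list(range(100, 2200, 100)))
        w = LocusWindow("g", 100, 5100, list(range(21)))
        with pytest.raises(ValueError):
            exhaustive_select(w, m, np.array([True, True, False, False]), max_size=20)

    def test_single_member_greedy_equals_exhaustive(self):
        m = rare_matrix([[0, 5]], 20)
        status = np.array([True] * 10 + [False] * 10)
        w = LocusWindow("g", 1000, 6000, [0])
        assert greedy_select(w, m, status).stat == pytest.approx(
            exhaustive_select(w, m, status).stat
        )


class TestPermutation:
    def test_no_carriers_gives_p_one(self):
        m = make_matrix(np.zeros((20, 1), dtype=np.int8))
        status = np.array([True] * 10 + [False] * 10)
        w = LocusWindow("g", 1000, 6000, [0])
        assert locus_permutation_p(w, m, status, n_perm=200, seed=0) == 1.0

    def test_planted_signal_detected(self):
        # 12 case carriers, 0 control carriers out of 40/40
        cols = [list(range(6)), list(range(6, 12))]
        m = rare_matrix(cols, 80, positions=[100, 900])
        status = np.array([True] * 40 + [False] * 40)
        w = LocusWindow("g", 100, 5100, [0, 1])
        p = locus_permutation_p(w, m, status, n_perm=1000, seed=1)
        assert p < 0.01

    def test_gene_wide_dominates_locus_p_on_shared_permutations(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(1, 0.06, (60, 9)).astype(np.int8)
        m = make_matrix(g, positions=[100, 300, 700, 5200, 5400, 5900, 11000, 11500, 12000])
        status = np.array([True] * 30 + [False] * 30)
        windows = enumerate_windows(m, window_size=5000)
        assert len(windows) >= 3
        # same permutation stream for locus and gene-wide null distributions
        perm = _label_permutations(60, 30, 400, np.random.default_rng(99))
        carrier_sets = [_carrier_minor(m, w.members) for w in windows]
        per_window = np.stack([_greedy_stats(c, perm) for c in carrier_sets])
        gene_max = per_window.max(axis=0)
        observed = np.array([greedy_select(w, m, status).stat for w in windows])
        p_locus = (1 + (per_window >= observed[:, None] - 1e-12).sum(axis=1)) / 401
        p_gene = (1 + (gene_max[None, :] >= observed[:, None] - 1e-12).sum(axis=1)) / 401
        assert (p_gene >= p_locus).all()

    def test_single_window_gene_wide_close_to_locus_p(self):
        cols = [list(range(5))]
        m = rare_matrix(cols, 60, positions=[100])
        status = np.array([True] * 30 + [False] * 30)
        w = LocusWindow("g", 100, 5100, [0])
        pl = locus_permutation_p(w, m, status, n_perm=2000, seed=2)
        pg = gene_wide_adjust([w], m, status, n_perm_gene=2000, seed=3)[0]
        assert abs(pl - pg) < 0.05

    def test_frozen_subset_permutation_is_anticonservative(self):
        # freezing C (not re-optimizing per permutation) must inflate significance
        rng = np.random.default_rng(21)
        p_reopt, p_frozen = [], []
        status = np.array([True] * 30 + [False] * 30)
        for rep in range(30):
            g = rng.binomial(1, 0.07, (60, 6)).astype(np.int8)  # pure noise
            m = make_matrix(g, positions=[100 * (j + 1) for j in range(6)])
            w = LocusWindow("g", 100, 5100, list(range(6)))
            lv = greedy_select(w, m, status)
            p_reopt.append(locus_permutation_p(w, m, status, n_perm=300, seed=rep))
            # frozen: permute labels, keep the observed A_C fixed
            perm = _label_permutations(60, 30, 300, np.random.default_rng(1000 + rep))
            carrier = lv.A_C.astype(bool)
            cas = perm[:, carrier].sum(axis=1).astype(float)
            tot = float(carrier.sum())
            a, b = cas, 30 - cas
            c, d = tot - cas, 30 - (tot - cas)
            stats = _chi2_vectorized(a, b, c, d)
            p_frozen.append((1 + (stats >= lv.stat - 1e-12).sum()) / 301)
        assert np.mean(p_frozen) < np.mean(p_reopt)
        assert np.mean(np.array(p_frozen) < 0.05) > np.mean(np.array(p_reopt) < 0.05)
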