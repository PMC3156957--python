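"""Staged SNV QC: HWE test, genotype masking, filter cascade, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extremeseq.core import MISSING, VariantSite
from extremeseq.variant_qc import (
    classify_variants,
    compute_maf,
    hwe_exact_test,
    hwe_test,
    mask_genotypes,
    qc_filter_sites,
)

from .conftest import make_matrix


class TestHWE:
    def test_exact_proportions_give_zero_stat(self):
        stat, p, direction = hwe_test(25, 50, 25)
        assert stat == 0.0 and p == 1.0 and direction == "none"

    def test_het_deficit_statistic_matches_direct_expectation(self):
        # allele freq 0.6 over 100 genotypes -> expected counts 36 / 48 / 16
        obs = np.array([50, 20, 30])
        exp = np.array([36.0, 48.0, 16.0])
        oracle = float(((obs - exp) ** 2 / exp).sum())
        stat, p, direction = hwe_test(50, 20, 30)
        assert stat == pytest.approx(oracle)  # 34.03
        assert stat == pytest.approx(34.0278, abs=1e-3)
        assert direction == "deficit"
        assert p < 1e-6

    def test_monomorphic_site_passes(self):
        assert hwe_test(147, 0, 0) == (0.0, 1.0, "none")
        assert hwe_test(0, 0, 147) == (0.0, 1.0, "none")

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    @given(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_allele_swap(self, a, b, c):
        if a + b + c == 0:
            return
        s1, p1, d1 = hwe_test(a, b, c)
        s2, p2, d2 = hwe_test(c, b, a)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)
        assert d1 == d2

    def test_exact_test_agrees_with_chisq_at_moderate_counts(self):
        # at comfortable expected counts the two tests agree in verdict
        _, p_chi, _ = hwe_test(80, 60, 10)
        p_ex = hwe_exact_test(80, 60, 10)
        assert (p_chi < 0.05) == (p_ex < 0.05)

    def test_null_calibration_rejection_rate_below_two_per_mille(self):
        # 10,000 sites simulated at exact HWE: fail(hwe) at P < 0.001 in <= 0.2%
        rng = np.random.default_rng(42)
        n = 289
        rejected = 0
        for _ in range(10_000):
            q = rng.uniform(0.1, 0.5)
            g = rng.binomial(1, q, (n, 2)).sum(axis=1)
            _, p, _ = hwe_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            rejected += p < 1e-3
        assert rejected <= 20


class TestMasking:
    def test_low_depth_or_low_quality_masked_thresholds_strict(self):
        m = make_matrix([[1, 1, 1]], depth=[[2, 3, 10]], quality=[[40, 10, 9]])
        out = mask_genotypes(m)
        # depth 2 -> masked; depth 3 & quality 10 retained; quality 9 -> masked
        assert list(out.genotypes[0]) == [MISSING, 1, MISSING]

    def test_identity_when_all_pass_and_idempotent(self):
        m = make_matrix([[0, 1], [2, 1]], depth=3, quality=10)
        out = mask_genotypes(m)
        assert np.array_equal(out.genotypes, m.genotypes)
        twice = mask_genotypes(mask_genotypes(m))
        assert np.array_equal(twice.genotypes, out.genotypes)

    @given(st.integers(0, 50), st.integers(0, 60))
    @settings(max_examples=60, deadline=None)
    def test_masking_idempotent_property(self, depth, quality):
        m = make_matrix([[1]], depth=[[depth]], quality=[[quality]])
        once = mask_genotypes(m)
        twice = mask_genotypes(once)
        assert np.array_equal(once.genotypes, twice.genotypes)


class TestMAF:
    def test_single_het_among_289_fully_called(self):
        g = np.zeros((289, 1), dtype=np.int8)
        g[0, 0] = 1
        maf, count = compute_maf(make_matrix(g), 0)
        assert count == 1
        assert maf == pytest.approx(1 / 578)
        assert round(maf, 3) == 0.002

    def test_all_homalt_minor_is_reference(self):
        maf, count = compute_maf(make_matrix(2 * np.ones((10, 1))), 0)
        assert maf == 0.0 and count == 0

    def test_hand_counted_frequency(self):
        # 123 alt alleles over 578: 61 hom-alt + 1 het among 289
        g = np.zeros((289, 1), dtype=np.int8)
        g[:61, 0] = 2
        g[61, 0] = 1
        maf, count = compute_maf(make_matrix(g), 0)
        assert count == 123
        assert maf == pytest.approx(123 / 578)
        assert round(maf, 3) == 0.213

    def test_missing_excluded_from_denominator(self):
        g = np.array([[1], [0], [MISSING], [MISSING]], dtype=np.int8)
        maf, count = compute_maf(make_matrix(g), 0)
        assert maf == pytest.approx(1 / 4)

    def test_no_calls_raise(self):
        g = np.full((4, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            compute_maf(make_matrix(g), 0)


class TestFilterCascade:
    def _cohort(self, sites_genotypes, **kw):
        m = make_matrix(sites_genotypes, **kw)
        controls = m.sample_ids[len(m.sample_ids) // 2 :]
        return m, controls

    def test_identity_when_everything_passes(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(1, 0.3, (60, 5)).astype(np.int8) + rng.binomial(1, 0.3, (60, 5))
        m, controls = self._cohort(g)
        filtered, reports, ledger, multi = qc_filter_sites(m, controls)
        assert ledger.as_dict() == {
            "input_sites": 5,
            "biallelic": 5,
            "hwe_pass": 5,
            "call_rate_pass": 5,
            "multiallelic_excluded": 0,
        }
        assert filtered.n_sites == 5
        assert all(r.passed for r in reports)

    def test_planted_hwe_violation_fails_stage_two(self):
        # zero hets at MAF ~0.3 among 147 controls: extreme het deficit
        n_ctrl = 147
        g_ctrl = np.zeros((n_ctrl, 1), dtype=np.int8)
        g_ctrl[:44] = 2
        g_case = np.random.default_rng(1).binomial(1, 0.3, (142, 1)).astype(np.int8)
        g = np.vstack([g_case, g_ctrl])
        m = make_matrix(g)
        controls = m.sample_ids[142:]
        from extremeseq.variant_qc import hwe_test

        _, p_oracle, _ = hwe_test(103, 0, 44)
        assert p_oracle < 1e-3
        _, reports, ledger, _ = qc_filter_sites(m, controls)
        assert reports[0].verdict == "fail(hwe)"
        assert ledger.n_hwe_pass == 0

    def test_call_rate_below_ninety_percent_fails(self):
        # HWE-consistent genotypes so only the call-rate stage can fail
        g = np.random.default_rng(8).binomial(2, 0.5, (100, 1)).astype(np.int8)
        depth = np.full((100, 1), 40)
        depth[:12, 0] = 2  # masked at stage 3 -> call rate 0.88
        m = make_matrix(g, depth=depth)
        _, reports, ledger, _ = qc_filter_sites(m, m.sample_ids[50:])
        assert reports[0].call_rate == pytest.approx(0.88)
        assert reports[0].verdict == "fail(call_rate)"

    def test_multiallelic_reported_separately(self):
        sites = [
            VariantSite("chr3", 100, "A", ("G",)),
            VariantSite("chr3", 200, "A", ("G", "T")),
        ]
        g = np.array([[0, 1], [1, 0], [0, 0], [0, 0]], dtype=np.int8)
        m = make_matrix(g)
        m.sites = sites
        filtered, reports, ledger, multi = qc_filter_sites(m, m.sample_ids[2:])
        assert ledger.n_multiallelic == 1
        assert len(multi) == 1 and multi[0].n_alt_carriers == 1
        assert all(r.site.is_biallelic for r in reports)

    def test_ledger_counts_monotone_and_sample_order_invariant(self, small_cohort):
        matrix, samples, _ = small_cohort
        controls = samples.loc[samples["group"] == "control", "sample_id"].tolist()
        _, _, ledger, _ = qc_filter_sites(matrix, controls)
        d = ledger.as_dict()
        assert d["input_sites"] >= d["biallelic"] >= d["hwe_pass"] >= d["call_rate_pass"]
        # permute sample order: identical ledger
        perm = np.random.default_rng(3).permutation(matrix.n_samples)
        shuffled = make_matrix(
            matrix.genotypes[perm],
            positions=[s.pos for s in matrix.sites],
            depth=matrix.depth[perm],
            quality=matrix.quality[perm],
        )
        shuffled.sample_ids = [matrix.sample_ids[i] for i in perm]
        _, _, ledger2, _ = qc_filter_sites(shuffled, controls)
        assert ledger2.as_dict() == d

    def test_empty_control_set_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        with pytest.raises(ValueError):
            qc_filter_sites(matrix, [])


class TestClassification:
    def test_empty_known_set_gives_novel_fraction_one(self):
        from extremeseq.datasets import snv_reports_fixture

        reports, _ = snv_reports_fixture()
        summary = classify_variants(reports, set())
        assert summary.frac_novel == 1.0

    def test_known_novel_singleton_rare_fractions(self):
        from extremeseq.datasets import snv_reports_fixture

        reports, known = snv_reports_fixture()
        summary = classify_variants(reports, known)
        assert summary.n_pass == 1393
        assert summary.n_known == 433
        assert round(100 * summary.frac_novel) == 69
        assert round(100 * summary.frac_singleton) == 37
        assert round(100 * summary.frac_rare) == 55
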