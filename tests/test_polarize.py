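import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_sitetable
from ecoscan.polarize import (
    DerivedCounts,
    ancestral_coverage_report,
    assign_ancestral,
    classify_mutation,
    count_derived_by_class,
    derived_sharing,
    estimate_tmrca,
    estimate_tstv,
    shared_derived_fraction,
)

# the radiation's printed third-codon partition, used as constructed input
COUNTS = DerivedCounts(
    fixed_transitions=11_176,
    fixed_transversions=7_120,
    within_transitions=1_608,
    within_transversions=421,
    mixed=6,
)


class TestClassify:
    @pytest.mark.parametrize(
        "pair,expected",
        [(("A", "G"), "transition"), (("C", "T"), "transition"),
         (("A", "T"), "transversion"), (("G", "C"), "transversion")],
    )
    def test_definition(self, pair, expected):
        assert classify_mutation(*pair) == expected

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_symmetric(self, a, b):
        if a == b:
            with pytest.raises(ValueError):
                classify_mutation(a, b)
        else:
            assert classify_mutation(a, b) == classify_mutation(b, a)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation("N", "A")


class TestAssignAncestral:
    def test_outgroup_must_match_an_observed_allele(self):
        g = np.array([[[0, 1]], [[0, 1]], [[0, 1]]], dtype=np.int8)
        tab = make_sitetable(genotypes=g, popmap={"i0": "p"}, ref="A", alt="G", anc="N")
        out, rep = assign_ancestral(tab, ["A", "G", "C"])  # C matches neither allele
        assert list(out.sites["anc"]) == ["A", "G", "N"]
        assert rep.inferable == 2

    def test_all_unknown_outgroup(self):
        g = np.zeros((2, 1, 2), dtype=np.int8)
        tab = make_sitetable(genotypes=g, popmap={"i0": "p"})
        _, rep = assign_ancestral(tab, ["N", "N"])
        assert rep.percent == 0.0

    def test_genome_scale_coverage_percentage(self):
        rep = ancestral_coverage_report(2_206_055_540, 2_249_565_739)
        assert round(rep.percent, 1) == 98.1


class TestDerivedCounts:
    def test_printed_partition_identity(self):
        assert COUNTS.total_transversions == 7_547  # 7,120 + 421 + 6
        assert COUNTS.total_transitions == 12_784  # 11,176 + 1,608

    def test_counting_on_constructed_panel(self):
        # 9 diploids; 2 sites fixed derived transversion, 1 segregating
        # transversion, 1 fixed transition, 1 below the frequency cutoff
        n = 9
        g = np.zeros((5, n, 2), dtype=np.int8)
        g[0], g[1] = 1, 1  # fixed
        g[2, :3, :] = 1  # segregating at 6/18 = 0.33
        g[3] = 1  # fixed transition
        g[4, 0, 0] = 1  # singleton at 1/18 < 0.1 -> excluded
        tab = make_sitetable(
            genotypes=g,
            popmap={f"i{k}": "p" for k in range(n)},
            ref="A",
            alt=["T", "T", "T", "G", "T"],
            anc="A",
            third_codon=True,
        )
        counts = count_derived_by_class(tab, [f"i{k}" for k in range(n)], maf_cutoff=0.1)
        assert (counts.fixed_transversions, counts.within_transversions) == (2, 1)
        assert (counts.fixed_transitions, counts.within_transitions) == (1, 0)

    def test_missing_data_in_any_panel_member_masks_site(self):
        g = np.ones((1, 3, 2), dtype=np.int8)
        g[0, 2, 0] = -1
        tab = make_sitetable(genotypes=g, popmap={f"i{k}": "p" for k in range(3)},
                             ref="A", alt="T", third_codon=True)
        counts = count_derived_by_class(tab, ["i0", "i1", "i2"], maf_cutoff=0.0)
        assert counts.total_transversions == 0
        assert counts.complete_third_codon_sites == 0


class TestTsTv:
    def test_printed_within_lineage_ratio(self):
        assert round(estimate_tstv(COUNTS), 1) == 3.8

    def test_robust_to_mixed_site_convention(self):
        assert round(estimate_tstv(COUNTS, include_mixed=True), 1) == 3.8

    def test_equal_counts(self):
        c = DerivedCounts(within_transitions=100, within_transversions=100)
        assert estimate_tstv(c) == 1.0

    def test_zero_transversions_signalled(self):
        with pytest.raises(ZeroDivisionError):
            estimate_tstv(DerivedCounts(within_transitions=5))


class TestSharedDerived:
    def panel_table(self):
        # 3 usable sites for i0: i1 shares 2 of 3
        g = np.zeros((3, 2, 2), dtype=np.int8)
        g[:, 0, :] = 1
        g[0, 1, 0] = 1
        g[1, 1, :] = 1
        tab = make_sitetable(genotypes=g, popmap={"i0": "p", "i1": "p"},
                             ref="A", alt="T", third_codon=True)
        return tab

    def test_counting_oracle(self):
        tab = self.panel_table()
        assert shared_derived_fraction(tab, "i0", "i1", maf_cutoff=0.0) == pytest.approx(2 / 3)

    def test_self_comparison_is_one(self):
        tab = self.panel_table()
        assert shared_derived_fraction(tab, "i0", "i0", maf_cutoff=0.0) == 1.0

    def test_disjoint_carriers_share_nothing(self):
        g = np.zeros((2, 2, 2), dtype=np.int8)
        g[:, 0, :] = 1
        tab = make_sitetable(genotypes=g, popmap={"i0": "p", "i1": "p"},
                             ref="A", alt="T", third_codon=True)
        assert shared_derived_fraction(tab, "i0", "i1", maf_cutoff=0.0) == 0.0
        n_focal, _ = derived_sharing(tab, "i1", "i0", maf_cutoff=0.0)
        assert n_focal == 0
        with pytest.raises(ZeroDivisionError):
            shared_derived_fraction(tab, "i1", "i0", maf_cutoff=0.0)


class TestTMRCA:
    def test_transversion_formula_evaluation(self):
        est = estimate_tmrca(124, "transversion", 3_127_876, 9.10e-10, tstv=3.8)
        assert est.years == pytest.approx(2.09e5, rel=0.005)

    def test_doubling_sites_halves_age(self):
        a = estimate_tmrca(100, "combined", 1_000_000, 1e-9)
        b = estimate_tmrca(100, "combined", 2_000_000, 1e-9)
        assert a.years == pytest.approx(2 * b.years)

    def test_zero_mutations_zero_age(self):
        assert estimate_tmrca(0, "combined", 1_000_000, 1e-9).years == 0.0

    def test_hpd_interval_endpoints_swap(self):
        est = estimate_tmrca(124, "transversion", 3_127_876, 9.10e-10,
                             mu_hpd=(6.68e-10, 1.18e-9), tstv=3.8)
        lo, hi = est.interval_years
        assert lo < est.years < hi
        # the younger bound comes from the larger rate
        faster = estimate_tmrca(124, "transversion", 3_127_876, 1.18e-9, tstv=3.8)
        assert lo == pytest.approx(faster.years)

    def test_class_rates_partition_total(self):
        ti = estimate_tmrca(1, "transition", 1, 1e-9, tstv=3.8)
        tv = estimate_tmrca(1, "transversion", 1, 1e-9, tstv=3.8)
        assert 1 / ti.years + 1 / tv.years == pytest.approx(1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_tmrca(10, "transversion", 0, 1e-9, tstv=3.8)
        with pytest.raises(ValueError):
            estimate_tmrca(10, "transversion", 100, 1e-9, tstv=-1)
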