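import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ecoscan.selection import (
    branch_length_T,
    category_bin_chisq,
    fisher_term_enrichment,
    outlier_call,
    pbs,
    top_fst_snps,
)


class TestBranchLength:
    @pytest.mark.parametrize("fst,expected", [(0.0, 0.0), (0.5, 0.6931), (0.09, 0.0943)])
    def test_log_transform(self, fst, expected):
        assert branch_length_T(fst) == pytest.approx(expected, abs=1e-4)

    def test_negative_fst_clamped_to_zero(self):
        assert branch_length_T(-0.05) == 0.0

    def test_unit_fst_signalled(self):
        with pytest.raises(ValueError, match="infinite"):
            branch_length_T(1.0)


class TestPBS:
    def test_symmetric_trio(self):
        assert pbs(0.4, 0.4, 0.4) == pytest.approx(0.2)

    def test_worked_example(self):
        t_ab = branch_length_T(0.2)
        t_ac = branch_length_T(0.2)
        t_bc = branch_length_T(0.05)
        assert pbs(t_ab, t_ac, t_bc) == pytest.approx(0.19750, abs=1e-5)

    def test_negative_pbs_unclamped(self):
        assert pbs(0.1, 0.1, 0.5) == pytest.approx(-0.15)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(*(st.floats(0.0, 0.99),) * 3)
    def test_additivity(self, f_ab, f_ac, f_bc):
        t_ab, t_ac, t_bc = (branch_length_T(f) for f in (f_ab, f_ac, f_bc))
        pbs_a = pbs(t_ab, t_ac, t_bc)
        pbs_b = pbs(t_ab, t_bc, t_ac)
        assert pbs_a + pbs_b == pytest.approx(t_ab, abs=1e-12)


class TestOutliers:
    def frame(self, values):
        return pd.DataFrame({"pbs": values, "eligible": True})

    def test_top_ten_of_ten_thousand(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(10_000, dtype=float))
        out, thr = outlier_call(self.frame(vals), 99.9, "pbs")
        assert len(out) == 10
        assert sorted(out["pbs"]) == list(np.arange(9_990, 10_000, dtype=float))

    def test_ties_at_threshold_all_included(self):
        vals = np.array([0.0] * 995 + [1.0] * 5)
        out, thr = outlier_call(self.frame(vals), 99.9, "pbs")
        assert thr == 1.0 and len(out) == 5

    def test_degenerate_all_equal(self):
        out, thr = outlier_call(self.frame(np.ones(2000)), 99.9, "pbs")
        assert len(out) == 2000  # tie rule: everything at the threshold

    def test_percentile_zero_returns_all(self):
        out, _ = outlier_call(self.frame(np.arange(100.0)), 0, "pbs")
        assert len(out) == 100

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            outlier_call(pd.DataFrame(columns=["pbs"]), 99.9, "pbs")


class TestTopFstSnps:
    def test_simple_count(self):
        tab = pd.DataFrame({"fst": np.linspace(0, 1, 1000)})
        assert len(top_fst_snps(tab, 0.01)) == 10

    def test_ties_may_exceed_the_fraction(self):
        tab = pd.DataFrame({"fst": [0.9] * 30 + [0.1] * 970})
        assert len(top_fst_snps(tab, 0.01)) == 30

    def test_fraction_one_returns_everything(self):
        tab = pd.DataFrame({"fst": np.arange(50.0)})
        assert len(top_fst_snps(tab, 1.0)) == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fst_snps(pd.DataFrame(columns=["fst"]))


class TestCategoryBinChisq:
    def test_uniform_table_has_zero_residuals(self):
        snps = pd.DataFrame(
            {"category": ["exon", "intron"] * 50, "fst": [0.05, 0.05, 0.15, 0.15] * 25}
        )
        res = category_bin_chisq(snps, bins=[0.0, 0.1, 0.2])
        assert np.allclose(res.residuals.to_numpy()[np.isfinite(res.residuals.to_numpy())], 0.0)
        assert not res.significant.to_numpy().any()

    def test_two_by_two_matches_hand_computed_residuals(self):
        # obs 30/70 vs 10/90 in a 2x2 (n=200)
        snps = pd.DataFrame(
            {
                "category": ["exon"] * 30 + ["intron"] * 70 + ["exon"] * 10 + ["intron"] * 90,
                "fst": [0.05] * 100 + [0.15] * 100,
            }
        )
        res = category_bin_chisq(snps, bins=[0.0, 0.1, 0.2])
        obs = np.array([[30, 10], [70, 90]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = (obs - expected) / np.sqrt(expected)
        got = res.residuals.loc[["exon", "intron"]].to_numpy()
        assert np.allclose(got, hand, atol=1e-12)
        chi2 = np.nansum(res.residuals.to_numpy() ** 2)
        ref = stats.chi2_contingency(obs, correction=False).statistic
        assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_bonferroni_cell_alpha(self):
        rng = np.random.default_rng(2)
        snps = pd.DataFrame(
            {
                "category": rng.choice(["exon", "intron", "flank", "intergenic"], 4000),
                "fst": rng.random(4000) * 0.5,
            }
        )
        res = category_bin_chisq(snps, bins=np.linspace(0, 0.5, 6))
        assert res.cell_alpha == pytest.approx(0.05 / 20)

    def test_sparse_cells_excluded_from_testing(self):
        snps = pd.DataFrame({"category": ["exon"] * 99 + ["intron"], "fst": [0.05] * 100})
        res = category_bin_chisq(snps, bins=[0.0, 0.1, 0.2])
        assert res.unreliable.to_numpy().sum() > 0
        assert not (res.significant & res.unreliable).to_numpy().any()


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    from math import comb

    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / comb(N, n)


class TestFisherEnrichment:
    def test_term_covering_all_genes_is_uninformative(self):
        genes = [f"g{i}" for i in range(20)]
        ann = {g: {"everything"} for g in genes}
        res = fisher_term_enrichment(genes[:5], ann, genes)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_tail_matches_enumeration_oracle(self):
        # 2x2: 8 of 10 outliers in-term, 10 of 90 background non-outliers
        background = [f"g{i}" for i in range(100)]
        outliers = background[:10]
        in_term = background[:8] + background[10:20]
        ann = {g: {"t1"} for g in in_term}
        res = fisher_term_enrichment(outliers, ann, background)
        expected = hypergeom_tail_oracle(8, 100, 18, 10)
        assert res["p_value"].iloc[0] == pytest.approx(expected, abs=1e-9)
        odds, p = stats.fisher_exact([[8, 2], [10, 80]], alternative="greater")
        assert res["p_value"].iloc[0] == pytest.approx(p, abs=1e-9)

    def test_empty_outlier_set_yields_no_tests(self):
        ann = {"g1": {"t"}}
        res = fisher_term_enrichment([], ann, ["g1", "g2"])
        assert len(res) == 0

    def test_outliers_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_enrichment(["gX"], {"g1": {"t"}}, ["g1"])
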