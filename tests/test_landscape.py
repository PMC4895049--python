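import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_sitetable
from ecoscan.landscape import (
    landscape_correlations,
    landscape_scan,
    make_windows,
    site_dxy,
    site_fst_components,
    site_pi,
    window_fst,
    window_pi,
)
from ecoscan.layout import GenomeLayout

freqs = st.floats(0.0, 1.0)


class TestSiteKernels:
    def test_hudson_components_worked_example(self):
        num, den = site_fst_components(0.5, 20, 0.25, 20)
        assert num == pytest.approx(0.039474, abs=1e-6)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(0.0789, abs=1e-4)

    def test_fixed_difference_gives_unity(self):
        num, den = site_fst_components(1.0, 100, 0.0, 100)
        assert (num, den) == (1.0, 1.0)

    def test_no_differentiation_is_negative_in_expectation(self):
        num, _ = site_fst_components(0.5, 20, 0.5, 20)
        assert num == pytest.approx(-2 * 0.25 / 19)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            site_fst_components(0.5, 1, 0.5, 10)

    @pytest.mark.parametrize("p1,p2,expected", [(1, 0, 1.0), (0.5, 0.5, 0.5), (0.3, 0.6, 0.54)])
    def test_dxy_arithmetic(self, p1, p2, expected):
        assert site_dxy(p1, p2) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(freqs, freqs)
    def test_dxy_symmetry_and_bounds(self, p1, p2):
        d = site_dxy(p1, p2)
        assert d == site_dxy(p2, p1)
        assert 0.0 <= d <= 1.0

    def test_pi_single_site_formula(self):
        # p=0.5, 10 alleles, 1,000 covered bases
        assert site_pi(0.5, 10) / 1000 == pytest.approx(5.56e-4, abs=1e-6)

    def test_pi_unbiased_under_binomial_resampling(self):
        # mean over resampled allele counts at known p matches 2p(1-p)
        rng = np.random.default_rng(1)
        p, n = 0.3, 20
        draws = rng.binomial(n, p, size=1000) / n
        est = site_pi(draws, n).mean()
        truth = 2 * p * (1 - p)
        se = np.std(site_pi(draws, n), ddof=1) / np.sqrt(1000)
        assert abs(est - truth) < 2 * se + 1e-3


def random_two_pop_table(n_sites=100, seed=0, n1=6, n2=8):
    rng = np.random.default_rng(seed)
    g = rng.choice([0, 1], size=(n_sites, n1 + n2, 2)).astype(np.int8)
    popmap = {f"a{k}": "p1" for k in range(n1)}
    popmap.update({f"b{k}": "p2" for k in range(n2)})
    return make_sitetable(positions=range(0, n_sites * 10, 10), genotypes=g, popmap=popmap)


class TestWindowFst:
    def test_ratio_of_sums_matches_brute_oracle(self):
        tab = random_two_pop_table(100, seed=3)
        win = [("chr1", 0, 1000)]
        got = window_fst(tab, "p1", "p2", win)["fst"].iloc[0]
        # independent site-by-site oracle
        num_sum = den_sum = 0.0
        for i in range(tab.n_sites):
            g1 = tab.genotypes[i, :6].reshape(-1)
            g2 = tab.genotypes[i, 6:].reshape(-1)
            p1, p2 = g1.mean(), g2.mean()
            if (p1 == p2 == 0.0) or (p1 == p2 == 1.0):
                continue
            num_sum += (p1 - p2) ** 2 - p1 * (1 - p1) / 11 - p2 * (1 - p2) / 15
            den_sum += p1 * (1 - p2) + p2 * (1 - p1)
        assert got == pytest.approx(num_sum / den_sum, abs=1e-12)

    def test_all_fixed_differences_give_one(self):
        g = np.zeros((10, 4, 2), dtype=np.int8)
        g[:, 2:, :] = 1
        popmap = {"a0": "p1", "a1": "p1", "b0": "p2", "b1": "p2"}
        tab = make_sitetable(genotypes=g, popmap=popmap)
        assert window_fst(tab, "p1", "p2", [("chr1", 0, 100)])["fst"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged_nan(self):
        g = np.zeros((5, 4, 2), dtype=np.int8)
        popmap = {"a0": "p1", "a1": "p1", "b0": "p2", "b1": "p2"}
        tab = make_sitetable(genotypes=g, popmap=popmap)
        assert np.isnan(window_fst(tab, "p1", "p2", [("chr1", 0, 100)])["fst"].iloc[0])

    def test_window_sums_are_additive(self):
        tab = random_two_pop_table(100, seed=5)
        whole = window_fst(tab, "p1", "p2", [("chr1", 0, 1000)])
        halves = window_fst(tab, "p1", "p2", [("chr1", 0, 500), ("chr1", 500, 1000)])
        assert whole["fst_num"].iloc[0] == pytest.approx(halves["fst_num"].sum(), abs=1e-12)
        assert whole["fst_den"].iloc[0] == pytest.approx(halves["fst_den"].sum(), abs=1e-12)


class TestWindowPi:
    def test_monomorphic_window_is_zero(self):
        g = np.zeros((5, 5, 2), dtype=np.int8)
        tab = make_sitetable(genotypes=g, popmap={f"i{k}": "p" for k in range(5)})
        assert window_pi(tab, "p", [("chr1", 0, 100)])["pi"].iloc[0] == 0.0

    def test_neutral_expectation_recovered(self, two_pop_layout):
        # single population: window pi ~ 4 Ne mu
        from ecoscan.simdata import DemographicModel, simulate_cohort

        model = DemographicModel(
            populations=["A"], epochs={"A": [(0.0, 10_000.0)]}, mu=1e-8, recomb=1e-8,
        )
        vals = []
        for seed in range(1, 6):
            ds = simulate_cohort(model, two_pop_layout, {"A": 10}, seed=seed)
            vals.append(window_pi(ds.sites, "A", [("chr1", 0, 1_000_000)])["pi"].iloc[0])
        assert np.mean(vals) == pytest.approx(4e-4, rel=0.15)


class TestScanAndCorrelations:
    def test_windows_cover_layout(self):
        layout = GenomeLayout((("chr1", 120_000), ("chr2", 40_000)))
        tiles = make_windows(layout, 50_000)
        assert tiles == [("chr1", 0, 50_000), ("chr1", 50_000, 100_000), ("chr1", 100_000, 120_000),
                         ("chr2", 0, 40_000)]
        sliding = make_windows(GenomeLayout((("chr1", 100_000),)), 50_000, 10_000)
        assert len(sliding) == 6 and sliding[1] == ("chr1", 10_000, 60_000)

    def test_identical_comparisons_identical_tables(self, small_dataset):
        a = landscape_scan(small_dataset, [("B1", "B2")], 50_000)[("B1", "B2")]
        b = landscape_scan(small_dataset, [("B1", "B2")], 50_000)[("B1", "B2")]
        pd.testing.assert_frame_equal(a, b)

    def test_self_correlation_is_unity(self, small_dataset):
        tables = landscape_scan(small_dataset, [("B1", "B2"), ("B1", "C")], 50_000)
        corr = landscape_correlations(tables, statistics=("fst",))
        assert np.allclose(np.diag(corr.rho), 1.0)
        assert np.allclose(corr.rho, corr.rho.T)

    def test_independent_tables_correlate_near_zero(self):
        rng = np.random.default_rng(7)
        idx = pd.MultiIndex.from_arrays(
            [["chr1"] * 200, np.arange(200) * 1000, np.arange(200) * 1000 + 1000],
            names=["chrom", "start", "end"],
        )
        tables = {
            ("a", "b"): pd.DataFrame({"fst": rng.random(200)}, index=idx).reset_index(),
            ("c", "d"): pd.DataFrame({"fst": rng.random(200)}, index=idx).reset_index(),
        }
        corr = landscape_correlations(tables, statistics=("fst",))
        assert abs(corr.rho[0, 1]) < 0.2

    def test_insufficient_windows_rejected(self):
        idx = pd.DataFrame({"chrom": ["chr1"] * 5, "start": range(5), "end": range(1, 6), "fst": 0.1})
        with pytest.raises(ValueError, match="aligned windows"):
            landscape_correlations({("a", "b"): idx, ("c", "d"): idx}, statistics=("fst",))
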