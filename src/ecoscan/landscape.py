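"""Windowed differentiation and diversity landscapes.

Per-site FST uses the Hudson/Bhatia method-of-moments components; windows
aggregate as a ratio of sums (sum of numerators over sum of denominators),
which is robust to sample-size variation and leaves negative site
numerators unclamped so the aggregate stays unbiased. Dxy is the mean of
``p1*q2 + p2*q1`` and pi the per-site unbiased heterozygosity
``2p(1-p) n/(n-1)``, both normalized by covered bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout
from .sites import SiteTable
from .sitefilter import window_coverage_filter

WINDOW_SIZES = (50_000, 100_000, 200_000)


# -- per-site kernels ------------------------------------------------------


def site_fst_components(p1, n1, p2, n2):
    """Hudson/Bhatia method-of-moments FST components for one or many sites.

    ``n1``/``n2`` are *allele* counts (2x individuals). Returns
    ``(numerator, denominator)``; window FST is the ratio of their sums.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("allele counts must exceed 1")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def site_dxy(p1, p2):
    """Mean pairwise divergence component ``p1*q2 + p2*q1`` (0 for invariant sites)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    return p1 * (1 - p2) + p2 * (1 - p1)


def site_pi(p, n):
    """Unbiased per-site heterozygosity ``2 p (1-p) n/(n-1)`` (n = allele count)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("allele counts must exceed 1")
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


# -- windows ---------------------------------------------------------------


def make_windows(layout: GenomeLayout, window_bp: int, step_bp: int | None = None) -> list:
    """(chrom, start, end) tiles (default) or sliding windows over the layout."""
    if window_bp <= 0:
        raise ValueError("window size must be positive")
    step = step_bp or window_bp
    if step <= 0:
        raise ValueError("step must be positive")
    windows = []
    for chrom, length in layout:
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            windows.append((chrom, start, end))
            if end == length:
                break
            start += step
    return windows


def _window_sums(positions, values, starts, ends):
    """Sum ``values`` whose position falls in each [start, end) window."""
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    cs = np.concatenate([[0.0], np.cumsum(values[order])])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    return cs[hi] - cs[lo], hi - lo


def _per_chrom_windows(windows):
    by = {}
    for chrom, start, end in windows:
        by.setdefault(chrom, []).append((start, end))
    return {c: np.array(v, dtype=np.int64) for c, v in by.items()}


def window_fst(sites: SiteTable, pop1: str, pop2: str, windows) -> pd.DataFrame:
    """Ratio-of-sums window FST for one population pair.

    Windows with a zero denominator (no variation in either population)
    get ``fst = NaN`` and are flagged ineligible downstream.
    """
    p1 = sites.alt_freq(pop1)
    p2 = sites.alt_freq(pop2)
    _, n1 = sites.alt_counts(pop1)
    _, n2 = sites.alt_counts(pop2)
    ok = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2)
    num = np.zeros(sites.n_sites)
    den = np.zeros(sites.n_sites)
    if ok.any():
        num[ok], den[ok] = site_fst_components(p1[ok], n1[ok], p2[ok], n2[ok])
    variable = ok & ((p1 > 0) | (p2 > 0)) & ((p1 < 1) | (p2 < 1))
    num[~variable] = 0.0
    den[~variable] = 0.0

    rows = []
    chrom_arr = sites.sites["chrom"].to_numpy()
    pos_arr = sites.sites["pos"].to_numpy()
    for chrom, win in _per_chrom_windows(windows).items():
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        nsum, nsnp = _window_sums(pos, num[sel], win[:, 0], win[:, 1])
        dsum, _ = _window_sums(pos, den[sel], win[:, 0], win[:, 1])
        snps, _ = _window_sums(pos, variable[sel].astype(float), win[:, 0], win[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(dsum > 0, nsum / np.where(dsum > 0, dsum, 1.0), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": win[:, 0],
                    "end": win[:, 1],
                    "fst_num": nsum,
                    "fst_den": dsum,
                    "fst": fst,
                    "n_snps": snps.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "fst_num", "fst_den", "fst", "n_snps"]
    )


def window_dxy(sites: SiteTable, pop1: str, pop2: str, windows, covered_bp=None) -> pd.DataFrame:
    """Window Dxy: summed site divergence over covered bases."""
    p1 = np.nan_to_num(sites.alt_freq(pop1))
    p2 = np.nan_to_num(sites.alt_freq(pop2))
    vals = site_dxy(p1, p2)
    return _normalized_window_sum(sites, vals, windows, covered_bp, "dxy")


def window_pi(sites: SiteTable, pop: str, windows, covered_bp=None) -> pd.DataFrame:
    """Window nucleotide diversity for one population."""
    p = sites.alt_freq(pop)
    _, n = sites.alt_counts(pop)
    ok = (n > 1) & ~np.isnan(p)
    vals = np.zeros(sites.n_sites)
    if ok.any():
        vals[ok] = site_pi(p[ok], n[ok])
    return _normalized_window_sum(sites, vals, windows, covered_bp, "pi")


def _normalized_window_sum(sites, vals, windows, covered_bp, name):
    chrom_arr = sites.sites["chrom"].to_numpy()
    pos_arr = sites.sites["pos"].to_numpy()
    rows = []
    for chrom, win in _per_chrom_windows(windows).items():
        sel = chrom_arr == chrom
        ssum, _ = _window_sums(pos_arr[sel], np.asarray(vals)[sel], win[:, 0], win[:, 1])
        if covered_bp is None:
            cov = (win[:, 1] - win[:, 0]).astype(float)
        else:
            cov = np.asarray([covered_bp.get((chrom, int(s), int(e)), e - s) for s, e in win], dtype=float)
        if np.any(cov <= 0):
            raise ValueError("window with zero covered bases")
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": win[:, 0], "end": win[:, 1], name: ssum / cov})
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["chrom", "start", "end", name])


# -- the scan --------------------------------------------------------------


def landscape_scan(
    dataset,
    comparisons,
    window_bp: int = 50_000,
    step_bp: int | None = None,
    min_covered_bp: int = 10_000,
    min_individuals: int = 5,
) -> dict:
    """Windowed FST/Dxy/pi tables for population pairs on a shared grid.

    Applies the per-population coverage filter first, then computes the
    statistics over the eligible windows; all comparisons share one window
    grid so rows align across tables.
    """
    windows = make_windows(dataset.layout, window_bp, step_bp)
    coverage = dataset.coverage()
    tables = {}
    for pop_a, pop_b in comparisons:
        cov = {p: coverage[p] for p in (pop_a, pop_b)}
        eligible = window_coverage_filter(windows, cov, min_covered_bp, min_individuals)
        if not eligible:
            import warnings

            warnings.warn(f"no eligible windows for {pop_a} vs {pop_b}")
            tables[(pop_a, pop_b)] = pd.DataFrame(
                columns=["chrom", "start", "end", "fst", "dxy", f"pi_{pop_a}", f"pi_{pop_b}", "n_snps"]
            )
            continue
        fst = window_fst(dataset.sites, pop_a, pop_b, eligible)
        dxy = window_dxy(dataset.sites, pop_a, pop_b, eligible)
        pia = window_pi(dataset.sites, pop_a, eligible)
        pib = window_pi(dataset.sites, pop_b, eligible)
        tab = fst.merge(dxy, on=["chrom", "start", "end"])
        tab[f"pi_{pop_a}"] = pia["pi"].to_numpy()
        tab[f"pi_{pop_b}"] = pib["pi"].to_numpy()
        tables[(pop_a, pop_b)] = tab
    return tables


@dataclass
class CorrelationMatrix:
    labels: list
    rho: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


def landscape_correlations(tables: dict, statistics=("fst",), min_windows: int = 30) -> CorrelationMatrix:
    """Spearman rank correlations of window statistics across comparisons.

    Uses windows present in all tables (pairwise-complete within each
    correlation). Labels are ``"stat:popA-popB"``.
    """
    series = {}
    for (pop_a, pop_b), tab in tables.items():
        keyed = tab.set_index(["chrom", "start", "end"])
        for stat in statistics:
            col = stat if stat in keyed.columns else f"{stat}_{pop_a}"
            if col not in keyed.columns:
                raise KeyError(f"statistic {stat!r} not in table for {(pop_a, pop_b)}")
            series[f"{stat}:{pop_a}-{pop_b}"] = keyed[col]
    frame = pd.DataFrame(series).dropna(how="all")
    labels = list(frame.columns)
    k = len(labels)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pair = frame.iloc[:, [i, j]].dropna()
            if len(pair) < min_windows:
                raise ValueError(
                    f"only {len(pair)} aligned windows for {labels[i]} vs {labels[j]} (need {min_windows})"
                )
            r = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(labels=labels, rho=rho)
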