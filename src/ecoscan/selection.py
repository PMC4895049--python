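"""PBS selection scans and outlier enrichment tests.

Pairwise window FST values are transformed into branch-scaled divergence
times ``T = -log(1 - FST)`` and combined over a population trio into the
population branch statistic ``PBS_A = (T_AB + T_AC - T_BC) / 2`` — the
allele-frequency branch length specific to the focal population. Outliers
are called against empirical genome-wide percentiles; enrichment of
high-FST SNPs by genomic category uses a chi-squared residual table and a
one-sided Fisher (hypergeometric) test over user-supplied gene terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import make_windows, window_fst
from .sites import CATEGORIES
from .sitefilter import window_coverage_filter

DEFAULT_PERCENTILES = (99.9, 99.99)
_FST_CEILING = 1.0 - 1e-12


def branch_length_T(fst: float) -> float:
    """Cavalli-Sforza divergence ``T = -log(1 - FST)``; negative FST counts as 0."""
    fst = float(fst)
    if fst >= 1.0:
        raise ValueError("FST = 1 gives infinite branch length")
    return -np.log1p(-max(fst, 0.0))


def pbs(t_ab: float, t_ac: float, t_bc: float) -> float:
    """Branch length of focal population A: ``(T_AB + T_AC - T_BC) / 2``."""
    if min(t_ab, t_ac, t_bc) < 0:
        raise ValueError("branch-scaled divergences must be non-negative")
    return (t_ab + t_ac - t_bc) / 2.0


def _t_array(fst_values: np.ndarray) -> np.ndarray:
    f = np.clip(np.asarray(fst_values, dtype=float), 0.0, _FST_CEILING)
    return -np.log1p(-f)


def pbs_scan(
    dataset,
    trio,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    features=None,
    min_snps: int = 2,
    min_covered_bp: int = 10_000,
    min_individuals: int = 5,
) -> pd.DataFrame:
    """PBS over sliding windows (and optional exon features) for a trio.

    ``trio`` is (focal, sister, outgroup-population). Window FSTs come from
    the landscape ratio-of-sums machinery; values are clipped to [0, 1) so
    fixed-difference windows stay finite after the log transform. Features
    with fewer than ``min_snps`` SNPs are reported but flagged ineligible
    (excluded from percentile ranking).
    """
    a, b, c = trio
    if len({a, b, c}) != 3:
        raise ValueError("trio populations must be distinct")
    if features is None:
        windows = make_windows(dataset.layout, window_bp, step_bp)
        coverage = {p: dataset.coverage()[p] for p in (a, b, c)}
        windows = window_coverage_filter(windows, coverage, min_covered_bp, min_individuals)
        feature_kind = "window"
    else:
        windows = [tuple(f) for f in features]
        feature_kind = "exon"
    if not windows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "kind", "fst_ab", "fst_ac", "fst_bc",
                     "t_ab", "t_ac", "t_bc", f"pbs_{a}", f"pbs_{b}", f"pbs_{c}", "n_snps", "eligible"]
        )
    f_ab = window_fst(dataset.sites, a, b, windows)
    f_ac = window_fst(dataset.sites, a, c, windows)
    f_bc = window_fst(dataset.sites, b, c, windows)
    t_ab = _t_array(np.nan_to_num(f_ab["fst"].to_numpy()))
    t_ac = _t_array(np.nan_to_num(f_ac["fst"].to_numpy()))
    t_bc = _t_array(np.nan_to_num(f_bc["fst"].to_numpy()))
    n_snps = np.maximum.reduce([f_ab["n_snps"].to_numpy(), f_ac["n_snps"].to_numpy(), f_bc["n_snps"].to_numpy()])
    out = f_ab[["chrom", "start", "end"]].copy()
    out["kind"] = feature_kind
    out["fst_ab"] = f_ab["fst"].to_numpy()
    out["fst_ac"] = f_ac["fst"].to_numpy()
    out["fst_bc"] = f_bc["fst"].to_numpy()
    out["t_ab"] = t_ab
    out["t_ac"] = t_ac
    out["t_bc"] = t_bc
    out[f"pbs_{a}"] = (t_ab + t_ac - t_bc) / 2.0
    out[f"pbs_{b}"] = (t_ab + t_bc - t_ac) / 2.0
    out[f"pbs_{c}"] = (t_ac + t_bc - t_ab) / 2.0
    out["n_snps"] = n_snps
    out["eligible"] = n_snps >= (min_snps if features is not None else 1)
    return out


def outlier_call(records: pd.DataFrame, percentile: float, value_col: str):
    """Features at or above the empirical genome-wide percentile.

    The threshold is the order statistic at the percentile (``method=
    'higher'``), and ties at the threshold are all included. Returns
    (outlier DataFrame, threshold value).
    """
    if records.empty:
        raise ValueError("empty record table")
    if not (0 <= percentile <= 100):
        raise ValueError("percentile must be in [0, 100]")
    pool = records[records["eligible"]] if "eligible" in records.columns else records
    values = pool[value_col].to_numpy(dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no finite values to rank")
    if percentile >= 99.9 and values.size < 1000:
        warnings.warn(f"only {values.size} features; the {percentile} percentile is unstable")
    if percentile == 0:
        threshold = -np.inf
    else:
        threshold = np.percentile(values, percentile, method="higher")
    mask = pool[value_col].to_numpy(dtype=float) >= threshold
    return pool[mask], float(threshold)


def top_fst_snps(per_site_fst: pd.DataFrame, fraction: float = 0.01, value_col: str = "fst") -> pd.DataFrame:
    """Highest-FST fraction of SNPs, ties at the cutoff included."""
    if per_site_fst.empty:
        raise ValueError("no SNPs")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    values = per_site_fst[value_col].to_numpy(dtype=float)
    k = max(int(np.ceil(fraction * values.size)), 1)
    threshold = np.sort(values)[::-1][k - 1]
    return per_site_fst[values >= threshold]


@dataclass
class EnrichmentTable:
    """Category x FST-bin chi-squared table with Pearson residuals."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    significant: pd.DataFrame  # flags after Bonferroni, tested cells only
    unreliable: pd.DataFrame  # expected < 1, excluded from testing
    cell_alpha: float


def category_bin_chisq(
    snps: pd.DataFrame,
    bins=None,
    background: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fst_col: str = "fst",
    category_col: str = "category",
) -> EnrichmentTable:
    """Over/under-representation of SNP categories across FST bins.

    Builds the category x bin contingency table of ``snps``. Expected counts
    come from row/column independence, or — when a ``background`` SNP table
    is supplied — from the background's per-bin category shares. Pearson
    residuals ``(obs - exp)/sqrt(exp)`` are flagged two-sided against the
    normal quantile at ``alpha`` Bonferroni-corrected over the tested cells;
    cells with expected < 1 are excluded from testing.
    """
    if bins is None:
        bins = np.round(np.arange(0.0, 1.1, 0.1), 10)
    bins = np.asarray(bins, dtype=float)
    labels = [f"[{bins[i]:g},{bins[i + 1]:g})" for i in range(len(bins) - 1)]

    def table_of(df):
        cats = pd.Categorical(df[category_col], categories=list(CATEGORIES))
        binned = pd.cut(np.clip(df[fst_col], bins[0], np.nextafter(bins[-1], 0)), bins, right=False, labels=labels)
        return pd.crosstab(cats, binned, dropna=False).reindex(
            index=list(CATEGORIES), columns=labels, fill_value=0
        )

    observed = table_of(snps)
    n = observed.to_numpy().sum()
    if n == 0:
        raise ValueError("no SNPs to tabulate")
    if background is None:
        row = observed.sum(axis=1).to_numpy()[:, None]
        col = observed.sum(axis=0).to_numpy()[None, :]
        expected = row * col / n
    else:
        bg = table_of(background)
        bg_tot = bg.sum(axis=0).to_numpy()[None, :].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(bg_tot > 0, bg.to_numpy() / np.where(bg_tot > 0, bg_tot, 1.0), 0.0)
        expected = share * observed.sum(axis=0).to_numpy()[None, :]
    expected_df = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (observed.to_numpy() - expected) / np.sqrt(np.where(expected > 0, expected, np.nan))
    resid_df = pd.DataFrame(resid, index=observed.index, columns=observed.columns)
    unreliable = expected_df < 1.0
    n_tested = int((~unreliable).to_numpy().sum())
    cell_alpha = alpha / max(n_tested, 1)
    zcrit = stats.norm.ppf(1.0 - cell_alpha / 2.0)
    flags = resid_df.abs().gt(zcrit) & ~unreliable
    return EnrichmentTable(
        observed=observed.astype(int),
        expected=expected_df,
        residuals=resid_df,
        significant=flags,
        unreliable=unreliable,
        cell_alpha=cell_alpha,
    )


def fisher_term_enrichment(outlier_genes, annotation, background) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric) enrichment per term.

    ``annotation`` maps gene -> iterable of terms (or a two-column
    DataFrame). Terms with no annotated genes in the background are
    skipped. Returns raw and Bonferroni-adjusted p-values.
    """
    outliers = set(outlier_genes)
    background = set(background)
    if not outliers <= background:
        raise ValueError("outlier genes must be a subset of the background")
    if isinstance(annotation, pd.DataFrame):
        gene_col, term_col = annotation.columns[:2]
        mapping = {}
        for gene, term in zip(annotation[gene_col], annotation[term_col]):
            mapping.setdefault(gene, set()).add(term)
    else:
        mapping = {g: set(ts) for g, ts in annotation.items()}
    if not mapping:
        raise ValueError("annotation is empty")
    term_genes: dict = {}
    for gene, terms in mapping.items():
        if gene not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    N = len(background)
    n = len(outliers)
    for term in sorted(term_genes):
        in_term = term_genes[term]
        K = len(in_term)
        if K == 0 or n == 0:
            continue
        k = len(in_term & outliers)
        # P(X >= k) for X ~ Hypergeom(N, K, n): one-sided Fisher's exact test
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "outliers_in_term": k, "term_size": K,
                     "n_outliers": n, "n_background": N, "p_value": p})
    result = pd.DataFrame(rows, columns=["term", "outliers_in_term", "term_size",
                                         "n_outliers", "n_background", "p_value"])
    if len(result):
        result["p_bonferroni"] = np.minimum(result["p_value"] * len(result), 1.0)
    else:
        result["p_bonferroni"] = pd.Series(dtype=float)
    return result
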