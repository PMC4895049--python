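"""Four-population D-statistic (ABBA-BABA) and three-population f3 tests.

Both operate on per-site derived-allele frequencies and use a delete-one
block jackknife over contiguous SNP blocks (default 1,000 SNPs, mirroring
linkage-disequilibrium-scale blocking) for standard errors. With the
outgroup fixed ancestral after polarization its frequency is 0; a genotyped
outgroup population can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BLOCK_SIZE = 1000


@dataclass
class DStatResult:
    d: float
    abba_sum: float
    baba_sum: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    n_sites: int


@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    target: str
    source_a: str
    source_b: str
    n_blocks: int
    n_sites: int


def _block_edges(n_sites: int, block_size: int) -> np.ndarray:
    """Contiguous block boundaries; the remainder folds into the last block."""
    if block_size <= 0:
        raise ValueError("block size must be positive")
    n_blocks = max(n_sites // block_size, 1)
    edges = np.arange(n_blocks + 1, dtype=np.int64) * block_size
    edges[-1] = n_sites
    return edges


def _jackknife_ratio(num: np.ndarray, den: np.ndarray, edges: np.ndarray):
    """Delete-one block jackknife SE of ``sum(num)/sum(den)``."""
    tot_n, tot_d = num.sum(), den.sum()
    n_blocks = len(edges) - 1
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks for the jackknife")
    loo = np.empty(n_blocks)
    for j in range(n_blocks):
        lo, hi = edges[j], edges[j + 1]
        bn = num[lo:hi].sum()
        bd = den[lo:hi].sum()
        if tot_d - bd == 0:
            raise ZeroDivisionError("leave-one-out denominator is zero")
        loo[j] = (tot_n - bn) / (tot_d - bd)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum())
    return se, n_blocks


def dstat(p1, p2, p3, p4=None, block_size_snps: int = DEFAULT_BLOCK_SIZE) -> DStatResult:
    """ABBA-BABA D for per-site derived frequencies of (P1, P2, P3, Outgroup).

    ``D = sum(ABBA - BABA) / sum(ABBA + BABA)`` with ``ABBA = (1-p1) p2 p3
    (1-p4)`` and ``BABA = p1 (1-p2) p3 (1-p4)``; a missing ``p4`` means a
    polarized outgroup fixed for the ancestral allele. Positive D marks
    excess derived-allele sharing between P2 and P3.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.zeros_like(p1) if p4 is None else np.asarray(p4, dtype=float)
    if not (p1.shape == p2.shape == p3.shape == p4.shape):
        raise ValueError("frequency arrays must align")
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
    p1, p2, p3, p4 = p1[ok], p2[ok], p3[ok], p4[ok]
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num = abba - baba
    den = abba + baba
    tot_den = den.sum()
    if tot_den == 0:
        raise ZeroDivisionError("no informative sites (ABBA + BABA sums to zero)")
    d = num.sum() / tot_den
    edges = _block_edges(len(num), block_size_snps)
    se, n_blocks = _jackknife_ratio(num, den, edges)
    z = d / se if se > 0 else np.nan
    return DStatResult(
        d=float(d), abba_sum=float(abba.sum()), baba_sum=float(baba.sum()),
        se=float(se), z=float(z), n_blocks=n_blocks,
        block_size=block_size_snps, n_sites=int(len(num)),
    )


def f3(
    c_freq,
    a_freq,
    b_freq,
    n_c,
    block_size_snps: int = DEFAULT_BLOCK_SIZE,
    labels=("target", "sourceA", "sourceB"),
) -> F3Result:
    """Three-population f3(Target; A, B) with finite-sample correction.

    Per site ``(c - a)(c - b) - c(1 - c)/(n_c - 1)`` averaged over sites;
    a significantly negative value indicates the target is admixed between
    relatives of the two sources. ``n_c`` is the target's allele count.
    """
    c = np.asarray(c_freq, dtype=float)
    a = np.asarray(a_freq, dtype=float)
    b = np.asarray(b_freq, dtype=float)
    n = np.broadcast_to(np.asarray(n_c, dtype=float), c.shape)
    if not (c.shape == a.shape == b.shape):
        raise ValueError("frequency arrays must align")
    if np.any(n < 2):
        raise ValueError("target allele count must be at least 2")
    ok = ~(np.isnan(c) | np.isnan(a) | np.isnan(b))
    c, a, b, n = c[ok], a[ok], b[ok], n[ok]
    if c.size == 0:
        raise ValueError("no sites")
    vals = (c - a) * (c - b) - c * (1 - c) / (n - 1)
    ones = np.ones_like(vals)
    stat = vals.mean()
    edges = _block_edges(len(vals), block_size_snps)
    se, n_blocks = _jackknife_ratio(vals, ones, edges)
    z = stat / se if se > 0 else np.nan
    return F3Result(
        f3=float(stat), se=float(se), z=float(z),
        target=labels[0], source_a=labels[1], source_b=labels[2],
        n_blocks=n_blocks, n_sites=int(len(vals)),
    )


def _pop_freqs(dataset, pop: str):
    if pop in (None, "ANC", "ancestral_outgroup"):
        return np.zeros(dataset.sites.n_sites)
    return dataset.sites.derived_freq(pop)


def dstat_quartets(dataset, quartets, block_size_snps: int = DEFAULT_BLOCK_SIZE) -> pd.DataFrame:
    """One D-statistic per (P1, P2, P3, Outgroup) quartet of populations.

    The outgroup slot accepts "ANC" (fixed-ancestral after polarization) or
    any genotyped population. No multiple-testing correction is applied to
    the emitted Z scores; interpret families of quartets accordingly.
    """
    rows = []
    for quartet in quartets:
        q = tuple(quartet)
        if len(q) != 4 or len(set(q)) != 4:
            raise ValueError(f"quartet must name 4 distinct populations: {q}")
        freqs = [_pop_freqs(dataset, p) for p in q]
        res = dstat(*freqs, block_size_snps=block_size_snps)
        rows.append(
            {
                "p1": q[0], "p2": q[1], "p3": q[2], "outgroup": q[3],
                "d": res.d, "se": res.se, "z": res.z,
                "n_blocks": res.n_blocks, "n_sites": res.n_sites,
            }
        )
    return pd.DataFrame(rows)


def f3_test(dataset, target: str, source_a: str, source_b: str, block_size_snps: int = DEFAULT_BLOCK_SIZE) -> F3Result:
    """f3 on a dataset's derived-frequency tables."""
    c = dataset.sites.derived_freq(target)
    a = dataset.sites.derived_freq(source_a)
    b = dataset.sites.derived_freq(source_b)
    _, n_c = dataset.sites.derived_counts(target)
    ok = n_c >= 2
    return f3(c[ok], a[ok], b[ok], n_c[ok], block_size_snps, labels=(target, source_a, source_b))
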