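"""Masking and site-eligibility bookkeeping.

Masks combine repeat intervals, numt intervals and sites whose total read
depth across the cohort exceeds a threshold (strictly greater; such pileups
are characteristic of unmasked repeats). Provenance counts attribute each
masked site to the first source that masks it in the order repeat -> numt ->
depth; the union itself is order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _intervals as iv
from .layout import GenomeLayout
from .sites import SiteTable

DEFAULT_DEPTH_THRESHOLD = 200
SEX_CHROM_NAMES = frozenset({"X", "chrX", "Y", "chrY"})


@dataclass
class MaskTrack:
    """Merged mask intervals with per-source disjoint contribution counts."""

    intervals: dict = field(default_factory=dict)
    provenance_counts: dict = field(default_factory=dict)
    genome_length: int = 0

    @property
    def masked_sites(self) -> int:
        return iv.track_length(self.intervals)

    def contains(self, chrom: str, positions) -> np.ndarray:
        arr = self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        return iv.contains(arr, positions)


@dataclass
class MaskReport:
    masked_sites: int
    masked_fraction: float  # percent of the genome, full precision
    per_source: dict

    @property
    def masked_fraction_display(self) -> str:
        return f"{self.masked_fraction:.2f}"


def _as_track(track) -> dict:
    if track is None:
        return {}
    return {c: iv.normalize(a) for c, a in dict(track).items()}


def depth_track_to_intervals(depth_track, depth_threshold: int) -> dict:
    """Collapse per-site depths into intervals of sites with depth > threshold."""
    if depth_track is None:
        return {}
    if isinstance(depth_track, dict):
        # already interval form
        return _as_track(depth_track)
    df = depth_track
    out: dict = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp.loc[grp["total_depth"] > depth_threshold, "pos"].to_numpy(dtype=np.int64)
        if pos.size:
            out[chrom] = iv.normalize(np.stack([pos, pos + 1], axis=1))
    return out


def compile_mask(
    repeat_track,
    numt_track,
    depth_track,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    layout: GenomeLayout | None = None,
) -> MaskTrack:
    """Union of repeat, numt and high-depth sites with provenance accounting.

    ``depth_track`` may be a DataFrame (chrom, pos, total_depth) with 0-based
    positions, a precomputed {chrom: intervals} dict of already-thresholded
    high-depth regions, or None.
    """
    if depth_threshold <= 0:
        raise ValueError("depth threshold must be positive")
    repeat = _as_track(repeat_track)
    numt = _as_track(numt_track)
    high_depth = depth_track_to_intervals(depth_track, depth_threshold)

    if layout is not None:
        lengths = layout.lengths
        for name, track in (("repeat", repeat), ("numt", numt), ("depth", high_depth)):
            for chrom, arr in track.items():
                if chrom not in lengths:
                    raise ValueError(f"{name} track references unknown chromosome {chrom!r}")
                if len(arr) and (arr[:, 0].min() < 0 or arr[:, 1].max() > lengths[chrom]):
                    raise ValueError(f"{name} interval outside {chrom} bounds")
        genome_length = layout.total_bp
    else:
        genome_length = iv.track_length(iv.track_union(repeat, numt, high_depth))

    n_repeat = iv.track_length(repeat)
    mask = repeat
    numt_new = iv.track_subtract(numt, mask)
    n_numt = iv.track_length(numt_new)
    mask = iv.track_union(mask, numt)
    depth_new = iv.track_subtract(high_depth, mask)
    n_depth = iv.track_length(depth_new)
    mask = iv.track_union(mask, high_depth)

    return MaskTrack(
        intervals=mask,
        provenance_counts={"repeat": n_repeat, "numt": n_numt, "high_depth": n_depth},
        genome_length=int(genome_length),
    )


def mask_report(mask: MaskTrack) -> MaskReport:
    """Masked totals and genome fraction (percent, stored at full precision)."""
    if mask.genome_length <= 0:
        raise ValueError("genome length must be positive")
    masked = mask.masked_sites
    return MaskReport(
        masked_sites=masked,
        masked_fraction=100.0 * masked / mask.genome_length,
        per_source=dict(mask.provenance_counts),
    )


def apply_mask(sites: SiteTable, mask: MaskTrack) -> SiteTable:
    """Drop variant sites falling inside the mask."""
    keep = np.ones(sites.n_sites, dtype=bool)
    for chrom in sites.sites["chrom"].unique():
        sel = (sites.sites["chrom"] == chrom).to_numpy()
        keep[sel] = ~mask.contains(chrom, sites.sites.loc[sel, "pos"].to_numpy())
    return sites.subset(keep)


def filter_variants_for_structure(
    sites: SiteTable,
    min_individuals: int = 40,
    min_maf: float = 0.05,
) -> SiteTable:
    """Site filter used ahead of structure/clustering analyses.

    Keeps autosomal sites called in at least ``min_individuals`` individuals
    whose sample minor-allele frequency (over non-missing alleles) is at
    least ``min_maf`` (inclusive: "below 5%" is removed).
    """
    if min_individuals < 0 or not (0.0 <= min_maf <= 0.5):
        raise ValueError("thresholds out of range")
    called = (sites.genotypes[:, :, 0] >= 0).sum(axis=1)
    alt = (sites.genotypes == 1).sum(axis=(1, 2))
    tot = (sites.genotypes >= 0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    autosomal = ~sites.sites["chrom"].isin(SEX_CHROM_NAMES).to_numpy()
    keep = autosomal & (called >= min_individuals) & (tot > 0) & (maf >= min_maf)
    return sites.subset(keep)


def window_coverage_filter(
    windows,
    per_pop_coverage: dict,
    min_covered_bp: int = 10_000,
    min_individuals: int = 5,
) -> list:
    """Windows where every population covers > ``min_covered_bp`` sites.

    ``per_pop_coverage`` maps population -> chrom -> either a constant
    genotyped-individual count or a per-base count array. A base counts as
    covered for a population when at least ``min_individuals`` individuals
    are genotyped there; the window is eligible only if the covered-base
    count strictly exceeds ``min_covered_bp`` in *every* population.
    """
    eligible = []
    for chrom, start, end in windows:
        if end <= start:
            continue
        ok = True
        for pop, track in per_pop_coverage.items():
            cov = track.get(chrom)
            if cov is None:
                ok = False
                break
            if np.isscalar(cov):
                covered = (end - start) if cov >= min_individuals else 0
            else:
                arr = np.asarray(cov)
                if end > arr.size:
                    raise ValueError(f"window beyond coverage track on {chrom}")
                covered = int((arr[start:end] >= min_individuals).sum())
            if covered <= min_covered_bp:
                ok = False
                break
        if ok:
            eligible.append((chrom, int(start), int(end)))
    return eligible


def structure_filter_report(before: SiteTable, after: SiteTable) -> pd.DataFrame:
    return pd.DataFrame(
        {"stage": ["input", "retained"], "n_sites": [before.n_sites, after.n_sites]}
    )
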