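"""Genomic category annotation: exons, introns, gene flanks, intergenic.

Categories follow the precedence exon > intron > flank > intergenic, with
"flank" meaning a fixed margin (default 25 kb) on each side of a gene body.
Third-codon positions are modelled as every third base inside an exon
interval on the + strand (offset 2 from the exon start), the most degenerate
codon site and hence the one used for substitution counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _intervals as iv
from .layout import GenomeLayout
from .sites import CATEGORIES

DEFAULT_FLANK_BP = 25_000


@dataclass
class GenomeAnnotation:
    """Per-chromosome interval tracks for genes and derived categories."""

    genes: dict = field(default_factory=dict)
    exons: dict = field(default_factory=dict)
    introns: dict = field(default_factory=dict)
    flanks: dict = field(default_factory=dict)

    def categories(self, chrom: str, positions) -> np.ndarray:
        """Category of each position under exon > intron > flank precedence."""
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(pos.shape, "intergenic", dtype=object)
        for name, track in (("flank", self.flanks), ("intron", self.introns), ("exon", self.exons)):
            arr = track.get(chrom)
            if arr is not None and len(arr):
                out[iv.contains(arr, pos)] = name
        return out.astype(str)

    def third_codon(self, chrom: str, positions) -> np.ndarray:
        """True where the position is the third base of a + strand exon codon."""
        pos = np.asarray(positions, dtype=np.int64)
        out = np.zeros(pos.shape, dtype=bool)
        exons = self.exons.get(chrom)
        if exons is None or len(exons) == 0:
            return out
        exons = iv.normalize(exons)
        idx = np.searchsorted(exons[:, 0], pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos.shape, dtype=bool)
        inside[ok] = pos[ok] < exons[idx[ok], 1]
        rel = pos[inside] - exons[idx[inside], 0]
        out[inside] = rel % 3 == 2
        return out


    def third_codon_total(self) -> int:
        """Number of third-codon positions in the whole exon track."""
        return sum(
            int(((arr[:, 1] - arr[:, 0]) // 3).sum()) for arr in self.exons.values() if len(arr)
        )


def build_annotation(
    layout: GenomeLayout,
    gene_spacing: int = 150_000,
    exons_per_gene: int = 8,
    exon_bp: int = 200,
    intron_bp: int = 1_800,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> GenomeAnnotation:
    """Deterministic gene models tiled along each chromosome.

    Genes start at ``gene_spacing`` intervals (first at one spacing in) and
    consist of alternating exons and introns. The layout is intentionally
    regular: annotation structure is plumbing, not a random variable.
    """
    ann = GenomeAnnotation()
    gene_len = exons_per_gene * exon_bp + (exons_per_gene - 1) * intron_bp
    for chrom, length in layout:
        genes, exons, introns, flanks = [], [], [], []
        start = gene_spacing
        while start + gene_len <= length:
            genes.append((start, start + gene_len))
            cur = start
            for k in range(exons_per_gene):
                exons.append((cur, cur + exon_bp))
                cur += exon_bp
                if k < exons_per_gene - 1:
                    introns.append((cur, cur + intron_bp))
                    cur += intron_bp
            flanks.append((max(0, start - flank_bp), start))
            flanks.append((start + gene_len, min(length, start + gene_len + flank_bp)))
            start += gene_spacing + gene_len
        ann.genes[chrom] = iv.normalize(np.array(genes, dtype=np.int64).reshape(-1, 2))
        ann.exons[chrom] = iv.normalize(np.array(exons, dtype=np.int64).reshape(-1, 2))
        ann.introns[chrom] = iv.normalize(np.array(introns, dtype=np.int64).reshape(-1, 2))
        ann.flanks[chrom] = iv.normalize(np.array(flanks, dtype=np.int64).reshape(-1, 2))
    return ann


def validate_annotation(ann: GenomeAnnotation, layout: GenomeLayout) -> None:
    lengths = layout.lengths
    for track in (ann.genes, ann.exons, ann.introns, ann.flanks):
        for chrom, arr in track.items():
            if chrom not in lengths:
                raise ValueError(f"annotation references unknown chromosome {chrom!r}")
            if len(arr) and (arr[:, 0].min() < 0 or arr[:, 1].max() > lengths[chrom]):
                raise ValueError(f"annotation interval outside {chrom} bounds")


assert set(CATEGORIES) == {"exon", "intron", "flank", "intergenic"}
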