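"""Genome layout: chromosome names and lengths, 0-based half-open throughout."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes with positive lengths (bp)."""

    chromosomes: tuple = field(default_factory=tuple)  # ((name, length_bp), ...)

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self):
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self):
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self):
        return iter(self.chromosomes)


def default_layout(scale: float = 1.0, n_chromosomes: int = 5, chrom_bp: int = 2_000_000) -> GenomeLayout:
    """Desk-scale layout: ``n_chromosomes`` of ``chrom_bp * scale`` bases each."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    length = max(int(round(chrom_bp * scale)), 1)
    return GenomeLayout(tuple((f"chr{i + 1}", length) for i in range(n_chromosomes)))
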