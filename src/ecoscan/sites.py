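"""The per-site substrate of all statistics.

A :class:`SiteTable` holds variant sites (one row per biallelic site) plus a
dense diploid genotype array. Genotype alleles are coded against REF/ALT
(0 = REF, 1 = ALT, -1 = missing); polarized (ancestral/derived) views are
derived from the per-site ancestral state, which must equal REF or ALT to be
usable — otherwise the site is treated as unpolarizable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "anc", "category", "third_codon"]
CATEGORIES = ("exon", "intron", "flank", "intergenic")
_BASES = frozenset("ACGT")


class SiteTable:
    """Biallelic variant sites with per-individual diploid genotypes.

    Parameters
    ----------
    sites:
        DataFrame with columns chrom, pos (0-based), ref, alt, anc
        (A/C/G/T or "N" for unknown), category, third_codon (bool).
        Positions must be strictly increasing within each chromosome.
    genotypes:
        int8 array of shape (n_sites, n_individuals, 2); 0=REF, 1=ALT,
        -1=missing.
    individuals:
        sample names, aligned to axis 1 of ``genotypes``.
    popmap:
        individual -> population label.
    """

    def __init__(self, sites: pd.DataFrame, genotypes: np.ndarray, individuals, popmap: dict):
        sites = sites.reset_index(drop=True)
        missing = [c for c in SITE_COLUMNS if c not in sites.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 3 or genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_individuals, 2)")
        if genotypes.shape[0] != len(sites):
            raise ValueError("genotype rows do not match site rows")
        individuals = list(individuals)
        if genotypes.shape[1] != len(individuals):
            raise ValueError("genotype columns do not match individuals")
        unknown = [i for i in individuals if i not in popmap]
        if unknown:
            raise ValueError(f"individuals missing from popmap: {unknown[:5]}")
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.sites = sites
        self.genotypes = genotypes
        self.individuals = individuals
        self.popmap = dict(popmap)
        self._ind_index = {name: i for i, name in enumerate(individuals)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self):
        return sorted(set(self.popmap[i] for i in self.individuals))

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.array([self._ind_index[i] for i in self.individuals if self.popmap[i] == pop], dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"unknown or empty population: {pop!r}")
        return idx

    def individual_index(self, name: str) -> int:
        if name not in self._ind_index:
            raise KeyError(f"unknown individual: {name!r}")
        return self._ind_index[name]

    # -- allele bookkeeping ------------------------------------------------
    @property
    def polarized(self) -> np.ndarray:
        """True where the ancestral state equals REF or ALT."""
        anc = self.sites["anc"].to_numpy()
        return (anc == self.sites["ref"].to_numpy()) | (anc == self.sites["alt"].to_numpy())

    @property
    def derived_is_alt(self) -> np.ndarray:
        """True where ALT is the derived allele (ancestral == REF)."""
        return self.sites["anc"].to_numpy() == self.sites["ref"].to_numpy()

    def alt_counts(self, pop: str):
        """Per-site (ALT allele count, called allele count) for a population."""
        g = self.genotypes[:, self.pop_indices(pop), :]
        called = (g >= 0).sum(axis=(1, 2))
        alt = (g == 1).sum(axis=(1, 2))
        return alt.astype(np.int64), called.astype(np.int64)

    def alt_freq(self, pop: str) -> np.ndarray:
        alt, called = self.alt_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / np.maximum(called, 1), np.nan)

    def derived_counts(self, pop: str):
        """Per-site (derived count, called count); unpolarized sites -> (-1, total)."""
        alt, called = self.alt_counts(pop)
        der = np.where(self.derived_is_alt, alt, called - alt)
        der = np.where(self.polarized, der, -1)
        return der.astype(np.int64), called

    def derived_freq(self, pop: str) -> np.ndarray:
        """Derived allele frequency; NaN where unpolarized or uncalled."""
        der, called = self.derived_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called > 0, der / np.maximum(called, 1), np.nan)
        return np.where(der >= 0, f, np.nan)

    def derived_genotypes(self, individuals) -> np.ndarray:
        """Genotypes recoded 0=ancestral, 1=derived, -1=missing.

        Rows that are not polarizable are returned all-missing.
        """
        idx = np.array([self.individual_index(i) for i in individuals], dtype=np.intp)
        g = self.genotypes[:, idx, :].astype(np.int8).copy()
        flip = ~self.derived_is_alt
        sub = g[flip]
        called = sub >= 0
        sub[called] = 1 - sub[called]
        g[flip] = sub
        g[~self.polarized] = -1
        return g

    def called_individuals(self, pop: str) -> np.ndarray:
        """Per-site count of individuals with a called genotype in ``pop``."""
        g = self.genotypes[:, self.pop_indices(pop), :]
        return (g[:, :, 0] >= 0).sum(axis=1).astype(np.int64)

    # -- structural helpers ------------------------------------------------
    def subset(self, mask) -> "SiteTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        return SiteTable(
            self.sites.iloc[idx].reset_index(drop=True),
            self.genotypes[idx],
            self.individuals,
            self.popmap,
        )

    def chrom_slice(self, chrom: str):
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        return idx

    def equals(self, other: "SiteTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.popmap == other.popmap
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self):
        return f"SiteTable(n_sites={self.n_sites}, n_individuals={self.n_individuals}, populations={self.populations})"
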