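"""Ancestral-state assignment, derived-mutation classification and TMRCA.

Derived mutations at third-codon positions are the substrate: the most
degenerate codon site minimizes the footprint of purifying selection on
substitution counts. Counts are split by mutation class (transition vs
transversion) and by whether the derived allele is fixed across the whole
panel ("stem" mutations predating the radiation) or segregates within it.
The TMRCA estimator converts a derived-mutation count into years using a
class-specific share of the total substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sites import SiteTable

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


# -- ancestral assignment --------------------------------------------------


@dataclass
class AncestralCoverageReport:
    inferable: int
    total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.inferable / self.total if self.total else 0.0


def ancestral_coverage_report(inferable: int, total: int) -> AncestralCoverageReport:
    if total <= 0:
        raise ValueError("total bases must be positive")
    return AncestralCoverageReport(int(inferable), int(total))


def assign_ancestral(sites: SiteTable, outgroup_alleles, genome_length: int | None = None):
    """Assign ancestral states from an outgroup allele track.

    ``outgroup_alleles`` is aligned to the site table (one base or "N" per
    site). The ancestral state is the outgroup consensus where it equals one
    of the two observed alleles; anything else stays unknown rather than
    fabricating a third state. Returns the updated table and a coverage
    report (over ``genome_length`` when given, else over the variant sites).
    """
    out = np.asarray(outgroup_alleles, dtype=object)
    if out.shape[0] != sites.n_sites:
        raise ValueError("outgroup track not aligned to site table")
    ref = sites.sites["ref"].to_numpy()
    alt = sites.sites["alt"].to_numpy()
    anc = np.where((out == ref) | (out == alt), out, "N")
    df = sites.sites.copy()
    df["anc"] = anc.astype(str)
    new = SiteTable(df, sites.genotypes, sites.individuals, sites.popmap)
    inferable = int((anc != "N").sum())
    total = int(genome_length) if genome_length else sites.n_sites
    return new, AncestralCoverageReport(inferable, total)


# -- mutation classes ------------------------------------------------------


def classify_mutation(ancestral: str, derived: str) -> str:
    """"transition" for purine<->purine / pyrimidine<->pyrimidine, else "transversion"."""
    a, d = str(ancestral).upper(), str(derived).upper()
    if a not in _BASES or d not in _BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ancestral!r}->{derived!r}")
    if a == d:
        raise ValueError("ancestral and derived bases are identical")
    same_family = ({a, d} <= _PURINES) or ({a, d} <= _PYRIMIDINES)
    return "transition" if same_family else "transversion"


@dataclass
class DerivedCounts:
    """Derived third-codon mutation counts partitioned by class and sharing.

    ``mixed`` counts sites that are a transversion in at least one lineage
    but a transition in at least one other; by convention they are included
    in the transversion class total.
    """

    fixed_transitions: int = 0
    fixed_transversions: int = 0
    within_transitions: int = 0
    within_transversions: int = 0
    mixed: int = 0
    total_third_codon_sites: int = 0
    complete_third_codon_sites: int = 0

    @property
    def total_transitions(self) -> int:
        return self.fixed_transitions + self.within_transitions

    @property
    def total_transversions(self) -> int:
        return self.fixed_transversions + self.within_transversions + self.mixed

    def validate(self):
        vals = [
            self.fixed_transitions, self.fixed_transversions,
            self.within_transitions, self.within_transversions, self.mixed,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("counts must be non-negative")


def count_derived_by_class(
    sites: SiteTable,
    panel,
    maf_cutoff: float = 0.1,
    frequency: str = "derived",
) -> DerivedCounts:
    """Count derived third-codon mutations in a panel of individuals.

    Sites with missing data in any panel individual are masked out. The
    low-frequency cutoff (default 0.1, guarding against sequencing error)
    applies to the derived-allele frequency by default; ``frequency="minor"``
    folds it. Each retained polymorphic-or-derived site is classed as
    transition/transversion and as fixed (derived in every panel allele)
    versus within-lineage.
    """
    if frequency not in ("derived", "minor"):
        raise ValueError("frequency must be 'derived' or 'minor'")
    panel = list(panel)
    if not panel:
        raise ValueError("panel is empty")
    third = sites.sites["third_codon"].to_numpy()
    polarized = sites.polarized
    if not polarized.any() and third.any():
        raise ValueError("site table is not polarized")
    g = sites.derived_genotypes(panel)  # (n_sites, n_panel, 2); -1 missing/unpolarized
    complete = (g >= 0).all(axis=(1, 2))
    use = third & polarized & complete
    counts = DerivedCounts(
        total_third_codon_sites=int(third.sum()),
        complete_third_codon_sites=int((third & complete & polarized).sum()),
    )
    if not use.any():
        return counts
    der = (g[use] == 1).sum(axis=(1, 2))
    n_alleles = 2 * len(panel)
    freq = der / n_alleles
    if frequency == "minor":
        freq = np.minimum(freq, 1.0 - freq)
    keep = (der > 0) & (freq >= maf_cutoff)
    rows = np.flatnonzero(use)[keep]
    der = der[keep]
    ref = sites.sites["ref"].to_numpy()
    alt = sites.sites["alt"].to_numpy()
    anc = sites.sites["anc"].to_numpy()
    for row, d in zip(rows, der):
        derived_allele = alt[row] if anc[row] == ref[row] else ref[row]
        cls = classify_mutation(anc[row], derived_allele)
        fixed = d == n_alleles
        if cls == "transition":
            if fixed:
                counts.fixed_transitions += 1
            else:
                counts.within_transitions += 1
        else:
            if fixed:
                counts.fixed_transversions += 1
            else:
                counts.within_transversions += 1
    return counts


def estimate_tstv(counts: DerivedCounts, scope: str = "within_lineage", include_mixed: bool = False) -> float:
    """Transition/transversion ratio of derived mutations.

    ``scope="within_lineage"`` uses mutations segregating within the clade
    (the default, matching how a radiation-internal Ts/Tv is read off);
    ``scope="all"`` includes stem mutations. Mixed-state sites join the
    transversion denominator only when ``include_mixed`` is set.
    """
    counts.validate()
    if scope == "within_lineage":
        ti, tv = counts.within_transitions, counts.within_transversions
    elif scope == "all":
        ti, tv = counts.total_transitions, counts.fixed_transversions + counts.within_transversions
    else:
        raise ValueError("scope must be 'within_lineage' or 'all'")
    if include_mixed:
        tv += counts.mixed
    if tv == 0:
        raise ZeroDivisionError("transversion count is zero; Ts/Tv undefined")
    return ti / tv


# -- sharing ---------------------------------------------------------------


def derived_sharing(
    sites: SiteTable,
    focal: str,
    other: str,
    mutation_class: str = "combined",
    maf_cutoff: float = 0.1,
    panel=None,
):
    """(focal derived-site count, count also derived in ``other``).

    Considers polarized third-codon sites where both individuals are
    genotyped (and, when ``panel`` is given, complete in the whole panel
    with the frequency cutoff applied over that panel).
    """
    if mutation_class not in ("transition", "transversion", "combined"):
        raise ValueError("mutation_class must be transition/transversion/combined")
    panel = list(panel) if panel is not None else [focal, other]
    if focal not in panel or other not in panel:
        raise ValueError("focal and other must be in the panel")
    g = sites.derived_genotypes(panel)
    third = sites.sites["third_codon"].to_numpy()
    complete = (g >= 0).all(axis=(1, 2))
    use = third & complete
    if maf_cutoff > 0:
        der = (g == 1).sum(axis=(1, 2))
        freq = der / (2 * len(panel))
        use &= (freq >= maf_cutoff) | (der == 0)
    if mutation_class != "combined":
        ref = sites.sites["ref"].to_numpy()
        alt = sites.sites["alt"].to_numpy()
        anc = sites.sites["anc"].to_numpy()
        cls = np.array(
            [
                classify_mutation(a, al if a == r else r) if a in _BASES and al != a else ""
                for a, r, al in zip(anc, ref, alt)
            ],
            dtype=object,
        )
        use &= cls == mutation_class
    fi, oi = panel.index(focal), panel.index(other)
    focal_der = (g[use, fi, :] == 1).any(axis=1)
    other_der = (g[use, oi, :] == 1).any(axis=1)
    n_focal = int(focal_der.sum())
    n_shared = int((focal_der & other_der).sum())
    return n_focal, n_shared


def shared_derived_fraction(
    sites: SiteTable,
    focal: str,
    other: str,
    mutation_class: str = "combined",
    maf_cutoff: float = 0.1,
    panel=None,
) -> float:
    """Fraction of the focal individual's derived alleles carried by ``other``."""
    n_focal, n_shared = derived_sharing(sites, focal, other, mutation_class, maf_cutoff, panel)
    if n_focal == 0:
        raise ZeroDivisionError("focal individual carries no derived alleles at compared sites")
    return n_shared / n_focal


# -- TMRCA -----------------------------------------------------------------


@dataclass
class TMRCAEstimate:
    derived_count: int
    mutation_class: str
    L: int
    mu_total: float
    tstv: float | None
    years: float
    interval_years: tuple | None


def class_rate(mu_total: float, mutation_class: str, tstv: float | None) -> float:
    """Share of the total substitution rate carried by a mutation class."""
    if mu_total <= 0:
        raise ValueError("mu_total must be positive")
    if mutation_class == "combined":
        return mu_total
    if tstv is None or tstv <= 0:
        raise ValueError("tstv must be positive for class-specific rates")
    if mutation_class == "transversion":
        return mu_total / (1.0 + tstv)
    if mutation_class == "transition":
        return mu_total * tstv / (1.0 + tstv)
    raise ValueError("mutation_class must be transition/transversion/combined")


def estimate_tmrca(
    derived_count: int,
    mutation_class: str,
    L: int,
    mu_total: float,
    mu_hpd: tuple | None = None,
    tstv: float | None = None,
) -> TMRCAEstimate:
    """Years to accumulate ``derived_count`` mutations over ``L`` sites.

    ``mu_total`` is the total substitution rate per site per year; the
    class rate is its transition or transversion share given ``tstv``.
    The interval evaluates the same formula at the rate HPD bounds (a larger
    rate gives a younger age, so the endpoints swap).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if derived_count < 0:
        raise ValueError("derived_count must be non-negative")
    rate = class_rate(mu_total, mutation_class, tstv)
    years = derived_count / (L * rate)
    interval = None
    if mu_hpd is not None:
        lo_rate, hi_rate = mu_hpd
        if not (0 < lo_rate <= hi_rate):
            raise ValueError("mu_hpd bounds must be positive and ordered")
        young = derived_count / (L * class_rate(hi_rate, mutation_class, tstv))
        old = derived_count / (L * class_rate(lo_rate, mutation_class, tstv))
        interval = (young, old)
    return TMRCAEstimate(
        derived_count=int(derived_count),
        mutation_class=mutation_class,
        L=int(L),
        mu_total=mu_total,
        tstv=tstv,
        years=years,
        interval_years=interval,
    )
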