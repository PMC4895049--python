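"""Synthetic cohorts with the statistical structure of an ecotype radiation.

The generator realizes a coalescent model of five populations descending
from one ancestor through sequential founder bottlenecks (Ne < 1,000)
followed by expansion, with one directional admixture pulse. Mutations use
an HKY model whose transition/transversion bias is set so that derived
mutations resemble the strongly transition-biased spectrum seen at mammal
third-codon positions. Truth tables (the model itself, injected sweeps)
ride along for parameter-recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from . import _intervals as iv
from .annotate import GenomeAnnotation, build_annotation, validate_annotation
from .layout import GenomeLayout, default_layout
from .sites import SiteTable

PAPER_SAMPLE_SIZES = {"resident": 10, "transient": 10, "B1": 7, "B2": 11, "C": 10}
DEFAULT_MU = 2.34e-8  # per site per generation, autosomal
DEFAULT_RECOMB = 1e-8
DEFAULT_GENERATION_TIME = 25.7  # years; ~250 KY radiation over ~9,700 generations
DEFAULT_KAPPA = 7.6  # HKY ts/tv bias; equal base frequencies give Ts/Tv ~ 3.8

_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass
class DemographicModel:
    """Populations, epochs, splits and pulses defining the simulated truth.

    ``epochs[pop]`` lists ``(start_generations_ago, diploid_Ne)`` ordered by
    increasing time ago; each epoch applies from its start time backwards
    until the next entry (or the population's split into its parent).
    ``splits`` are ``(child, parent, time_generations_ago)``; ``pulses`` are
    forward-time ``(source, dest, time_generations_ago, fraction)``.
    """

    populations: list
    epochs: dict
    splits: list = field(default_factory=list)
    pulses: list = field(default_factory=list)
    mu: float = DEFAULT_MU
    recomb: float = DEFAULT_RECOMB
    generation_time_years: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self):
        if self.mu <= 0 or self.recomb <= 0 or self.generation_time_years <= 0:
            raise ValueError("mu, recomb and generation time must be positive")
        for pop in self.populations:
            eps = self.epochs.get(pop)
            if not eps:
                raise ValueError(f"population {pop!r} has no epochs")
            times = [t for t, _ in eps]
            if times != sorted(times) or len(set(times)) != len(times):
                raise ValueError(f"epochs for {pop!r} not strictly time-ordered")
            if any(ne < 2 for _, ne in eps):
                raise ValueError(f"epoch Ne < 2 for {pop!r}")
        parents = {}
        for child, parent, t in self.splits:
            if child not in self.populations or parent not in self.populations:
                raise ValueError(f"split references unknown population: {(child, parent)}")
            if t <= 0:
                raise ValueError("split times must be positive")
            parents[child] = (parent, float(t))
        for child in parents:
            # walk to the root; times must strictly increase along the lineage
            seen = set()
            node, t = child, parents[child][1]
            while node in parents:
                if node in seen:
                    raise ValueError("cycle in population splits")
                seen.add(node)
                parent, pt = parents[node]
                if node != child and pt <= t:
                    raise ValueError("split times not strictly ordered along lineage")
                node, t = parent, pt
        for source, dest, t, f in self.pulses:
            if source not in self.populations or dest not in self.populations:
                raise ValueError("pulse references unknown population")
            if not (0.0 < f < 1.0):
                raise ValueError(f"pulse fraction must be in (0, 1), got {f}")
            if t <= 0:
                raise ValueError("pulse time must be positive")

    # -- structure ---------------------------------------------------------
    @property
    def leaves(self) -> list:
        internal = {parent for _, parent, _ in self.splits}
        return [p for p in self.populations if p not in internal]

    def split_time(self, child: str) -> float:
        for c, _, t in self.splits:
            if c == child:
                return float(t)
        raise KeyError(child)

    def bottleneck_epochs(self, ne_below: float = 1000.0) -> list:
        """(pop, start_time, Ne) for every epoch with Ne below the cutoff."""
        return [
            (pop, t, ne)
            for pop in self.populations
            for t, ne in self.epochs[pop]
            if ne < ne_below
        ]

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        for pop in self.populations:
            dem.add_population(name=pop, initial_size=self.epochs[pop][0][1])
        for pop in self.populations:
            for t, ne in self.epochs[pop][1:]:
                dem.add_population_parameters_change(time=t, population=pop, initial_size=ne)
        by_event = {}
        for child, parent, t in self.splits:
            by_event.setdefault((parent, float(t)), []).append(child)
        for (parent, t), children in by_event.items():
            dem.add_population_split(time=t, derived=children, ancestral=parent)
        for source, dest, t, f in self.pulses:
            # forward-time pulse source->dest == backward mass migration dest->source
            dem.add_mass_migration(time=t, source=dest, dest=source, proportion=f)
        dem.sort_events()
        return dem

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "epochs": {p: [[float(t), float(n)] for t, n in e] for p, e in self.epochs.items()},
            "splits": [[c, p, float(t)] for c, p, t in self.splits],
            "pulses": [[s, d, float(t), float(f)] for s, d, t, f in self.pulses],
            "mu": self.mu,
            "recomb": self.recomb,
            "generation_time_years": self.generation_time_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            populations=list(d["populations"]),
            epochs={p: [tuple(e) for e in eps] for p, eps in d["epochs"].items()},
            splits=[tuple(s) for s in d["splits"]],
            pulses=[tuple(p) for p in d["pulses"]],
            mu=d["mu"],
            recomb=d["recomb"],
            generation_time_years=d["generation_time_years"],
        )


@dataclass
class SimulatedDataset:
    """A simulated cohort plus its annotation tracks and truth tables."""

    layout: GenomeLayout
    annotation: GenomeAnnotation
    repeats: dict
    sites: SiteTable
    depth: np.ndarray  # per variant site total read depth across the cohort
    outgroup: np.ndarray  # per variant site outgroup consensus base
    truth: dict

    @property
    def panel(self) -> dict:
        return self.sites.popmap

    def coverage(self) -> dict:
        """pop -> chrom -> genotyped-individual count (constant per chrom).

        The simulator genotypes every individual at every retained site, so
        callable coverage is uniform; real per-base tracks can be substituted
        when working from files.
        """
        counts = {}
        for pop in self.sites.populations:
            n = len(self.sites.pop_indices(pop))
            counts[pop] = {chrom: n for chrom, _ in self.layout}
        return counts


def build_paper_scenario(
    scale: float = 1.0,
    seed: int = 7,
    pulse_fraction: float = 0.1,
    pulse_time: float = 1000.0,
) -> DemographicModel:
    """Five-ecotype radiation: sequential founder bottlenecks plus one pulse.

    One ancestor gives rise (backwards: 7,000 / 5,000 / 3,000 / 1,500
    generations ago) to the transient, resident, and the Antarctic clade
    (C, then B1/B2). Every founder passes through a bottleneck epoch with
    Ne < 1,000 before expanding, and a directional pulse flows from a
    resident-related lineage into the transient. ``scale`` only checks
    positivity here; it scales the genome via :func:`default_layout`.
    ``pulse_fraction=0`` omits the pulse (a no-gene-flow null).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    del seed  # the scenario is fully deterministic; seed kept for interface symmetry
    populations = [
        "resident", "transient", "B1", "B2", "C",
        "anc_B", "anc_antarctic", "anc_rest", "ancestral",
    ]
    epochs = {
        "transient": [(0.0, 15000.0), (6850.0, 400.0)],
        "resident": [(0.0, 15000.0), (4650.0, 80.0)],
        "C": [(0.0, 25000.0), (2960.0, 900.0)],
        "B1": [(0.0, 25000.0), (1460.0, 900.0)],
        "B2": [(0.0, 25000.0), (1460.0, 950.0)],
        "anc_B": [(0.0, 20000.0)],
        "anc_antarctic": [(0.0, 20000.0), (4900.0, 600.0)],
        "anc_rest": [(0.0, 10000.0)],
        "ancestral": [(0.0, 10000.0)],
    }
    splits = [
        ("B1", "anc_B", 1500.0),
        ("B2", "anc_B", 1500.0),
        ("C", "anc_antarctic", 3000.0),
        ("anc_B", "anc_antarctic", 3000.0),
        ("resident", "anc_rest", 5000.0),
        ("anc_antarctic", "anc_rest", 5000.0),
        ("transient", "ancestral", 7000.0),
        ("anc_rest", "ancestral", 7000.0),
    ]
    pulses = []
    if pulse_fraction:
        pulses.append(("resident", "transient", float(pulse_time), float(pulse_fraction)))
    return DemographicModel(populations=populations, epochs=epochs, splits=splits, pulses=pulses)


def build_repeats(layout: GenomeLayout, seed: int, fraction: float = 0.05, per_chrom: int = 4) -> dict:
    """Seeded repeat-like intervals covering ~``fraction`` of each chromosome."""
    rng = np.random.default_rng(seed)
    track = {}
    for chrom, length in layout:
        rep_len = max(int(fraction * length / per_chrom), 1)
        starts = np.sort(rng.integers(0, max(length - rep_len, 1), size=per_chrom))
        track[chrom] = iv.normalize(np.stack([starts, starts + rep_len], axis=1))
    return track


def simulate_cohort(
    model: DemographicModel,
    layout: GenomeLayout,
    samples_per_pop: dict | None = None,
    seed: int = 1,
    outgroup_error: float = 0.0,
    missing_rate: float = 0.0,
    mean_depth: float = 2.0,
    kappa: float = DEFAULT_KAPPA,
    annotation: GenomeAnnotation | None = None,
    repeats: dict | None = None,
) -> SimulatedDataset:
    """Coalescent-simulate genotypes for a cohort under ``model``.

    Returns biallelic sites only, polarized against the simulated root state
    observed through an outgroup with mislabelling rate ``outgroup_error``
    (default 0 so printed-arithmetic checks stay exact). Per-site total read
    depth is drawn around ``mean_depth`` per individual, inflated inside
    repeat intervals to emulate unmasked-repeat pileups.
    """
    if samples_per_pop is None:
        samples_per_pop = {p: PAPER_SAMPLE_SIZES[p] for p in model.leaves if p in PAPER_SAMPLE_SIZES}
        if not samples_per_pop:
            raise ValueError("no default sample sizes for this model; pass samples_per_pop")
    unknown = set(samples_per_pop) - set(model.populations)
    if unknown:
        raise ValueError(f"unknown population labels: {sorted(unknown)}")
    if layout.total_bp <= 0 or not layout.names:
        raise ValueError("zero-length genome")
    if not (0.0 <= outgroup_error < 1.0) or not (0.0 <= missing_rate < 1.0):
        raise ValueError("rates must be in [0, 1)")

    if annotation is None:
        annotation = build_annotation(layout)
    validate_annotation(annotation, layout)
    if repeats is None:
        repeats = build_repeats(layout, seed=seed + 104729)

    pops_in_order = [p for p in model.populations if p in samples_per_pop]
    individuals, popmap = [], {}
    for pop in pops_in_order:
        for k in range(int(samples_per_pop[pop])):
            name = f"{pop}_{k}"
            individuals.append(name)
            popmap[name] = pop
    n_ind = len(individuals)

    demography = model.to_msprime()
    ss = np.random.SeedSequence(seed)
    chrom_seeds = ss.generate_state(2 * len(layout.names), dtype=np.uint32).reshape(-1, 2)
    rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    geno_chunks = []
    depth_chunks = []
    outgroup_chunks = []
    for (chrom, length), (s_anc, s_mut) in zip(layout, chrom_seeds):
        ts = msprime.sim_ancestry(
            samples={p: int(samples_per_pop[p]) for p in pops_in_order},
            demography=demography,
            sequence_length=length,
            recombination_rate=model.recomb,
            random_seed=int(s_anc) % (2**31 - 1) + 1,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=model.mu,
            model=msprime.HKY(kappa=kappa),
            random_seed=int(s_mut) % (2**31 - 1) + 1,
        )
        pos_list, anc_list, der_list, geno_list = [], [], [], []
        for var in ts.variants():
            alleles = [a for a in var.alleles if a is not None]
            if len(alleles) != 2:
                continue
            anc = var.site.ancestral_state
            if anc not in alleles or any(a not in "ACGT" for a in alleles):
                continue
            pos = int(var.site.position)
            if pos_list and pos <= pos_list[-1]:
                continue
            derived = alleles[1] if alleles[0] == anc else alleles[0]
            g = var.genotypes  # node-ordered; alleles index
            # recode to 0=ancestral allele, 1=derived allele
            anc_idx = alleles.index(anc)
            g01 = (g != anc_idx).astype(np.int8)
            pos_list.append(pos)
            anc_list.append(anc)
            der_list.append(derived)
            geno_list.append(g01)
        if not pos_list:
            continue
        pos_arr = np.array(pos_list, dtype=np.int64)
        g_nodes = np.array(geno_list, dtype=np.int8)  # (n_sites, 2 * n_ind)
        geno = g_nodes.reshape(len(pos_list), n_ind, 2)
        anc_arr = np.array(anc_list, dtype=object)
        der_arr = np.array(der_list, dtype=object)

        outg = anc_arr.copy()
        if outgroup_error > 0:
            err = rng.random(len(pos_arr)) < outgroup_error
            for i in np.flatnonzero(err):
                outg[i] = _OTHER_BASES[anc_arr[i]][rng.integers(3)]

        if missing_rate > 0:
            miss = rng.random((len(pos_arr), n_ind)) < missing_rate
            geno = geno.copy()
            geno[miss] = -1

        depth = rng.poisson(mean_depth * n_ind, size=len(pos_arr))
        in_rep = iv.contains(repeats.get(chrom, np.empty((0, 2), dtype=np.int64)), pos_arr)
        if in_rep.any():
            depth[in_rep] = rng.poisson(4.0 * mean_depth * n_ind, size=int(in_rep.sum()))

        cats = annotation.categories(chrom, pos_arr)
        third = annotation.third_codon(chrom, pos_arr)
        anc_assigned = np.where((outg == anc_arr) | (outg == der_arr), outg, "N")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos_arr,
                    "ref": anc_arr.astype(str),
                    "alt": der_arr.astype(str),
                    "anc": anc_assigned.astype(str),
                    "category": cats,
                    "third_codon": third,
                }
            )
        )
        geno_chunks.append(geno)
        depth_chunks.append(depth)
        outgroup_chunks.append(outg.astype(str))

    if rows:
        sites_df = pd.concat(rows, ignore_index=True)
        genotypes = np.concatenate(geno_chunks, axis=0)
        depth = np.concatenate(depth_chunks)
        outgroup = np.concatenate(outgroup_chunks)
    else:
        sites_df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                 [("chrom", str), ("pos", np.int64), ("ref", str), ("alt", str),
                                  ("anc", str), ("category", str), ("third_codon", bool)]})
        genotypes = np.empty((0, n_ind, 2), dtype=np.int8)
        depth = np.empty(0, dtype=np.int64)
        outgroup = np.empty(0, dtype=str)

    table = SiteTable(sites_df, genotypes, individuals, popmap)
    truth = {
        "model": model.to_dict(),
        "seed": int(seed),
        "samples_per_pop": {p: int(samples_per_pop[p]) for p in pops_in_order},
        "outgroup_error": float(outgroup_error),
        "sweeps": [],
    }
    return SimulatedDataset(
        layout=layout,
        annotation=annotation,
        repeats=repeats,
        sites=table,
        depth=np.asarray(depth, dtype=np.int64),
        outgroup=np.asarray(outgroup, dtype=object),
        truth=truth,
    )


def spike_sweep(dataset: SimulatedDataset, region, pop: str, shift: float, seed: int = 0) -> SimulatedDataset:
    """Displace derived-allele frequencies toward fixation inside a region.

    Each polarized site in ``region`` has ``round(shift * n_ancestral)`` of
    the population's ancestral alleles flipped to derived, so the frequency
    moves to ``p + shift * (1 - p)`` up to integer rounding (exactly 1 at
    ``shift=1``). The spiked region is recorded in the truth table.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    if chrom not in dataset.layout.names:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (0.0 <= shift <= 1.0):
        raise ValueError("shift must be in [0, 1]")
    idx_pop = dataset.sites.pop_indices(pop)  # raises on unknown pop
    if shift == 0.0:
        return dataset

    table = dataset.sites
    sel = (
        (table.sites["chrom"] == chrom)
        & (table.sites["pos"] >= start)
        & (table.sites["pos"] < end)
    ).to_numpy() & table.polarized
    geno = table.genotypes.copy()
    der_is_alt = table.derived_is_alt
    rng = np.random.default_rng(seed)
    for row in np.flatnonzero(sel):
        anc_code = 0 if der_is_alt[row] else 1
        alleles = geno[row, idx_pop, :].reshape(-1)
        anc_slots = np.flatnonzero(alleles == anc_code)
        k = int(round(shift * anc_slots.size))
        if k:
            flip = rng.choice(anc_slots, size=k, replace=False)
            alleles[flip] = 1 - anc_code
            geno[row, idx_pop, :] = alleles.reshape(-1, 2)

    new_table = SiteTable(table.sites.copy(), geno, table.individuals, table.popmap)
    truth = copy.deepcopy(dataset.truth)
    truth["sweeps"].append(
        {"chrom": chrom, "start": int(start), "end": int(end), "pop": pop, "shift": float(shift)}
    )
    return SimulatedDataset(
        layout=dataset.layout,
        annotation=dataset.annotation,
        repeats=dataset.repeats,
        sites=new_table,
        depth=dataset.depth,
        outgroup=dataset.outgroup,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict:
    """Write VCF/BED/TSV artifacts; see :mod:`ecoscan.io`."""
    from . import io as _io

    return _io.write_dataset(dataset, out_dir)


__all__ = [
    "DemographicModel",
    "SimulatedDataset",
    "PAPER_SAMPLE_SIZES",
    "build_paper_scenario",
    "build_repeats",
    "simulate_cohort",
    "spike_sweep",
    "write_dataset",
    "default_layout",
]
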