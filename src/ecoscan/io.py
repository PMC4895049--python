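"""Readers and writers for the package's on-disk formats.

All internal coordinates are 0-based half-open. On disk: VCF positions are
1-based (as the format requires, with the ancestral allele in the ``AA``
INFO tag), BED intervals are 0-based half-open, and the depth track TSV is
1-based to match the VCF. A written dataset round-trips losslessly through
:func:`read_dataset`.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import _intervals as iv
from .annotate import GenomeAnnotation
from .layout import GenomeLayout
from .sites import SiteTable

# -- small text tables ----------------------------------------------------


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV with optional ``# key=value`` provenance header lines."""
    with open(path, "w") as fh:
        for key in sorted(meta or {}):
            fh.write(f"# {key}={meta[key]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- BED / layout / popmap / depth ----------------------------------------


def write_bed(track: dict, path, layout: GenomeLayout | None = None) -> None:
    order = layout.names if layout is not None else sorted(track)
    with open(path, "w") as fh:
        for chrom in order:
            for start, end in track.get(chrom, []):
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_bed(path) -> dict:
    track: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            track.setdefault(chrom, []).append((int(start), int(end)))
    return {c: iv.normalize(np.array(rows, dtype=np.int64)) for c, rows in track.items()}


def write_layout(layout: GenomeLayout, path) -> None:
    write_table(pd.DataFrame(list(layout), columns=["chrom", "length_bp"]), path)


def read_layout(path) -> GenomeLayout:
    df = read_table(path)
    return GenomeLayout(tuple(zip(df["chrom"], df["length_bp"])))


def write_popmap(popmap: dict, individuals, path) -> None:
    write_table(pd.DataFrame({"individual": individuals, "population": [popmap[i] for i in individuals]}), path)


def read_popmap(path) -> dict:
    df = read_table(path)
    return dict(zip(df["individual"], df["population"]))


def write_depth(sites_df: pd.DataFrame, depth, path) -> None:
    write_table(
        pd.DataFrame({"chrom": sites_df["chrom"], "pos": sites_df["pos"] + 1, "total_depth": depth}),
        path,
    )


def read_depth(path) -> pd.DataFrame:
    """Depth track with positions converted back to 0-based."""
    df = read_table(path)
    df = df.rename(columns={df.columns[0]: "chrom", df.columns[1]: "pos", df.columns[2]: "total_depth"})
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df


# -- VCF -------------------------------------------------------------------

_GT_CODE = {-1: ".", 0: "0", 1: "1"}


def write_vcf(table: SiteTable, outgroup, layout: GenomeLayout, path) -> None:
    """Minimal VCF 4.2 with GT genotypes and the AA ancestral-allele tag."""
    outgroup = np.asarray(outgroup, dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele from outgroup consensus">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in layout:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.individuals) + "\n")
        sites = table.sites
        geno = table.genotypes
        for i in range(table.n_sites):
            row = sites.iloc[i]
            gts = "\t".join(
                f"{_GT_CODE[int(a)]}/{_GT_CODE[int(b)]}" for a, b in geno[i]
            )
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\tAA={outgroup[i]}\tGT\t{gts}\n"
            )


def read_vcf(path, popmap: dict, annotation: GenomeAnnotation | None = None):
    """Read a VCF into a :class:`SiteTable` plus the raw AA track.

    The ancestral state is assigned from AA only where it matches REF or
    ALT (otherwise "N"); categories and third-codon flags are recomputed
    from ``annotation`` when given.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, poss, refs, alts, aas = [], [], [], [], []
    geno_rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        aa = var.INFO.get("AA")
        aas.append(aa if aa else "N")
        g = np.array([row[:2] for row in var.genotypes], dtype=np.int8)
        geno_rows.append(g)
    vcf.close()
    n = len(poss)
    genotypes = (
        np.stack(geno_rows, axis=0) if n else np.empty((0, len(individuals), 2), dtype=np.int8)
    )
    ref_arr = np.array(refs, dtype=object)
    alt_arr = np.array(alts, dtype=object)
    aa_arr = np.array(aas, dtype=object)
    anc = np.where((aa_arr == ref_arr) | (aa_arr == alt_arr), aa_arr, "N")
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(poss, dtype=np.int64),
            "ref": ref_arr.astype(str),
            "alt": alt_arr.astype(str),
            "anc": anc.astype(str),
            "category": "intergenic",
            "third_codon": False,
        }
    )
    if annotation is not None and n:
        cats = np.empty(n, dtype=object)
        third = np.zeros(n, dtype=bool)
        for chrom in df["chrom"].unique():
            mask = (df["chrom"] == chrom).to_numpy()
            pos = df.loc[mask, "pos"].to_numpy()
            cats[mask] = annotation.categories(chrom, pos)
            third[mask] = annotation.third_codon(chrom, pos)
        df["category"] = cats.astype(str)
        df["third_codon"] = third
    table = SiteTable(df, genotypes, individuals, popmap)
    return table, aa_arr


# -- whole dataset ---------------------------------------------------------

DATASET_FILES = {
    "vcf": "cohort.vcf",
    "layout": "layout.tsv",
    "popmap": "popmap.tsv",
    "depth": "depth.tsv",
    "genes": "genes.bed",
    "exons": "exons.bed",
    "introns": "introns.bed",
    "flanks": "flanks.bed",
    "repeats": "repeats.bed",
    "truth": "truth.json",
}


def write_dataset(dataset, out_dir) -> dict:
    """Emit VCF + BED tracks + popmap/depth/layout TSVs + truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in DATASET_FILES.items()}
    write_vcf(dataset.sites, dataset.outgroup, dataset.layout, paths["vcf"])
    write_layout(dataset.layout, paths["layout"])
    write_popmap(dataset.sites.popmap, dataset.sites.individuals, paths["popmap"])
    write_depth(dataset.sites.sites, dataset.depth, paths["depth"])
    ann = dataset.annotation
    write_bed(ann.genes, paths["genes"], dataset.layout)
    write_bed(ann.exons, paths["exons"], dataset.layout)
    write_bed(ann.introns, paths["introns"], dataset.layout)
    write_bed(ann.flanks, paths["flanks"], dataset.layout)
    write_bed(dataset.repeats, paths["repeats"], dataset.layout)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_dataset(in_dir):
    """Inverse of :func:`write_dataset`; returns a SimulatedDataset."""
    from .simdata import SimulatedDataset  # local import to avoid a cycle

    paths = {k: os.path.join(in_dir, v) for k, v in DATASET_FILES.items()}
    layout = read_layout(paths["layout"])
    popmap = read_popmap(paths["popmap"])
    annotation = GenomeAnnotation(
        genes=read_bed(paths["genes"]),
        exons=read_bed(paths["exons"]),
        introns=read_bed(paths["introns"]),
        flanks=read_bed(paths["flanks"]),
    )
    repeats = read_bed(paths["repeats"]) if os.path.exists(paths["repeats"]) else {}
    table, aa = read_vcf(paths["vcf"], popmap, annotation)
    depth_df = read_depth(paths["depth"])
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    return SimulatedDataset(
        layout=layout,
        annotation=annotation,
        repeats=repeats,
        sites=table,
        depth=depth_df["total_depth"].to_numpy(dtype=np.int64),
        outgroup=aa,
        truth=truth,
    )
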