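"""End-to-end orchestration: simulate -> mask/filter -> polarize -> landscape
-> PBS/enrichment -> admixture statistics, from a single flat config.

Every stage is a pure function of (inputs, config, seed); tables are written
with a provenance header carrying the config hash and seed, so a rerun with
the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import polarize as pol
from .admixture import dstat_quartets, f3_test
from .landscape import landscape_correlations, landscape_scan, site_fst_components
from .layout import default_layout
from .selection import category_bin_chisq, fisher_term_enrichment, outlier_call, pbs_scan, top_fst_snps
from .simdata import build_paper_scenario, simulate_cohort, spike_sweep, write_dataset
from .sitefilter import apply_mask, compile_mask, filter_variants_for_structure, mask_report

ALL_PAIRS = [
    ("resident", "transient"), ("resident", "B1"), ("resident", "B2"), ("resident", "C"),
    ("transient", "B1"), ("transient", "B2"), ("transient", "C"),
    ("B1", "B2"), ("B1", "C"), ("B2", "C"),
]


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class RunConfig:
    """One flat bundle of every threshold the analysis constellation uses."""

    scenario: str = "paper"
    scale: float = 0.1
    seed: int = 1
    pulse_fraction: float = 0.1
    sweep: bool = True
    sweep_pop: str = "B1"
    sweep_shift: float = 0.5
    sweep_window_bp: int = 50_000
    depth_threshold: int = 200
    maf_tmrca: float = 0.1
    maf_structure: float = 0.05
    min_individuals_structure: int = 40
    min_individuals_window: int = 5
    min_covered_bp: int = 10_000
    window_bp: int = 50_000
    pbs_window_bp: int = 50_000
    pbs_step_bp: int = 10_000
    pbs_percentile: float = 99.9
    pbs_percentile_short: float = 99.99
    top_fst_fraction: float = 0.01
    block_size_snps: int = 1000
    mu_year: float = 9.10e-10
    mu_hpd: tuple = (6.68e-10, 1.18e-9)
    mu_a: float = 2.34e-8
    alpha: float = 2.0
    comparisons: list = field(default_factory=lambda: list(ALL_PAIRS))
    pbs_trio: tuple = ("B1", "B2", "C")
    quartets: list = field(default_factory=lambda: [("C", "resident", "transient", "ANC")])
    f3_triple: tuple = ("transient", "resident", "C")
    min_correlation_windows: int = 30
    out_dir: str = "ecoscan_run"

    def validate(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for name in ("pbs_percentile", "pbs_percentile_short"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not (0 < self.top_fst_fraction <= 1):
            raise ValueError("top_fst_fraction must be in (0, 1]")
        if not (0 <= self.pulse_fraction < 1):
            raise ValueError("pulse_fraction must be in [0, 1)")
        if not (0 <= self.sweep_shift <= 1):
            raise ValueError("sweep_shift must be in [0, 1]")
        if self.depth_threshold <= 0 or self.block_size_snps <= 0:
            raise ValueError("depth_threshold and block_size_snps must be positive")
        return self

    def to_dict(self, include_out_dir: bool = True) -> dict:
        d = asdict(self)
        d["mu_hpd"] = list(self.mu_hpd)
        d["comparisons"] = [list(c) for c in self.comparisons]
        d["pbs_trio"] = list(self.pbs_trio)
        d["quartets"] = [list(q) for q in self.quartets]
        d["f3_triple"] = list(self.f3_triple)
        if not include_out_dir:
            d.pop("out_dir")
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("mu_hpd", "pbs_trio", "f3_triple"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        cfg.quartets = [tuple(q) for q in cfg.quartets]
        return cfg.validate()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(include_out_dir=False), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig, term_annotation=None) -> dict:
    """Execute all stages in dependency order; returns paths and summaries."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed}
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}

    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(include_out_dir=False), fh, sort_keys=True)

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        model = build_paper_scenario(config.scale, config.seed, pulse_fraction=config.pulse_fraction)
        layout = default_layout(config.scale)
        ds = simulate_cohort(model, layout, seed=config.seed)
        if config.sweep:
            chrom, length = layout.chromosomes[0]
            mid = length // 2
            region = (chrom, mid, min(mid + config.sweep_window_bp, length))
            ds = spike_sweep(ds, region, config.sweep_pop, config.sweep_shift, seed=config.seed + 1)
        return ds

    dataset = stage_simulate()
    write_dataset(dataset, os.path.join(out, "data"))
    summary["n_sites"] = dataset.sites.n_sites

    # -- masking -----------------------------------------------------------
    @_stage("mask")
    def stage_mask():
        depth_df = pd.DataFrame(
            {"chrom": dataset.sites.sites["chrom"], "pos": dataset.sites.sites["pos"],
             "total_depth": dataset.depth}
        )
        mask = compile_mask(dataset.repeats, {}, depth_df, config.depth_threshold, dataset.layout)
        report = mask_report(mask)
        eio.write_table(
            pd.DataFrame(
                {
                    "masked_sites": [report.masked_sites],
                    "masked_percent": [report.masked_fraction],
                    "repeat": [report.per_source["repeat"]],
                    "numt": [report.per_source["numt"]],
                    "high_depth": [report.per_source["high_depth"]],
                }
            ),
            os.path.join(out, "mask_report.tsv"),
            meta,
        )
        return mask, report

    mask, report = stage_mask()
    summary["masked_percent"] = report.masked_fraction
    sites = apply_mask(dataset.sites, mask)
    dataset.sites = sites

    # -- structure filter --------------------------------------------------
    @_stage("filter")
    def stage_filter():
        kept = filter_variants_for_structure(
            sites, config.min_individuals_structure, config.maf_structure
        )
        eio.write_table(
            pd.DataFrame({"stage": ["input", "retained"], "n_sites": [sites.n_sites, kept.n_sites]}),
            os.path.join(out, "structure_filter.tsv"),
            meta,
        )
        return kept

    structure_sites = stage_filter()
    summary["structure_sites"] = structure_sites.n_sites

    # -- polarize / TMRCA --------------------------------------------------
    @_stage("polarize")
    def stage_polarize():
        panel = []
        for pop in dataset.sites.populations:
            members = [i for i in dataset.sites.individuals if dataset.sites.popmap[i] == pop]
            panel.extend(members[: (1 if pop == "B1" else 2)])
        counts = pol.count_derived_by_class(sites, panel, maf_cutoff=config.maf_tmrca)
        res: dict = {
            "panel": panel,
            "third_codon_sites": counts.total_third_codon_sites,
            "complete_third_codon_sites": counts.complete_third_codon_sites,
            "transitions": counts.total_transitions,
            "transversions": counts.total_transversions,
            "within_transitions": counts.within_transitions,
            "within_transversions": counts.within_transversions,
        }
        try:
            res["tstv_within"] = pol.estimate_tstv(counts)
        except ZeroDivisionError:
            res["tstv_within"] = None
        focal, other = f"{config.sweep_pop}_0", "resident_0"
        try:
            n_focal, n_shared = pol.derived_sharing(
                sites, focal, other, "combined", config.maf_tmrca, panel=[focal, other]
            )
            private = n_focal - n_shared
            gen_time = dataset.truth["model"]["generation_time_years"]
            # L counts every screened third-codon position (invariant included):
            # the cohort is fully genotyped, so that is the whole exon track / 3
            L = dataset.annotation.third_codon_total()
            est = pol.estimate_tmrca(
                private, "combined", L or 1,
                config.mu_year, config.mu_hpd, tstv=res["tstv_within"] or 1.0,
            )
            res.update(
                {
                    "tmrca_focal": focal, "tmrca_other": other,
                    "derived_private": private, "tmrca_years": est.years,
                    "tmrca_interval_years": list(est.interval_years),
                    "tmrca_generations": est.years / gen_time,
                }
            )
        except (KeyError, ZeroDivisionError, ValueError):
            res["tmrca_years"] = None
        with open(os.path.join(out, "polarize.json"), "w") as fh:
            json.dump({**meta, **res}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return res

    summary["polarize"] = stage_polarize()

    # -- landscape ---------------------------------------------------------
    @_stage("landscape")
    def stage_landscape():
        tables = landscape_scan(
            dataset, config.comparisons, config.window_bp,
            min_covered_bp=config.min_covered_bp, min_individuals=config.min_individuals_window,
        )
        for (a, b), tab in tables.items():
            eio.write_table(tab, os.path.join(out, f"landscape_{a}_vs_{b}.tsv"), meta)
        n_windows = min((len(t) for t in tables.values()), default=0)
        if n_windows >= config.min_correlation_windows:
            corr = landscape_correlations(tables, statistics=("fst",), min_windows=config.min_correlation_windows)
            eio.write_table(
                corr.to_frame().reset_index(names="label"),
                os.path.join(out, "landscape_correlations.tsv"), meta,
            )
        return tables

    tables = stage_landscape()
    summary["mean_fst"] = {
        f"{a}-{b}": float(np.nansum(t["fst_num"]) / np.nansum(t["fst_den"]))
        for (a, b), t in tables.items() if len(t)
    }

    # -- selection ---------------------------------------------------------
    @_stage("selection")
    def stage_selection():
        records = pbs_scan(
            dataset, config.pbs_trio, config.pbs_window_bp, config.pbs_step_bp,
            min_covered_bp=config.min_covered_bp, min_individuals=config.min_individuals_window,
        )
        eio.write_table(records, os.path.join(out, "pbs_windows.tsv"), meta)
        focal = config.pbs_trio[0]
        outliers, threshold = outlier_call(records, config.pbs_percentile, f"pbs_{focal}")
        eio.write_table(outliers, os.path.join(out, "pbs_outliers.tsv"), {**meta, "threshold": f"{threshold:.6g}"})

        a, b = config.comparisons[0]
        p1, n1 = dataset.sites.alt_freq(a), dataset.sites.alt_counts(a)[1]
        p2, n2 = dataset.sites.alt_freq(b), dataset.sites.alt_counts(b)[1]
        ok = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2) & ((p1 > 0) | (p2 > 0)) & ((p1 < 1) | (p2 < 1))
        num, den = site_fst_components(p1[ok], n1[ok], p2[ok], n2[ok])
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        snp_table = dataset.sites.sites.loc[ok, ["chrom", "pos", "category"]].copy()
        snp_table["fst"] = np.clip(fst, 0.0, 1.0)
        snp_table = snp_table.dropna(subset=["fst"])
        top = top_fst_snps(snp_table, config.top_fst_fraction)
        enrich = category_bin_chisq(top, background=snp_table)
        eio.write_table(
            enrich.residuals.reset_index(names="category"),
            os.path.join(out, "top_fst_category_residuals.tsv"), meta,
        )
        res = {"n_pbs_windows": len(records), "pbs_threshold": threshold, "n_outliers": len(outliers),
               "n_top_fst_snps": len(top)}
        if term_annotation is not None:
            genes = sorted(set(top.get("gene", pd.Series(dtype=str)).dropna()))
            background_genes = sorted(set(snp_table.get("gene", pd.Series(dtype=str)).dropna()))
            if genes and background_genes:
                fisher = fisher_term_enrichment(genes, term_annotation, background_genes)
                eio.write_table(fisher, os.path.join(out, "term_enrichment.tsv"), meta)
                res["n_terms_tested"] = len(fisher)
        return res

    summary["selection"] = stage_selection()

    # -- admixture ---------------------------------------------------------
    @_stage("admixture")
    def stage_admixture():
        dtab = dstat_quartets(dataset, config.quartets, config.block_size_snps)
        eio.write_table(dtab, os.path.join(out, "dstat.tsv"), meta)
        t, sa, sb = config.f3_triple
        f3res = f3_test(dataset, t, sa, sb, config.block_size_snps)
        eio.write_table(
            pd.DataFrame(
                [{"target": t, "source_a": sa, "source_b": sb, "f3": f3res.f3,
                  "se": f3res.se, "z": f3res.z, "n_blocks": f3res.n_blocks, "n_sites": f3res.n_sites}]
            ),
            os.path.join(out, "f3.tsv"), meta,
        )
        return {"d": dtab.to_dict("records"), "f3_z": f3res.z}

    summary["admixture"] = stage_admixture()

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary
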