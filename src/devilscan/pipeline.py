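"""End-to-end orchestration of the temporal selection scan.

Stage order mirrors the analysis the package implements: dataset-wide
filters -> per-population stratum call-rate filters -> LD pruning ->
allele-frequency-change scan -> cross-population candidate regions ->
haplotype Rsb -> window composite statistic -> annotation randomization ->
temporal Ne and per-SNP selection-coefficient estimates.  Every threshold
lives in :class:`RunConfig`; a run writes per-stage tables, a JSON manifest
of thresholds and SNP counts, and a human-readable summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    GenotypeTable,
    Interval,
    extract_haplotypes,
    read_genes,
    read_genotypes,
    write_intervals,
)
from . import afchange, annotest, composite, filters, haplostats, temporal

ALL_STAGES = ("afchange", "rsb", "composite", "annotest", "temporal")


@dataclass
class PopulationConfig:
    name: str
    pre_years: list
    post_years: list
    ne: int
    min_call_pre: float = 1 / 3
    min_call_post: float = 1 / 3


@dataclass
class RunConfig:
    populations: list  # of PopulationConfig
    vcf: str | None = None
    metadata: str | None = None
    scaffold_table: str | None = None
    genes: str | None = None
    outdir: str | None = None
    x_scaffolds: list = field(default_factory=list)
    het_max: float = 0.5
    call_rate_min: float = 1 / 3
    maf_min: float = 0.01
    prune_max_snp_dist: int = 20
    prune_max_bp: int = 50_000
    prune_r2_max: float = 0.99
    top_fraction: float = 0.025
    flank: int = 100_000
    window: int = 100_000
    rsb_maf_min: float = 0.05
    min_scaffold_snps: int = 10
    hap_min_rate: float = 0.30
    target_terms: list = field(default_factory=lambda: list(annotest_default_terms()))
    n_draws: int = 1000
    generation_time: float = 2.0
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    def __post_init__(self):
        self.populations = [
            p if isinstance(p, PopulationConfig) else PopulationConfig(**p)
            for p in self.populations
        ]
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def annotest_default_terms():
    from .simulate import TARGET_GO_TERMS

    return TARGET_GO_TERMS


def analyze(g: GenotypeTable, genes, cfg: RunConfig) -> dict:
    """Run the configured stages on an in-memory dataset; returns a result bundle."""
    results: dict = {"filter_reports": [], "counts": {}}
    g0, reports = filters.apply_standard_filters(
        g,
        x_scaffolds=cfg.x_scaffolds,
        het_max=cfg.het_max,
        call_rate_min=cfg.call_rate_min,
        maf_min=cfg.maf_min,
    )
    results["filter_reports"] = [r.to_dict() for r in reports]
    results["counts"]["post_filter"] = g0.n_snps
    results["filtered"] = g0

    scan_tables, window_lists, pruned_tables = {}, {}, {}
    for pc in cfg.populations:
        sub = g0
        pre_mask = sub.sample_mask(population=pc.name, years=pc.pre_years)
        post_mask = sub.sample_mask(population=pc.name, years=pc.post_years)
        sub, rep_pre = filters.filter_call_rate(sub, pc.min_call_pre, pre_mask)
        post_mask = sub.sample_mask(population=pc.name, years=pc.post_years)
        sub, rep_post = filters.filter_call_rate(sub, pc.min_call_post, post_mask)
        results["filter_reports"] += [
            {**rep_pre.to_dict(), "population": pc.name, "stratum": "pre"},
            {**rep_post.to_dict(), "population": pc.name, "stratum": "post"},
        ]
        pruned, removed = afchange.ld_prune(
            sub,
            max_snp_dist=cfg.prune_max_snp_dist,
            max_bp=cfg.prune_max_bp,
            r2_max=cfg.prune_r2_max,
        )
        results["counts"][f"pruned_{pc.name}"] = pruned.n_snps
        pruned_tables[pc.name] = pruned
        table, windows = afchange.scan_population(
            pruned,
            pc.name,
            pc.pre_years,
            pc.post_years,
            top_fraction=cfg.top_fraction,
            flank=cfg.flank,
        )
        scan_tables[pc.name] = table
        window_lists[pc.name] = windows
    results["scan_tables"] = scan_tables
    results["windows"] = window_lists

    regions = afchange.intersect_populations(window_lists, scan_tables, flank=cfg.flank)
    afchange.attach_genes(regions, genes or [])
    results["regions"] = regions

    rsb_tables = {}
    if "rsb" in cfg.stages:
        for pc in cfg.populations:
            per_scaf = []
            base = results["filtered"]
            # mirror the pre-phasing filters: SNPs called in >= 1/3 of the
            # population, scaffolds with enough SNPs
            pop_mask = base.sample_mask(population=pc.name)
            pop_g, _ = filters.filter_call_rate(base, cfg.call_rate_min, pop_mask)
            for scaf in pop_g.snps["scaffold"].unique():
                if (pop_g.snps["scaffold"] == scaf).sum() < cfg.min_scaffold_snps:
                    continue
                pre = extract_haplotypes(
                    pop_g, pc.name, pc.pre_years, scaf, "pre", cfg.hap_min_rate
                )
                post = extract_haplotypes(
                    pop_g, pc.name, pc.post_years, scaf, "post", cfg.hap_min_rate
                )
                if pre.n_haplotypes < 4 or post.n_haplotypes < 4:
                    continue
                t = haplostats.rsb_table(pre, post, maf_min=cfg.rsb_maf_min)
                if len(t):
                    per_scaf.append(t)
            rsb_tables[pc.name] = haplostats.standardize_rsb(
                pd.concat(per_scaf, ignore_index=True)
            ) if per_scaf else pd.DataFrame(
                columns=["snp_id", "scaffold", "pos", "ies_pre", "ies_post", "rsb_raw", "rsb_std"]
            )
        results["rsb_tables"] = rsb_tables

    if "composite" in cfg.stages and g.scaffolds is not None:
        quantile_tables = {}
        for pc in cfg.populations:
            t = scan_tables[pc.name]
            quantile_tables[f"{pc.name}:afchange"] = t[["scaffold", "pos", "quantile"]]
            if "rsb" in cfg.stages and len(rsb_tables.get(pc.name, ())):
                rt = rsb_tables[pc.name].copy()
                # sweep-after-epidemic evidence sits in the lower rsb tail
                # (iES_post inflated); rank so that high quantile = evidence
                rt["quantile"] = afchange.empirical_quantiles(-rt["rsb_std"].to_numpy())
                quantile_tables[f"{pc.name}:rsb"] = rt[["scaffold", "pos", "quantile"]]
        window_stats = composite.composite_scan(
            quantile_tables, g.scaffolds, window=cfg.window
        )
        results["window_stats"] = window_stats
        results["region_combined_p"] = [
            composite.region_combined_p(window_stats, r.interval) for r in regions
        ]

    if "annotest" in cfg.stages and genes:
        all_snps = pd.concat(
            [t[["scaffold", "pos"]] for t in scan_tables.values()], ignore_index=True
        ).drop_duplicates()
        lengths = (
            dict(zip(g.scaffolds["scaffold"], g.scaffolds["length"]))
            if g.scaffolds is not None
            else None
        )
        results["annotest"] = annotest.randomization_test(
            all_snps,
            genes,
            cfg.target_terms,
            scaffold_lengths=lengths,
            n_draws=cfg.n_draws,
            width=2 * cfg.flank,
            seed=cfg.seed,
            observed_regions=[r.interval for r in regions] or None,
        )

    if "temporal" in cfg.stages:
        ne_estimates, fits, region_s = {}, {}, []
        for pc in cfg.populations:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ne_estimates[pc.name] = temporal.jorde_ryman_ne(
                    results["filtered"],
                    pc.name,
                    pc.pre_years,
                    pc.post_years,
                    generation_time=cfg.generation_time,
                )
            pop_fits = []
            if regions:
                pruned = pruned_tables[pc.name]
                in_region = np.zeros(pruned.n_snps, dtype=bool)
                for r in regions:
                    in_region |= (
                        (pruned.snps["scaffold"] == r.interval.scaffold)
                        & (pruned.snps["pos"] >= r.interval.start)
                        & (pruned.snps["pos"] < r.interval.end)
                    ).to_numpy()
                region_g = pruned.subset_snps(in_region)
                if region_g.n_snps:
                    trajs = temporal.trajectories_from_genotypes(
                        region_g,
                        pc.name,
                        years=list(pc.pre_years) + list(pc.post_years),
                        generation_time=cfg.generation_time,
                        increasing_allele=True,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pop_fits = [temporal.estimate_s(t, pc.ne) for t in trajs]
            fits[pc.name] = pop_fits
            snp_pos = {
                row.snp_id: (row.scaffold, row.pos)
                for row in pruned_tables[pc.name].snps.itertuples(index=False)
            }
            for r in regions:
                region_s.append(
                    {
                        "population": pc.name,
                        "scaffold": r.interval.scaffold,
                        "start": r.interval.start,
                        "end": r.interval.end,
                        **temporal.region_mean_s(pop_fits, snp_pos, r.interval),
                    }
                )
        results["ne_estimates"] = ne_estimates
        results["selection_fits"] = fits
        results["region_mean_s"] = pd.DataFrame(region_s)

    return results


def run_pipeline(cfg: RunConfig, data=None, genes=None) -> dict:
    """File-based entry point: read inputs, analyze, write outputs and manifest."""
    if data is None:
        if not (cfg.vcf and cfg.metadata):
            raise ValueError("RunConfig needs vcf and metadata paths (or pass data=)")
        data = read_genotypes(cfg.vcf, cfg.metadata, cfg.scaffold_table)
        genes = read_genes(cfg.genes) if cfg.genes else []
    results = analyze(data, genes or [], cfg)

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for pop, t in results["scan_tables"].items():
            t.to_csv(out / f"scan_{pop}.tsv", sep="\t", index=False)
        write_intervals(
            [r.interval for r in results["regions"]], out / "candidate_regions.bed"
        )
        if "window_stats" in results:
            results["window_stats"].drop(columns=["window_id"]).to_csv(
                out / "window_composite.tsv", sep="\t", index=False
            )
        if "rsb_tables" in results:
            for pop, t in results["rsb_tables"].items():
                t.to_csv(out / f"rsb_{pop}.tsv", sep="\t", index=False)
        if "region_mean_s" in results:
            results["region_mean_s"].to_csv(out / "region_mean_s.tsv", sep="\t", index=False)
        manifest = build_manifest(cfg, results)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(summarize(results))
    return results


def build_manifest(cfg: RunConfig, results: dict) -> dict:
    return {
        "devilscan_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "filter_reports": results["filter_reports"],
        "counts": results["counts"],
        "n_candidate_regions": len(results["regions"]),
    }


def summarize(results: dict) -> str:
    lines = ["candidate regions:"]
    pvals = results.get("region_combined_p")
    for i, r in enumerate(results["regions"]):
        p = f", combined P = {pvals[i]:.4g}" if pvals is not None else ""
        genes = ",".join(gr.gene_id for gr in r.genes) or "-"
        lines.append(
            f"  {r.interval.scaffold}:{r.interval.start}-{r.interval.end}"
            f" (genes: {genes}{p})"
        )
    if not results["regions"]:
        lines.append("  none")
    for pop, est in results.get("ne_estimates", {}).items():
        lines.append(
            f"Ne[{pop}] = {est.ne_hat:.1f} (95% CI {est.ci_low:.1f}-{est.ci_high:.1f}, "
            f"{est.n_loci} loci)"
        )
    if "region_mean_s" in results and len(results["region_mean_s"]):
        for row in results["region_mean_s"].itertuples(index=False):
            if row.n_snps:
                lines.append(
                    f"mean s[{row.population}] in {row.scaffold}:{row.start}-{row.end} = "
                    f"{row.mean_s:.2f} (range {row.min_s:.2f}-{row.max_s:.2f}, n={row.n_snps})"
                )
    ann = results.get("annotest")
    if ann is not None:
        lines.append(
            f"annotation randomization: fraction_hit = {ann.fraction_hit:.3f}, "
            f"empirical P = {ann.empirical_p}"
        )
    return "\n".join(lines) + "\n"


def study_run_config(sim_cfg=None, **overrides) -> RunConfig:
    """RunConfig matching the generator's default three-population design."""
    from .simulate import SimConfig

    sim_cfg = sim_cfg or SimConfig()
    pops = []
    for i, name in enumerate(sim_cfg.populations):
        pops.append(
            PopulationConfig(
                name=name,
                pre_years=[sim_cfg.pre_years[i]],
                post_years=[sim_cfg.post_year(i)],
                ne=sim_cfg.ne[i],
            )
        )
    return RunConfig(populations=pops, **overrides)
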