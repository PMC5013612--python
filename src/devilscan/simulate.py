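"""Forward Wright-Fisher simulator for replicated pre/post-epidemic SNP data.

The generator emulates the data structure of a temporal selection scan in a
bottlenecked host species hit by an epidemic: three small populations
(Ne 34/37/26) drawing on shared standing variation, sparse markers (mean
spacing 33 kb), one selected standing variant (p0 ~ 0.2) shared across
populations, linked neutral markers under recombination, pre- and
post-epidemic samples of distinct individuals, and heavy per-genotype
missingness (call rates ~55-70%).

Standing variation is built from a small founder-haplotype set: within
segments of a few hundred kb, site alleles are nested subsets of a common
founder permutation (a caterpillar genealogy) with subset sizes drawn from
the neutral 1/i frequency spectrum.  This reproduces the strong
bottleneck-driven LD — persisting well above background to ~100 kb — that
makes flank-based windowing around outlier SNPs meaningful.  A shared
ancestral pool is then burnt in under neutral drift and recombination
before the populations split.  No new mutations arise during the epidemic
phase: selection acts on standing variation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenotypeTable,
    GeneRecord,
    Interval,
    MISSING,
    write_genes,
    write_genotypes,
    write_metadata,
    write_scaffold_table,
)

TARGET_GO_TERMS = ("immune response", "cell proliferation", "cell death")


@dataclass
class SimConfig:
    populations: tuple = ("Freycinet", "Narawntapu", "WestPencilPine")
    ne: tuple = (34, 37, 26)
    # epidemic duration per population, generations (2 y/generation)
    epidemic_generations: tuple = (6, 4, 4)
    pre_years: tuple = (1999, 2001, 2005)
    n_sampled: int = 25  # diploid individuals per time point
    missing_rate: tuple = (0.31, 0.44, 0.36)  # per-genotype, per population
    sel_coeff: float | tuple = 0.5
    p0_selected: float = 0.2
    p0_window: tuple = (0.15, 0.25)  # accepted pool frequency after burn-in
    selected_scaffold_index: int = 0
    selected_pos_fraction: float = 0.5
    n_scaffolds: int = 12
    scaffold_length: int = 5_000_000
    snp_spacing: float = 33_000.0
    founder_haplotypes: int = 16
    founder_segment_bp: int = 300_000
    ancestral_pool_size: int = 100  # diploid individuals
    burnin_generations: int = 30
    recomb_rate: float = 1e-8  # per bp per generation
    generation_time: float = 2.0
    # annotation model
    gene_spacing: float = 150_000.0
    gene_length: int = 20_000
    target_term_fraction: float = 0.1
    target_terms: tuple = TARGET_GO_TERMS
    gene_in_selected_region: bool = True
    phased: bool = True
    seed: int = 0

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def sel_coeff_of(self, i: int) -> float:
        if np.isscalar(self.sel_coeff):
            return float(self.sel_coeff)
        return float(self.sel_coeff[i])

    def post_year(self, i: int) -> int:
        return int(
            self.pre_years[i] + self.generation_time * self.epidemic_generations[i]
        )

    def validate(self):
        if not (
            len(self.ne)
            == len(self.epidemic_generations)
            == len(self.pre_years)
            == len(self.missing_rate)
            == self.n_populations
        ):
            raise ValueError("per-population config fields have mismatched lengths")
        if any(n <= 0 for n in self.ne) or self.n_sampled <= 0:
            raise ValueError("sizes must be positive")
        if any(self.n_sampled > ne for ne in self.ne):
            raise ValueError(
                "cannot sample more distinct individuals than the population holds"
            )


@dataclass
class SimTruth:
    selected_snp_id: str
    selected_interval: Interval
    sel_coeff: dict  # population -> s
    ne: dict
    p0_pool: float
    trajectories: dict  # population -> list of per-generation selected-site freqs
    freq_record: dict  # population -> (G+1, L) per-generation frequencies, all sites

    def to_json_dict(self) -> dict:
        return {
            "selected_snp_id": self.selected_snp_id,
            "selected_interval": {
                "scaffold": self.selected_interval.scaffold,
                "start": self.selected_interval.start,
                "end": self.selected_interval.end,
            },
            "sel_coeff": self.sel_coeff,
            "ne": self.ne,
            "p0_pool": self.p0_pool,
            "trajectories": {p: list(map(float, t)) for p, t in self.trajectories.items()},
        }


@dataclass
class SimResult:
    genotypes: GenotypeTable
    genes: list
    truth: SimTruth
    config: SimConfig

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "metadata": outdir / "samples.tsv",
            "scaffolds": outdir / "scaffolds.tsv",
            "genes": outdir / "genes.bed",
            "truth": outdir / "truth.json",
        }
        write_genotypes(self.genotypes, paths["vcf"])
        write_metadata(self.genotypes.samples, paths["metadata"])
        write_scaffold_table(self.genotypes.scaffolds, paths["scaffolds"])
        write_genes(self.genes, paths["genes"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1)
        return {k: str(v) for k, v in paths.items()}


def expected_trajectory(p0: float, sel_coeff: float, generations: int) -> np.ndarray:
    """Deterministic genic-selection recursion p' = p(1+s)/(1+ps), no drift."""
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must be in [0, 1]")
    out = np.empty(generations + 1)
    out[0] = p0
    for g in range(generations):
        p = out[g]
        out[g + 1] = p * (1 + sel_coeff) / (1 + p * sel_coeff)
    return out


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _snp_positions(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-process SNP positions; returns (scaffold_index, pos) arrays."""
    scaf_idx, pos = [], []
    for k in range(cfg.n_scaffolds):
        x = 0.0
        cur = []
        while True:
            x += rng.exponential(cfg.snp_spacing)
            if x >= cfg.scaffold_length:
                break
            cur.append(int(x))
        cur = sorted(set(cur))
        if len(cur) < 2:  # degenerate draw; force two markers
            cur = [cfg.scaffold_length // 3, 2 * cfg.scaffold_length // 3]
        scaf_idx.extend([k] * len(cur))
        pos.extend(cur)
    return np.array(scaf_idx), np.array(pos)


def _founder_alleles(cfg: SimConfig, scaf_idx, pos, sel_j, rng) -> np.ndarray:
    """Founder haplotype matrix (K, L) with nested within-segment structure."""
    K, L = cfg.founder_haplotypes, len(pos)
    founders = np.zeros((K, L), dtype=np.int8)
    # neutral SFS over subset sizes 1..K-1, weight 1/i
    sizes = np.arange(1, K)
    sfs = (1.0 / sizes) / (1.0 / sizes).sum()
    seg_key = np.stack([scaf_idx, pos // cfg.founder_segment_bp], axis=1)
    _, seg_id = np.unique(seg_key, axis=0, return_inverse=True)
    perms = {s: rng.permutation(K) for s in np.unique(seg_id)}
    m = rng.choice(sizes, size=L, p=sfs)
    m[sel_j] = max(1, round(cfg.p0_selected * K))
    for j in range(L):
        founders[perms[seg_id[j]][: m[j]], j] = 1
    return founders


def _gap_crossover_probs(cfg: SimConfig, scaf_idx, pos) -> np.ndarray:
    gaps = np.diff(pos).astype(float)
    prob = np.minimum(0.5, cfg.recomb_rate * gaps)
    prob[np.diff(scaf_idx) != 0] = 0.5  # free recombination between scaffolds
    return prob


def _reproduce(H: np.ndarray, fitness: np.ndarray, gap_prob, rng) -> np.ndarray:
    """One discrete WF generation: fitness-weighted parents, crossover gametes.

    H has shape (N, 2, L); returns an array of the same shape.
    """
    N, _, L = H.shape
    w = fitness / fitness.sum()
    parents = rng.choice(N, size=2 * N, p=w)
    chooser = np.empty((2 * N, L), dtype=np.int8)
    chooser[:, 0] = rng.integers(0, 2, size=2 * N)
    if L > 1:
        cross = rng.random((2 * N, L - 1)) < gap_prob
        parity = (np.cumsum(cross, axis=1, dtype=np.int32) % 2).astype(np.int8)
        chooser[:, 1:] = chooser[:, [0]] ^ parity
    gametes = H[parents[:, None], chooser, np.arange(L)[None, :]]
    return gametes.reshape(N, 2, L)


def simulate(cfg: SimConfig | None = None, max_burnin_tries: int = 200) -> SimResult:
    """Run the full generator; deterministic given (config, seed)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    scaf_idx, pos = _snp_positions(cfg, rng)
    L = len(pos)
    scaffold_names = [f"scf{k:02d}" for k in range(cfg.n_scaffolds)]
    # selected site: SNP nearest the requested point of its scaffold
    on_sel = np.flatnonzero(scaf_idx == cfg.selected_scaffold_index)
    target = cfg.selected_pos_fraction * cfg.scaffold_length
    sel_j = int(on_sel[np.argmin(np.abs(pos[on_sel] - target))])

    gap_prob = _gap_crossover_probs(cfg, scaf_idx, pos)
    ones = np.ones(cfg.ancestral_pool_size)

    # burn-in with rejection until the selected variant survives near p0
    pool = None
    for _ in range(max_burnin_tries):
        founders = _founder_alleles(cfg, scaf_idx, pos, sel_j, rng)
        draw = rng.integers(0, cfg.founder_haplotypes, size=(cfg.ancestral_pool_size, 2))
        cand = founders[draw]  # (N, 2, L)
        for _ in range(cfg.burnin_generations):
            cand = _reproduce(cand, ones, gap_prob, rng)
        f_sel = cand[:, :, sel_j].mean()
        if cfg.p0_window[0] <= f_sel <= cfg.p0_window[1]:
            pool = cand
            break
    if pool is None:
        raise RuntimeError(
            "burn-in failed to retain the selected variant near its target frequency"
        )
    p0_pool = float(pool[:, :, sel_j].mean())

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{scaffold_names[s]}_{p}" for s, p in zip(scaf_idx, pos)],
            "scaffold": [scaffold_names[s] for s in scaf_idx],
            "chromosome": [f"chr{1 + 3 * s // cfg.n_scaffolds}" for s in scaf_idx],
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "locus_id": [f"loc{j}" for j in range(L)],
        }
    )
    scaffolds = pd.DataFrame(
        {
            "scaffold": scaffold_names,
            "chromosome": [f"chr{1 + 3 * k // cfg.n_scaffolds}" for k in range(cfg.n_scaffolds)],
            "rank": np.arange(cfg.n_scaffolds),
            "length": cfg.scaffold_length,
        }
    )

    sample_rows = []
    a1_blocks, a2_blocks = [], []
    trajectories, freq_record, sel_map, ne_map = {}, {}, {}, {}

    for i, pop_name in enumerate(cfg.populations):
        ne = cfg.ne[i]
        s = cfg.sel_coeff_of(i)
        G = cfg.epidemic_generations[i]
        idx = rng.choice(cfg.ancestral_pool_size, size=ne, replace=False)
        H = pool[idx].copy()  # (ne, 2, L)

        traj = [float(H[:, :, sel_j].mean())]
        record = [H.reshape(2 * ne, L).mean(axis=0)]
        samples = []  # (time-point index, year, genotype array (n, 2, L))

        def draw_sample(year):
            take = rng.choice(ne, size=cfg.n_sampled, replace=False)
            samples.append((len(samples), year, H[take].copy()))

        draw_sample(cfg.pre_years[i])
        for _ in range(G):
            dosage = H[:, :, sel_j].sum(axis=1)
            fitness = (1.0 + s) ** dosage
            H = _reproduce(H, fitness, gap_prob, rng)
            traj.append(float(H[:, :, sel_j].mean()))
            record.append(H.reshape(2 * ne, L).mean(axis=0))
        draw_sample(cfg.post_year(i))

        trajectories[pop_name] = traj
        freq_record[pop_name] = np.stack(record)
        sel_map[pop_name] = s
        ne_map[pop_name] = ne

        for tp, year, geno in samples:
            n = geno.shape[0]
            a1 = geno[:, 0, :].astype(np.int8)
            a2 = geno[:, 1, :].astype(np.int8)
            miss = rng.random((n, L)) < cfg.missing_rate[i]
            a1[miss] = MISSING
            a2[miss] = MISSING
            a1_blocks.append(a1)
            a2_blocks.append(a2)
            sample_rows += [
                {
                    "sample_id": f"{pop_name}_t{tp}_{year}_{k:03d}",
                    "population": pop_name,
                    "year": year,
                }
                for k in range(n)
            ]

    samples_df = pd.DataFrame(sample_rows)
    a1 = np.vstack(a1_blocks)
    a2 = np.vstack(a2_blocks)
    phased = np.full(a1.shape, bool(cfg.phased))
    genotypes = GenotypeTable(
        samples=samples_df, snps=snps, a1=a1, a2=a2, phased=phased, scaffolds=scaffolds
    )

    genes = _make_annotation(cfg, scaffold_names, pos[sel_j], rng)
    truth = SimTruth(
        selected_snp_id=snps["snp_id"].iloc[sel_j],
        selected_interval=Interval(scaffold_names[scaf_idx[sel_j]], int(pos[sel_j]), int(pos[sel_j]) + 1),
        sel_coeff=sel_map,
        ne=ne_map,
        p0_pool=p0_pool,
        trajectories=trajectories,
        freq_record=freq_record,
    )
    return SimResult(genotypes=genotypes, genes=genes, truth=truth, config=cfg)


def _make_annotation(cfg: SimConfig, scaffold_names, sel_pos, rng) -> list[GeneRecord]:
    """Poisson gene placement with sparse target-term labelling."""
    genes = []
    gid = 0
    for k, scaf in enumerate(scaffold_names):
        x = rng.exponential(cfg.gene_spacing)
        while x + cfg.gene_length < cfg.scaffold_length:
            if rng.random() < cfg.target_term_fraction:
                terms = frozenset({rng.choice(cfg.target_terms)})
            else:
                terms = frozenset({"housekeeping"})
            genes.append(
                GeneRecord(
                    Interval(scaf, int(x), int(x) + cfg.gene_length),
                    gene_id=f"gene{gid:04d}",
                    go_terms=terms,
                )
            )
            gid += 1
            x += cfg.gene_length + rng.exponential(cfg.gene_spacing)
    if cfg.gene_in_selected_region:
        scaf = scaffold_names[cfg.selected_scaffold_index]
        start = max(0, int(sel_pos) - cfg.gene_length // 2)
        genes.append(
            GeneRecord(
                Interval(scaf, start, start + cfg.gene_length),
                gene_id="gene_sel",
                go_terms=frozenset({"immune response", "cell death"}),
            )
        )
    return genes
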