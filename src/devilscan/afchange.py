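"""Temporal allele-frequency-change scan.

The scan ranks SNPs within each population by the absolute change in alt
allele frequency between a pre-epidemic and a post-epidemic time stratum,
draws a fixed flank (default 100 kb either side) around the top-ranked SNPs,
merges the resulting windows, and intersects the merged windows across
populations to obtain candidate regions supported by every population.

Also here: genotypic (unphased, dosage-correlation) r^2, the left-to-right
LD pruner applied before ranking, a sliding-window mean |dfreq| variant of
the scan, and the LD-decay curve used to justify the flank size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GenotypeTable, GeneRecord, Interval, intersect_intervals, merge_intervals


def allele_frequencies(g: GenotypeTable, sample_mask=None) -> np.ndarray:
    """Per-SNP alt-allele frequency over called genotypes (NaN where none called)."""
    calls = g.calls if sample_mask is None else g.calls[np.asarray(sample_mask, bool)]
    if calls.shape[0] == 0:
        raise ValueError("empty sample subset")
    called = (calls >= 0).sum(axis=0)
    alt = np.where(calls >= 0, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, alt / (2.0 * called), np.nan)


def _dosage_float(g: GenotypeTable) -> np.ndarray:
    d = g.calls.astype(float)
    d[d < 0] = np.nan
    return d


def ld_r2_genotypic(a, b) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly called samples.

    This is the standard genotype-correlation LD measure for unphased data
    (as computed by plink's ``--r2``).  Returns NaN when fewer than two
    samples are jointly called or either vector is monomorphic among them.
    """
    a = np.asarray(a, dtype=float).copy()
    b = np.asarray(b, dtype=float).copy()
    a[a < 0] = np.nan
    b[b < 0] = np.nan
    # same arithmetic path as the vectorised pruner, so that a threshold
    # derived from this function compares bit-identically during pruning
    D = np.stack([a, b], axis=1)
    return float(_r2_one_vs_many(D, 0, np.array([1]))[0])


def _r2_one_vs_many(D: np.ndarray, j: int, idx: np.ndarray) -> np.ndarray:
    """Vectorised nan-aware r^2 of column j against columns idx (NaN = missing)."""
    a = D[:, j]
    B = D[:, idx]
    m = ~np.isnan(a)[:, None] & ~np.isnan(B)
    am = np.where(m, a[:, None], 0.0)
    bm = np.where(m, B, 0.0)
    n = m.sum(axis=0).astype(float)
    sx = am.sum(axis=0)
    sy = bm.sum(axis=0)
    sxx = (am * am).sum(axis=0)
    syy = (bm * bm).sum(axis=0)
    sxy = (am * bm).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r2 = np.where((n >= 2) & (den > 0), num * num / den, np.nan)
    return r2


def ld_prune(
    g: GenotypeTable,
    max_snp_dist: int = 20,
    max_bp: int = 50_000,
    r2_max: float = 0.99,
) -> tuple[GenotypeTable, list[str]]:
    """Remove near-duplicate SNPs in a single left-to-right pass.

    For each SNP (scaffold order, ascending position) the already-retained
    SNPs within ``max_snp_dist`` positions of the scaffold's SNP list *and*
    within ``max_bp`` are checked; if any has r^2 > ``r2_max`` with it, the
    right-hand SNP is removed (the leftmost of a violating pair survives).
    """
    order = np.lexsort((g.snps["pos"].to_numpy(), g.snps["scaffold"].to_numpy()))
    g = g.subset_snps(order)
    D = _dosage_float(g)
    pos = g.snps["pos"].to_numpy()
    scaf = g.snps["scaffold"].to_numpy()
    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        lo = max(0, j - max_snp_dist)
        cand = np.arange(lo, j)
        cand = cand[keep[cand] & (scaf[cand] == scaf[j]) & (pos[j] - pos[cand] <= max_bp)]
        if cand.size == 0:
            continue
        r2 = _r2_one_vs_many(D, j, cand)
        if np.any(np.nan_to_num(r2, nan=0.0) > r2_max):
            keep[j] = False
    removed = g.snps["snp_id"].to_numpy()[~keep].tolist()
    return g.subset_snps(keep), removed


def empirical_quantiles(values: np.ndarray) -> np.ndarray:
    """Mid-rank empirical quantiles rank/(N+1), ties averaged; strictly in (0,1)."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n:
        out[ok] = rankdata(v[ok], method="average") / (n + 1)
    return out


def snp_windows(
    g: GenotypeTable, snp_idx, flank: int = 100_000
) -> list[Interval]:
    """+-flank windows around the given SNPs, clipped to scaffold bounds, merged."""
    out = []
    for j in np.atleast_1d(snp_idx):
        row = g.snps.iloc[int(j)]
        length = g.scaffold_length(row["scaffold"])
        start = max(0, int(row["pos"]) - flank)
        end = int(row["pos"]) + flank
        if length is not None:
            end = min(end, length)
        out.append(Interval(row["scaffold"], start, max(end, start + 1)))
    return merge_intervals(out)


def scan_population(
    g: GenotypeTable,
    population: str,
    pre_years,
    post_years,
    top_fraction: float = 0.025,
    flank: int = 100_000,
    min_snps: int = 40,
) -> tuple[pd.DataFrame, list[Interval]]:
    """Rank SNPs by |dfreq| between time strata and window the top fraction.

    Returns the per-SNP scan table (freq_pre, freq_post, delta_signed,
    delta_abs, quantile, selected) and the merged candidate windows.
    Filtering and LD pruning are assumed already applied.
    """
    pre_mask = g.sample_mask(population=population, years=pre_years)
    post_mask = g.sample_mask(population=population, years=post_years)
    freq_pre = allele_frequencies(g, pre_mask)
    freq_post = allele_frequencies(g, post_mask)
    delta = freq_post - freq_pre
    ok = ~np.isnan(delta)
    if int(ok.sum()) < min_snps:
        raise ValueError(
            f"only {int(ok.sum())} SNPs with defined frequency change; "
            f"quantile ranking needs at least {min_snps}"
        )
    q = empirical_quantiles(np.abs(delta))
    selected = np.nan_to_num(q, nan=0.0) > 1.0 - top_fraction
    table = g.snps.copy()
    table["population"] = population
    table["freq_pre"] = freq_pre
    table["freq_post"] = freq_post
    table["delta_signed"] = delta
    table["delta_abs"] = np.abs(delta)
    table["quantile"] = q
    table["selected"] = selected
    windows = snp_windows(g, np.flatnonzero(selected), flank=flank)
    return table, windows


@dataclass
class CandidateRegion:
    interval: Interval
    supporting_snps: dict = field(default_factory=dict)  # population -> list of snp ids
    genes: list = field(default_factory=list)


def intersect_populations(
    interval_lists: dict, scan_tables: dict | None = None, flank: int = 100_000
) -> list[CandidateRegion]:
    """Candidate regions where the merged windows of every population overlap.

    ``interval_lists`` maps population name -> merged window list.  When the
    per-population scan tables are supplied, the top-quantile SNPs whose
    windows touch each region are attached as supporting SNPs.
    """
    pops = list(interval_lists)
    if len(pops) < 2:
        raise ValueError("need at least two populations to intersect")
    common = merge_intervals(interval_lists[pops[0]])
    for p in pops[1:]:
        common = intersect_intervals(common, merge_intervals(interval_lists[p]))
    regions = [CandidateRegion(iv) for iv in common]
    if scan_tables is not None:
        for region in regions:
            for p in pops:
                t = scan_tables[p]
                sel = t[t["selected"]]
                near = sel[
                    (sel["scaffold"] == region.interval.scaffold)
                    & (sel["pos"] + flank > region.interval.start)
                    & (sel["pos"] - flank < region.interval.end)
                ]
                region.supporting_snps[p] = near["snp_id"].tolist()
    return regions


def attach_genes(regions: list[CandidateRegion], genes: list[GeneRecord]) -> None:
    for region in regions:
        region.genes = [gr for gr in genes if gr.interval.overlaps(region.interval)]


def sliding_window_mean_delta(
    scan_table: pd.DataFrame,
    scaffolds: pd.DataFrame,
    window: int = 200_000,
    step: int = 50_000,
) -> pd.DataFrame:
    """Mean |dfreq| in sliding windows tiled per scaffold (NaN for empty windows)."""
    rows = []
    for _, srow in scaffolds.iterrows():
        scaf, length = srow["scaffold"], int(srow["length"])
        t = scan_table[scan_table["scaffold"] == scaf]
        pos = t["pos"].to_numpy()
        d = t["delta_abs"].to_numpy()
        start = 0
        while start < length:
            end = min(start + window, length)
            m = (pos >= start) & (pos < end)
            rows.append(
                {
                    "scaffold": scaf,
                    "start": start,
                    "end": end,
                    "n_snps": int(m.sum()),
                    "mean_delta_abs": float(np.nanmean(d[m])) if m.any() else np.nan,
                }
            )
            if end == length:
                break
            start += step
    return pd.DataFrame(rows)


def ld_decay_curve(
    g: GenotypeTable,
    sample_mask=None,
    maf_min: float = 0.05,
    max_dist: int = 500_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Binned mean genotypic r^2 against pairwise distance, within scaffolds.

    Only SNPs with MAF > ``maf_min`` in the target samples enter; pairs with
    undefined r^2 are dropped.  Returns columns bin_left, bin_right, n_pairs,
    mean_r2.
    """
    from .filters import minor_allele_frequency

    maf = minor_allele_frequency(
        g if sample_mask is None else g.subset_samples(np.asarray(sample_mask, bool))
    )
    keep = np.nan_to_num(maf, nan=0.0) > maf_min
    sub = g.subset_snps(keep)
    if sample_mask is not None:
        sub = sub.subset_samples(np.asarray(sample_mask, bool))
    D = _dosage_float(sub)
    pos = sub.snps["pos"].to_numpy()
    scaf = sub.snps["scaffold"].to_numpy()
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for j in range(sub.n_snps):
        same = (
            (scaf == scaf[j])
            & (pos > pos[j])
            & (pos - pos[j] <= max_dist)
        )
        idx = np.flatnonzero(same)
        if idx.size == 0:
            continue
        r2 = _r2_one_vs_many(D, j, idx)
        ok = ~np.isnan(r2)
        if not ok.any():
            continue
        b = np.clip(np.searchsorted(edges, pos[idx[ok]] - pos[j], side="right") - 1, 0, n_bins - 1)
        np.add.at(sums, b, r2[ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "n_pairs": counts,
            "mean_r2": mean_r2,
        }
    )
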