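"""SNP-level quality filters for reduced-representation genotype data.

The filters reproduce the study design this package targets: drop X-linked
scaffolds, drop whole RAD loci whose excess heterozygosity betrays collapsed
paralogues, require a minimum genotyping rate, and drop near-monomorphic
SNPs.  Each step returns the filtered table plus a :class:`FilterReport`;
thresholds use strict inequalities exactly as configured (a SNP *at* the
threshold survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable


@dataclass(frozen=True)
class FilterReport:
    step_name: str
    n_before: int
    n_after: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_after > self.n_before:
            raise ValueError("filter cannot add SNPs")

    def to_dict(self) -> dict:
        return {
            "step": self.step_name,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "params": dict(self.params),
        }


def filter_x_scaffolds(g: GenotypeTable, x_scaffolds) -> tuple[GenotypeTable, FilterReport]:
    """Remove every SNP on a scaffold assigned to the X chromosome."""
    x = set(x_scaffolds)
    keep = ~g.snps["scaffold"].isin(x).to_numpy()
    report = FilterReport(
        "x_scaffolds", g.n_snps, int(keep.sum()), {"n_x_scaffolds": len(x)}
    )
    return g.subset_snps(keep), report


def observed_heterozygosity(g: GenotypeTable, sample_mask=None) -> np.ndarray:
    """Per-SNP fraction of *called* genotypes that are heterozygous (NaN if none called)."""
    calls = g.calls if sample_mask is None else g.calls[sample_mask]
    called = (calls >= 0).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def filter_paralog_loci(
    g: GenotypeTable, het_max: float = 0.5
) -> tuple[GenotypeTable, FilterReport]:
    """Drop whole RAD loci where any SNP has observed heterozygosity > het_max.

    SNPs without a locus id are judged individually.  Excess heterozygosity
    across all samples is the classic signature of collapsed paralogous loci
    in reduced-representation data.
    """
    het = observed_heterozygosity(g)
    over = np.nan_to_num(het, nan=0.0) > het_max
    locus = g.snps["locus_id"]
    has_locus = locus.notna().to_numpy()
    bad_loci = set(locus.to_numpy()[has_locus & over])
    drop = over | (has_locus & locus.isin(bad_loci).to_numpy())
    report = FilterReport(
        "paralog_het", g.n_snps, int((~drop).sum()), {"het_max": het_max}
    )
    return g.subset_snps(~drop), report


def filter_call_rate(
    g: GenotypeTable, min_fraction: float, sample_mask=None
) -> tuple[GenotypeTable, FilterReport]:
    """Remove SNPs called in fewer than ``min_fraction`` of the targeted samples.

    ``sample_mask`` restricts the denominator to a population and/or time
    stratum; comparison is on the exact fraction (strict <).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if sample_mask is None:
        sample_mask = np.ones(g.n_samples, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    n = int(sample_mask.sum())
    if n == 0:
        raise ValueError("empty sample subset for call-rate filter")
    called = g.called_mask[sample_mask].sum(axis=0)
    keep = called / n >= min_fraction
    report = FilterReport(
        "call_rate",
        g.n_snps,
        int(keep.sum()),
        {"min_fraction": min_fraction, "n_samples": n},
    )
    return g.subset_snps(keep), report


def minor_allele_frequency(g: GenotypeTable, sample_mask=None) -> np.ndarray:
    calls = g.calls if sample_mask is None else g.calls[sample_mask]
    called = (calls >= 0).sum(axis=0)
    alt = np.where(calls >= 0, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / (2.0 * called), np.nan)
    return np.minimum(freq, 1.0 - freq)


def filter_maf(g: GenotypeTable, maf_min: float) -> tuple[GenotypeTable, FilterReport]:
    """Remove SNPs with minor-allele frequency < maf_min over all called genotypes."""
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    maf = minor_allele_frequency(g)
    if maf_min == 0:
        keep = np.ones(g.n_snps, dtype=bool)
    else:  # NaN maf (nothing called) cannot meet a positive threshold
        keep = np.nan_to_num(maf, nan=-1.0) >= maf_min
    report = FilterReport("maf", g.n_snps, int(keep.sum()), {"maf_min": maf_min})
    return g.subset_snps(keep), report


def apply_standard_filters(
    g: GenotypeTable,
    x_scaffolds=(),
    het_max: float = 0.5,
    call_rate_min: float = 1 / 3,
    maf_min: float = 0.01,
) -> tuple[GenotypeTable, list[FilterReport]]:
    """The fixed dataset-wide filter chain: X -> paralog -> call rate -> MAF."""
    reports = []
    g, r = filter_x_scaffolds(g, x_scaffolds)
    reports.append(r)
    g, r = filter_paralog_loci(g, het_max=het_max)
    reports.append(r)
    g, r = filter_call_rate(g, min_fraction=call_rate_min)
    reports.append(r)
    g, r = filter_maf(g, maf_min=maf_min)
    reports.append(r)
    return g, reports
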