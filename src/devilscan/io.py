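"""Data model and readers/writers for genotypes, metadata, annotation and intervals.

Conventions
-----------
* All coordinates are 0-based half-open internally.  VCF input (1-based) is
  converted on read; BED output is written natively.
* Missing alleles/genotypes are coded ``-1`` in integer matrices.
* Sample metadata is a tab-separated file with the exact header
  ``sample_id\tpopulation\tyear``.
* The scaffold ordering table is a tab-separated file with header
  ``scaffold\tchromosome\trank\tlength`` giving, per scaffold, its assigned
  chromosome, its rank within the chromosome-level concatenation order and
  its length in bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_COLUMNS = ["snp_id", "scaffold", "chromosome", "pos", "ref", "alt", "locus_id"]
SAMPLE_COLUMNS = ["sample_id", "population", "year"]
SCAFFOLD_COLUMNS = ["scaffold", "chromosome", "rank", "length"]

YEAR_RANGE = (1900, 2100)


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP (scaffold-level 0-based position)."""

    snp_id: str
    scaffold: str
    chromosome: str
    pos: int
    ref: str
    alt: str
    locus_id: str | None = None

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position for SNP {self.snp_id}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str
    year: int

    def __post_init__(self):
        if not (YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]):
            raise ValueError(
                f"sample {self.sample_id}: year {self.year} outside plausible range"
            )


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on one scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    interval: Interval
    gene_id: str
    go_terms: frozenset = frozenset()


@dataclass
class GenotypeTable:
    """Diploid genotype calls for a set of samples at a set of SNPs.

    ``a1``/``a2`` hold the two alleles per genotype (0/1, -1 = missing) so
    that phase information survives for downstream haplotype extraction;
    ``phased`` marks genotypes whose allele order is meaningful.  A genotype
    with either allele missing is treated as entirely missing.
    """

    samples: pd.DataFrame  # columns SAMPLE_COLUMNS
    snps: pd.DataFrame  # columns SNP_COLUMNS
    a1: np.ndarray  # (n_samples, n_snps) int8
    a2: np.ndarray
    phased: np.ndarray  # (n_samples, n_snps) bool
    scaffolds: pd.DataFrame | None = None  # columns SCAFFOLD_COLUMNS

    def __post_init__(self):
        ns, nv = len(self.samples), len(self.snps)
        for name in ("a1", "a2", "phased"):
            arr = getattr(self, name)
            if arr.shape != (ns, nv):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(ns, nv)}"
                )
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.snps.duplicated(subset=["scaffold", "pos"]).any():
            raise ValueError("duplicate (scaffold, pos) pairs")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def calls(self) -> np.ndarray:
        """Alt-allele dosage matrix with -1 for missing genotypes."""
        missing = (self.a1 < 0) | (self.a2 < 0)
        out = (self.a1 + self.a2).astype(np.int8)
        out[missing] = MISSING
        return out

    @property
    def called_mask(self) -> np.ndarray:
        return (self.a1 >= 0) & (self.a2 >= 0)

    def snp_meta(self, j: int) -> SnpMeta:
        row = self.snps.iloc[j]
        locus = row["locus_id"]
        return SnpMeta(
            snp_id=row["snp_id"],
            scaffold=row["scaffold"],
            chromosome=row["chromosome"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            locus_id=None if pd.isna(locus) else locus,
        )

    # -- subsetting ------------------------------------------------------
    def subset_snps(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            a1=self.a1[:, idx],
            a2=self.a2[:, idx],
            phased=self.phased[:, idx],
        )

    def subset_samples(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            a1=self.a1[idx, :],
            a2=self.a2[idx, :],
            phased=self.phased[idx, :],
        )

    def sample_mask(self, population=None, years=None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            mask &= (self.samples["population"] == population).to_numpy()
        if years is not None:
            mask &= self.samples["year"].isin(list(years)).to_numpy()
        return mask

    def scaffold_length(self, scaffold: str) -> int | None:
        if self.scaffolds is None:
            return None
        hit = self.scaffolds.loc[self.scaffolds["scaffold"] == scaffold, "length"]
        return int(hit.iloc[0]) if len(hit) else None


@dataclass
class HaplotypeSet:
    """Phased haplotypes for one population/time-stratum on one scaffold.

    ``haplotypes`` is (2 x retained individuals) x n_snps with values in
    {0, 1, -1}; -1 marks sites missing on that haplotype (a missing site
    breaks haplotype identity for every pair involving it).
    """

    haplotypes: np.ndarray
    snps: pd.DataFrame
    stratum: str

    def __post_init__(self):
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype matrix must have an even row count")
        if self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype/SNP column mismatch")
        if self.snps["scaffold"].nunique() > 1:
            raise ValueError("HaplotypeSet spans multiple scaffolds")
        pos = self.snps["pos"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("SNP positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.snps["pos"].to_numpy()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    if list(df.columns) != SAMPLE_COLUMNS:
        raise ValueError(
            f"metadata header must be {SAMPLE_COLUMNS}, got {list(df.columns)}"
        )
    df["year"] = df["year"].astype(int)
    bad = ~df["year"].between(*YEAR_RANGE)
    if bad.any():
        raise ValueError(f"implausible collection years: {df.loc[bad, 'year'].tolist()}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


def read_scaffold_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "chromosome": str})
    if list(df.columns) != SCAFFOLD_COLUMNS:
        raise ValueError(f"scaffold table header must be {SCAFFOLD_COLUMNS}")
    if df["scaffold"].duplicated().any():
        raise ValueError("scaffold listed twice in ordering table")
    return df


def read_genotypes(path, metadata_path, scaffold_table_path=None) -> GenotypeTable:
    """Read a VCF (GT field required) plus sample metadata into a GenotypeTable.

    Non-biallelic records are skipped (count logged).  A VCF sample absent
    from the metadata is a hard error.
    """
    from cyvcf2 import VCF

    meta = read_metadata(metadata_path)
    scaffolds = (
        read_scaffold_table(scaffold_table_path) if scaffold_table_path else None
    )
    chrom_of = (
        dict(zip(scaffolds["scaffold"], scaffolds["chromosome"]))
        if scaffolds is not None
        else {}
    )

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"])
    for s in vcf_samples:
        if s not in known:
            raise ValueError(f"VCF sample {s!r} absent from metadata")
    meta_by_id = meta.set_index("sample_id")
    samples = meta_by_id.loc[vcf_samples].reset_index()[SAMPLE_COLUMNS]

    snp_rows = []
    a1_cols, a2_cols, ph_cols = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=np.int64)  # (n, 3): a1, a2, phased
        a1 = gts[:, 0].astype(np.int8)
        a2 = gts[:, 1].astype(np.int8)
        ph = gts[:, 2].astype(bool)
        a1[a1 < 0] = MISSING
        a2[a2 < 0] = MISSING
        locus = dict(var.INFO).get("LOCUS")
        snp_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "scaffold": var.CHROM,
                "chromosome": chrom_of.get(var.CHROM, "unplaced"),
                "pos": var.POS - 1,  # to 0-based
                "ref": var.REF,
                "alt": var.ALT[0],
                "locus_id": locus,
            }
        )
        a1_cols.append(a1)
        a2_cols.append(a2)
        ph_cols.append(ph)
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)

    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)
    n, v = len(samples), len(snps)
    stack = lambda cols: (
        np.stack(cols, axis=1) if v else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeTable(
        samples=samples,
        snps=snps,
        a1=stack(a1_cols).astype(np.int8),
        a2=stack(a2_cols).astype(np.int8),
        phased=stack(ph_cols).astype(bool),
        scaffolds=scaffolds,
    )


def write_genotypes(g: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a minimal VCF 4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.scaffolds is not None:
            for _, row in g.scaffolds.iterrows():
                fh.write(f"##contig=<ID={row['scaffold']},length={row['length']}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples["sample_id"])
            + "\n"
        )
        a1, a2, ph = g.a1, g.a2, g.phased
        for j in range(g.n_snps):
            row = g.snps.iloc[j]
            locus = row["locus_id"]
            info = "." if pd.isna(locus) or locus is None else f"LOCUS={locus}"
            gts = []
            for i in range(g.n_samples):
                x, y = a1[i, j], a2[i, j]
                sep = "|" if ph[i, j] else "/"
                sx = "." if x < 0 else str(x)
                sy = "." if y < 0 else str(y)
                gts.append(f"{sx}{sep}{sy}")
            fh.write(
                f"{row['scaffold']}\t{row['pos'] + 1}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_scaffold_table(scaffolds: pd.DataFrame, path) -> None:
    scaffolds[SCAFFOLD_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval utilities (shared by the scan, composite and annotation modules)
# ---------------------------------------------------------------------------


def merge_intervals(intervals) -> list[Interval]:
    """Merge overlapping/adjacent-overlapping intervals; sorted by (scaffold, start)."""
    out: list[Interval] = []
    by_key = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))
    for iv in by_key:
        if out and out[-1].scaffold == iv.scaffold and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.scaffold, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_intervals(a, b) -> list[Interval]:
    """Intersection of two merged interval lists (half-open semantics)."""
    out = []
    for iv in a:
        for jv in b:
            if iv.scaffold != jv.scaffold:
                continue
            lo, hi = max(iv.start, jv.start), min(iv.end, jv.end)
            if lo < hi:
                out.append(Interval(iv.scaffold, lo, hi))
    return merge_intervals(out)


def write_intervals(intervals, path) -> None:
    """Write intervals as BED3 (0-based half-open), merged and sorted."""
    merged = merge_intervals(intervals)
    with open(path, "w") as fh:
        for iv in merged:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")


def read_intervals(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2])))
    return out


def read_genes(path) -> list[GeneRecord]:
    """Read gene annotation as BED6+1: the 7th column holds comma-separated GO terms."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            terms = frozenset(t for t in f[6].split(",") if t) if len(f) > 6 else frozenset()
            out.append(
                GeneRecord(Interval(f[0], int(f[1]), int(f[2])), gene_id=f[3], go_terms=terms)
            )
    return out


def write_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for gr in sorted(genes, key=lambda g: (g.interval.scaffold, g.interval.start)):
            terms = ",".join(sorted(gr.go_terms))
            fh.write(
                f"{gr.interval.scaffold}\t{gr.interval.start}\t{gr.interval.end}\t"
                f"{gr.gene_id}\t0\t+\t{terms}\n"
            )


# ---------------------------------------------------------------------------
# Haplotype extraction
# ---------------------------------------------------------------------------


def extract_haplotypes(
    g: GenotypeTable,
    population: str,
    years,
    scaffold: str,
    stratum: str = "pre",
    min_rate: float = 0.30,
) -> HaplotypeSet:
    """Extract phased haplotypes for one population/time-stratum on one scaffold.

    Each retained individual contributes two haplotype rows; haplotype rows
    with fewer than ``min_rate`` of sites called are dropped.  Any called but
    unphased genotype among the selected samples is a hard error.
    """
    smask = g.sample_mask(population=population, years=years)
    vmask = (g.snps["scaffold"] == scaffold).to_numpy()
    sub = g.subset_samples(smask).subset_snps(vmask)
    order = np.argsort(sub.snps["pos"].to_numpy(), kind="stable")
    sub = sub.subset_snps(order)

    called = sub.called_mask
    unphased = called & ~sub.phased
    if unphased.any():
        i = int(np.flatnonzero(unphased.any(axis=1))[0])
        raise ValueError(
            f"unphased genotype for sample {sub.samples['sample_id'].iloc[i]!r} "
            f"on scaffold {scaffold}"
        )

    # half-missing genotypes (e.g. "./1") are demoted to fully missing so
    # the two rows of an individual always share a call rate
    a1 = np.where(called, sub.a1, MISSING).astype(np.int8)
    a2 = np.where(called, sub.a2, MISSING).astype(np.int8)
    rows = np.empty((2 * sub.n_samples, sub.n_snps), dtype=np.int8)
    rows[0::2] = a1
    rows[1::2] = a2
    if sub.n_snps == 0:
        keep = np.zeros(rows.shape[0], dtype=bool)
    else:
        keep = (rows >= 0).mean(axis=1) >= min_rate
    # genotype-level missingness hits both alleles of an individual at once,
    # so the two rows of an individual share a call rate and are kept or
    # dropped together; the even-row invariant therefore holds by design
    kept = rows[keep]
    return HaplotypeSet(haplotypes=kept, snps=sub.snps, stratum=stratum)
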