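"""Site extended-haplotype-homozygosity statistics and the temporal Rsb contrast.

EHHS at offset x from a focal SNP is the probability that two haplotypes
drawn at random are identical over every SNP from the focal site out to x,
normalised to 1 at the focal site.  Haplotype homozygosity over an interval
uses the unbiased estimator

    hh = sum_h n_h (n_h - 1) / (n (n - 1)),

where n_h counts copies of each distinct multi-site haplotype; a missing
site breaks identity for every pair involving it, but the haplotype still
counts in the denominator (conservative, and symmetric between strata).

iES integrates the truncated EHHS curve over bp on both flanks.  Rsb for a
SNP is ln(iES_pre / iES_post); a recent sweep in the post-epidemic stratum
inflates iES_post and pushes Rsb negative.  Raw scores are standardised
genome-wide within a population by subtracting the median and dividing by
the standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HaplotypeSet

DEFAULT_TRUNCATION = 0.05


@dataclass
class EhhCurve:
    focal_index: int
    positions: np.ndarray  # bp offsets from focal SNP (negative left, 0, positive right)
    values: np.ndarray  # EHHS in [0, 1], 1 at offset 0


def _focal_maf(h: HaplotypeSet, focal: int) -> float:
    col = h.haplotypes[:, focal]
    called = col[col >= 0]
    if called.size == 0:
        return 0.0
    f = called.mean()
    return float(min(f, 1.0 - f))


def _group_homozygosity(labels: np.ndarray, alive: np.ndarray, denom: float) -> float:
    if alive.sum() < 2:
        return 0.0
    _, counts = np.unique(labels[alive], return_counts=True)
    return float((counts * (counts - 1)).sum() / denom)


def _scan_flank(H, pos, focal, direction, hh0, denom, truncation):
    n, L = H.shape
    alive = H[:, focal] >= 0
    labels = np.where(alive, H[:, focal], -1).astype(np.int64)
    offs, vals = [], []
    j = focal
    while True:
        j += direction
        if j < 0 or j >= L:
            break
        col = H[:, j]
        alive = alive & (col >= 0)
        labels = labels * 2 + np.where(alive, col, 0)
        if alive.any():  # compress labels to avoid overflow on long scans
            _, inv = np.unique(labels[alive], return_inverse=True)
            labels[alive] = inv
        ehhs = _group_homozygosity(labels, alive, denom) / hh0
        if ehhs < truncation:
            break
        offs.append(pos[j] - pos[focal])
        vals.append(ehhs)
    return offs, vals


def ehhs(
    h: HaplotypeSet,
    focal: int,
    truncation: float = DEFAULT_TRUNCATION,
    min_haplotypes: int = 4,
    maf_min: float = 0.05,
) -> EhhCurve:
    """Site-EHH curve around one focal SNP, truncated where EHHS < ``truncation``."""
    H = np.asarray(h.haplotypes)
    n = H.shape[0]
    if n < min_haplotypes:
        raise ValueError(f"need at least {min_haplotypes} haplotypes, have {n}")
    maf = _focal_maf(h, focal)
    if maf_min > 0:
        if maf == 0.0:
            raise ValueError("focal SNP is monomorphic")
        if maf < maf_min:
            raise ValueError(f"focal SNP MAF {maf:.3f} below {maf_min}")
    pos = h.positions
    denom = float(n * (n - 1))
    alive0 = H[:, focal] >= 0
    hh0 = _group_homozygosity(np.where(alive0, H[:, focal], -1), alive0, denom)
    if hh0 == 0.0:
        raise ValueError("no pair of haplotypes called at the focal SNP")
    left = _scan_flank(H, pos, focal, -1, hh0, denom, truncation)
    right = _scan_flank(H, pos, focal, +1, hh0, denom, truncation)
    positions = np.array(list(reversed(left[0])) + [0] + right[0], dtype=float)
    values = np.array(list(reversed(left[1])) + [1.0] + right[1], dtype=float)
    return EhhCurve(focal_index=focal, positions=positions, values=values)


def ehhs_bruteforce(h: HaplotypeSet, focal: int, truncation: float = DEFAULT_TRUNCATION):
    """O(n^2 L) pairwise-identity reference implementation (test oracle).

    Returns (positions, values) on the same truncation convention as
    :func:`ehhs`.
    """
    H = np.asarray(h.haplotypes)
    n, L = H.shape
    pos = h.positions

    def hh(j0, j1):  # inclusive interval
        count = 0
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                seg_a = H[a, j0 : j1 + 1]
                seg_b = H[b, j0 : j1 + 1]
                if np.all(seg_a >= 0) and np.all(seg_b >= 0) and np.array_equal(seg_a, seg_b):
                    count += 1
        return count / (n * (n - 1))

    hh0 = hh(focal, focal)
    positions, values = [0.0], [1.0]
    for j in range(focal + 1, L):
        v = hh(focal, j) / hh0
        if v < truncation:
            break
        positions.append(pos[j] - pos[focal])
        values.append(v)
    for j in range(focal - 1, -1, -1):
        v = hh(j, focal) / hh0
        if v < truncation:
            break
        positions.insert(0, pos[j] - pos[focal])
        values.insert(0, v)
    return np.array(positions, dtype=float), np.array(values, dtype=float)


def ies(curve: EhhCurve) -> float:
    """Trapezoidal integral of the EHHS curve over bp, both flanks (0 for a single point)."""
    p, v = curve.positions, curve.values
    if p.size < 2:
        return 0.0
    zero = int(np.searchsorted(p, 0.0))
    left = abs(np.trapezoid(v[: zero + 1], p[: zero + 1])) if zero > 0 else 0.0
    right = float(np.trapezoid(v[zero:], p[zero:])) if zero < p.size - 1 else 0.0
    return float(left + right)


def rsb_table(
    pre: HaplotypeSet,
    post: HaplotypeSet,
    maf_min: float = 0.05,
    truncation: float = DEFAULT_TRUNCATION,
) -> pd.DataFrame:
    """Raw Rsb = ln(iES_pre / iES_post) per SNP eligible in both strata.

    SNPs must have MAF >= ``maf_min`` in both strata and a positive iES in
    both; others are excluded.  Standardisation is a separate, genome-wide
    step (:func:`standardize_rsb`).
    """
    if not pre.snps["pos"].equals(post.snps["pos"]):
        raise ValueError("pre and post strata must share SNP coordinates")
    rows = []
    for j in range(len(pre.snps)):
        if _focal_maf(pre, j) < maf_min or _focal_maf(post, j) < maf_min:
            continue
        try:
            c_pre = ehhs(pre, j, truncation=truncation, maf_min=maf_min)
            c_post = ehhs(post, j, truncation=truncation, maf_min=maf_min)
        except ValueError:
            continue
        i_pre, i_post = ies(c_pre), ies(c_post)
        if i_pre <= 0 or i_post <= 0:
            continue
        row = pre.snps.iloc[j]
        rows.append(
            {
                "snp_id": row["snp_id"],
                "scaffold": row["scaffold"],
                "pos": int(row["pos"]),
                "ies_pre": i_pre,
                "ies_post": i_post,
                "rsb_raw": float(np.log(i_pre / i_post)),
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "scaffold", "pos", "ies_pre", "ies_post", "rsb_raw"]
    )


def standardize_rsb(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``rsb_std`` = (rsb_raw - median) / sd, pooled over the whole table."""
    out = table.copy()
    raw = out["rsb_raw"].to_numpy(dtype=float)
    sd = raw.std(ddof=1) if raw.size > 1 else np.nan
    med = np.median(raw) if raw.size else np.nan
    out["rsb_std"] = (raw - med) / sd if raw.size > 1 and sd > 0 else np.nan
    return out


def rsb(
    pre: HaplotypeSet,
    post: HaplotypeSet,
    maf_min: float = 0.05,
    truncation: float = DEFAULT_TRUNCATION,
) -> pd.DataFrame:
    """Standardised Rsb table for one scaffold pair of strata (convenience wrapper)."""
    return standardize_rsb(rsb_table(pre, post, maf_min=maf_min, truncation=truncation))
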