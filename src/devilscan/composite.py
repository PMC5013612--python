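"""Window-level composite selection statistic.

The genome is tiled into non-overlapping 100 kb windows (grid anchored at
position 0 of each scaffold).  For every (population, statistic)
combination — statistics being the allele-frequency-change quantile and the
Rsb quantile — the window's score is the maximum genome-wide empirical
quantile q among its s SNPs with a defined value, adjusted for window SNP
count as

    p = 1 - q**s,

the probability of seeing a value this extreme among s independent SNPs
(conservative when SNPs are correlated).  Adjusted p values across the
available combinations are combined by Fisher's method,

    X = -2 * sum(ln p_i),    X ~ chi^2 with df = 2n under the null,

and the window's combined P value is the upper-tail chi-squared probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import Interval


def adjusted_p(q: float, s: int) -> float:
    """Window-level adjusted P value 1 - q**s for max quantile q among s SNPs."""
    if not (0 < q < 1):
        raise ValueError("quantile must be strictly inside (0, 1)")
    if s < 1:
        raise ValueError("window must contain at least one SNP for this statistic")
    return 1.0 - q**s


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: returns (score, df, combined_p) for independent P values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no P values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P values must be in (0, 1]")
    score = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return score, df, float(chi2.sf(score, df))


def window_grid(scaffolds: pd.DataFrame, window: int = 100_000) -> pd.DataFrame:
    """Non-overlapping windows tiled from position 0 of each scaffold."""
    rows = []
    for _, srow in scaffolds.iterrows():
        length = int(srow["length"])
        for start in range(0, length, window):
            rows.append(
                {
                    "scaffold": srow["scaffold"],
                    "start": start,
                    "end": min(start + window, length),
                }
            )
    return pd.DataFrame(rows)


def composite_scan(
    quantile_tables: dict,
    scaffolds: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Combine per-SNP quantile tables into the window composite statistic.

    ``quantile_tables`` maps a combination label (e.g. ``("Freycinet",
    "afchange")``) to a DataFrame with columns scaffold, pos, quantile where
    the quantile is the SNP's genome-wide empirical quantile for that
    statistic, strictly inside (0, 1); SNPs with a missing quantile must be
    excluded upstream.  Windows with no combination at all get NaN
    combined_p.  Output is sorted by combined_p.
    """
    grid = window_grid(scaffolds, window=window)
    grid["window_id"] = np.arange(len(grid))
    key = {
        (row.scaffold, row.start): row.window_id
        for row in grid.itertuples(index=False)
    }
    n_win = len(grid)
    scores = np.zeros(n_win)
    n_combos = np.zeros(n_win, dtype=int)
    per_combo = {}
    for label, t in quantile_tables.items():
        t = t.dropna(subset=["quantile"])
        widx = np.array(
            [
                key.get((s, (int(p) // window) * window), -1)
                for s, p in zip(t["scaffold"], t["pos"])
            ],
            dtype=int,
        )
        ok = widx >= 0
        t, widx = t[ok], widx[ok]
        grp = pd.DataFrame({"w": widx, "q": t["quantile"].to_numpy()}).groupby("w")["q"]
        qmax = grp.max()
        s_count = grp.size()
        p_adj = 1.0 - qmax**s_count
        # clip away exact zeros that would make the Fisher log blow up; the
        # (0,1)-interior quantile convention upstream makes this a no-op
        p_adj = p_adj.clip(lower=np.nextafter(0, 1))
        scores[p_adj.index] += -2.0 * np.log(p_adj.to_numpy())
        n_combos[p_adj.index] += 1
        per_combo[label] = pd.DataFrame(
            {"window_id": qmax.index, "max_q": qmax.to_numpy(),
             "n_snps": s_count.to_numpy(), "adjusted_p": p_adj.to_numpy()}
        )
    grid["composite_score"] = scores
    grid["df"] = 2 * n_combos
    with np.errstate(invalid="ignore"):
        grid["combined_p"] = np.where(
            n_combos > 0, chi2.sf(scores, np.maximum(grid["df"], 1)), np.nan
        )
    out = grid.sort_values("combined_p", kind="stable").reset_index(drop=True)
    out.attrs["per_combo"] = per_combo
    return out


def region_combined_p(window_table: pd.DataFrame, region: Interval) -> float:
    """Combined P for an arbitrary region: minimum over overlapping grid windows."""
    t = window_table
    hit = t[
        (t["scaffold"] == region.scaffold)
        & (t["start"] < region.end)
        & (t["end"] > region.start)
    ]
    vals = hit["combined_p"].dropna()
    return float(vals.min()) if len(vals) else np.nan


def window_rank_percent(window_table: pd.DataFrame) -> pd.Series:
    """Percentile rank (0 = most significant) of each window by combined_p."""
    p = window_table["combined_p"]
    return 100.0 * (p.rank(method="min") - 1) / p.notna().sum()
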