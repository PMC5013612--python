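"""Region-pair randomization test for functional-annotation content.

The observed unit is a *pair* of candidate regions.  Each draw samples two
distinct SNPs uniformly without replacement, centres a fixed-width window on
each (clipped at scaffold ends), and asks whether the pair of windows
contains at least one gene carrying a target GO term (``criterion="any"``),
or genes covering at least two distinct target terms between them
(``criterion="two_categories"``).  The fraction of hitting draws estimates
how often a random region pair would look as functionally loaded as the
observed candidate pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneRecord, Interval


@dataclass
class RandomizationResult:
    n_draws: int
    target_terms: frozenset
    fraction_hit: float
    observed_hit: bool | None
    empirical_p: float | None
    criterion: str


def _pair_terms(intervals, genes) -> set:
    terms = set()
    for gr in genes:
        if any(gr.interval.overlaps(iv) for iv in intervals):
            terms |= set(gr.go_terms)
    return terms


def pair_hits(intervals, genes, target_terms, criterion: str = "any") -> bool:
    """Does a pair (or list) of regions meet the annotation criterion?

    ``any``: >= 1 overlapping gene carries >= 1 target term.
    ``two_categories``: the overlapping genes cover >= 2 distinct target terms.
    """
    found = _pair_terms(intervals, genes) & set(target_terms)
    if criterion == "any":
        return len(found) >= 1
    if criterion == "two_categories":
        return len(found) >= 2
    raise ValueError(f"unknown criterion {criterion!r}")


def randomization_test(
    snps: pd.DataFrame,
    genes: list[GeneRecord],
    target_terms,
    scaffold_lengths: dict | None = None,
    n_draws: int = 1000,
    width: int = 200_000,
    seed: int = 0,
    criterion: str = "any",
    observed_regions: list[Interval] | None = None,
) -> RandomizationResult:
    """Sample ``n_draws`` random region pairs and score their annotation content.

    ``snps`` needs columns scaffold, pos.  When ``observed_regions`` is
    given, ``empirical_p`` is the fraction of draws matching-or-exceeding
    the observed pair's criterion status (1.0 when the observed pair itself
    fails the criterion).
    """
    if len(snps) < 2:
        raise ValueError("need at least two SNPs to draw region pairs")
    rng = np.random.default_rng(seed)
    target_terms = frozenset(target_terms)
    scafs = snps["scaffold"].to_numpy()
    pos = snps["pos"].to_numpy(dtype=int)
    half = width // 2

    # pre-index genes per scaffold for speed
    by_scaf: dict[str, list[GeneRecord]] = {}
    for gr in genes:
        by_scaf.setdefault(gr.interval.scaffold, []).append(gr)

    def window(i):
        length = (scaffold_lengths or {}).get(scafs[i])
        start = max(0, pos[i] - half)
        end = pos[i] + half
        if length is not None:
            end = min(end, length)
        return Interval(scafs[i], start, max(end, start + 1))

    hits = 0
    for _ in range(n_draws):
        i, j = rng.choice(len(snps), size=2, replace=False)
        ivs = [window(i), window(j)]
        local = [g for iv in ivs for g in by_scaf.get(iv.scaffold, [])]
        if pair_hits(ivs, local, target_terms, criterion=criterion):
            hits += 1
    fraction_hit = hits / n_draws

    observed_hit = None
    empirical_p = None
    if observed_regions is not None:
        observed_hit = pair_hits(observed_regions, genes, target_terms, criterion=criterion)
        empirical_p = fraction_hit if observed_hit else 1.0
    return RandomizationResult(
        n_draws=n_draws,
        target_terms=target_terms,
        fraction_hit=fraction_hit,
        observed_hit=observed_hit,
        empirical_p=empirical_p,
        criterion=criterion,
    )
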