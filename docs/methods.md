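# Methods

This note documents the models implemented in `devilscan`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Scientific setting

The package targets a specific and unusual inference regime: detecting a
selective response within ~4–6 generations of an epidemic in small, severely
bottlenecked populations (effective sizes of a few tens), genotyped sparsely
(~1 SNP per 33 kb) with heavy per-genotype missingness (call rates 55–70%),
sampled before and after the epidemic in three replicate populations that
share standing genetic variation. On this timescale selection acts on
standing variants, so sweeps are soft and signals muted; the analysis
therefore leans on *concordance* across populations and across statistic
families (frequency change and haplotype homozygosity) rather than on any
single powerful test.

## Filtering

Order is fixed: X-linked scaffolds → paralogue heterozygosity → call rate →
MAF. All thresholds are strict inequalities on the removal side (a SNP
exactly at the threshold survives):

* Observed heterozygosity uses called genotypes only; if any SNP on a RAD
  locus exceeds 0.5, the whole locus is removed (collapsed-paralogue
  signature). SNPs without a locus id are judged individually.
* Call-rate comparisons use exact fractions (no floor rounding at
  non-divisible sample counts).
* MAF is pooled over called alleles across all in-scope samples.
* LD pruning is a single left-to-right pass per scaffold: a SNP is removed
  when some already-retained SNP within 20 list positions *and* 50 kb has
  genotype-correlation r² > 0.99 with it; the leftmost SNP of a violating
  pair always survives (a deterministic resolution of "remove one").
  Genotypic r² is the squared Pearson correlation of dosage vectors over
  jointly called samples, the standard unphased LD measure.

## Frequency-change scan

Per population, allele frequencies are computed in a pre and a post time
stratum (configurable year groupings), and SNPs are ranked by |Δp|.
Empirical quantiles use mid-ranks divided by (N+1), keeping them strictly
inside (0,1) so downstream logarithms are finite. SNPs above the 1−0.025
quantile get ±100 kb windows (clipped at scaffold ends — windows never
span scaffolds, because real inter-scaffold gaps are unknown); windows are
merged per population and intersected across populations (half-open
interval semantics throughout; coordinates are 0-based half-open
internally, converted from 1-based VCF on read). The flank width matches
the observed scale over which LD stays above background (~100 kb). A
200 kb / 50 kb-step sliding-window mean-|Δp| variant is provided as a
sensitivity analysis.

## Haplotype statistics (EHHS, iES, Rsb)

Site-level EHH (all haplotypes, self-normalised at the focal site) is used
rather than allele-partitioned EHH because the temporal contrast compares
the same site across strata, not alleles within a stratum. Haplotype
homozygosity over an interval uses the unbiased estimator
Σ n_h(n_h−1)/(n(n−1)); at the sample sizes involved (tens of haplotypes)
the biased n² version is noticeably off. A missing site breaks identity
for every pair involving it while the haplotype stays in the denominator —
a conservative choice that biases EHHS downward symmetrically in the pre
and post strata. Curves are truncated where EHHS < 0.05 and integration
stops at scaffold ends; iES is the trapezoidal integral over both flanks
in bp.

Rsb for a SNP eligible in both strata (MAF ≥ 0.05 before *and* after) is
ln(iES_pre/iES_post), standardised by subtracting the median and dividing
by the standard deviation, pooled over all scaffolds within a population
(no frequency-bin standardisation). Sign convention: a sweep *after* the
epidemic inflates iES_post and drives Rsb negative, so post-epidemic sweep
evidence sits in the lower tail; when Rsb feeds the composite statistic its
quantiles are computed on −Rsb_std so that, as for frequency change, high
quantile = more sweep evidence.

## Composite window statistic

The genome is tiled into non-overlapping 100 kb windows anchored at
position 0 of each scaffold (the anchor is arbitrary; 0 is reproducible).
For each (population × statistic) combination, a window's score is the
maximum genome-wide quantile q among its s SNPs with non-missing values,
adjusted to p = 1 − q^s — the probability of a maximum this extreme among
s independent SNPs, conservative when SNPs are correlated within the
window. Combinations with s = 0 are skipped. Fisher's method combines the
available adjusted P values (X = −2 Σ ln p, df = 2n) into a combined P per
window. For an arbitrary region (e.g. a cross-population candidate region
that is not a grid window), the region's combined P is the minimum over
overlapping grid windows — an interpretation choice, flagged as such.

Under a null of independent uniform quantiles the combined P is exactly
uniform, which the test suite verifies by KS test; with correlated SNPs
the statistic is conservative by construction.

## Annotation randomization

The sampling unit is a *pair* of regions, because the observed unit is a
pair of candidate regions. Each draw picks two distinct SNPs uniformly,
centres a 200 kb window on each (clipped at scaffold ends) and scores
whether any overlapping gene carries a target GO term (default criterion),
or whether the pair covers two distinct target terms (stricter option).
Gene membership is any overlap with the window, not full containment.
Term matching is literal label matching on the provided annotation — no GO
graph propagation.

## Temporal inference

**Selection.** Trajectories of per-SNP allele counts at dated generations
(2 years/generation) are modelled as a hidden Wright–Fisher chain over
allele counts 0..2Ne with genic selection p′ = p(1+s)/(1+ps) — the minimal
one-parameter fitness model when a single "selective advantage" per allele
is reported — binomial resampling, and binomial sampling of observed
counts. Because Ne ≤ a few hundred, the forward likelihood is computed
exactly with transition matrices (no diffusion approximation); the prior
over the initial hidden state is uniform, avoiding anchoring s on a noisy
first sample. Ne is a fixed input per population (34/37/26 defaults), not
co-estimated. `estimate_s` maximises over a bounded grid (default −0.9 to
3.0, 40 points) with bounded local refinement; the 95% CI is the
profile-likelihood interval at a 1.92 log-likelihood drop, censored (with a
warning) at the search bounds. Counts can be polarised so that s measures
the advantage of the allele that rose in frequency.

**Effective size.** The two-sample temporal estimator pools, over loci,
Fs = Σ(x−y)² / Σ z(1−z) with z=(x+y)/2, applies the small-sample bias
correction Fs′ = [Fs(1 − 1/(4ñ)) − 1/ñ]/(1 + Fs/4) with ñ the harmonic
mean sample size in diploid individuals, and inverts the accumulated-drift
expectation E[Fs′] = 1 − (1 − 1/(2Ne))^t (which reduces to the familiar
Ne = t/(2Fs′) for small Fs′; the exact inversion removes a ~2% bias at
t = 4, Ne ≈ 35). The 95% CI is a delete-one-locus jackknife on Fs′,
transformed to the Ne scale. Non-positive Fs′ (no drift signal) yields an
infinite estimate with a warning. In recovery simulations (5,000 unlinked
loci, truth 35, t = 4) the median estimate is within ~1% of truth and the
jackknife CI covers truth ~90% of the time.

## Synthetic-data generator

The generator emulates the *structure* of the target data, not its full
biology:

* **Standing variation and LD.** Ancestral variation descends from a small
  founder-haplotype set (default 16). Within segments of ~300 kb, site
  alleles are nested subsets of a per-segment founder permutation
  (equivalent to mutations on a caterpillar genealogy), with subset sizes
  drawn from the neutral 1/i spectrum. This produces the strong,
  bottleneck-driven LD — persisting well above background to ~100 kb —
  that motivates flank-based windowing, and yields realistic near-duplicate
  SNP pairs for the pruner. A shared pool (100 diploids) is burnt in for 30
  neutral generations with recombination (1e-8 /bp/gen; adjacent-marker
  crossover model, free recombination between scaffolds) before the three
  populations split from it, so populations share standing variation.
* **Selected site.** One standing variant, forced to ~p0 = 0.2 among
  founders and accepted only if its post-burn-in pool frequency lies in
  (0.15, 0.25); selection is genic with a per-population coefficient
  (default 0.5 everywhere), acting for 6 generations in the first
  population and 4 in the other two. No new mutations arise during the
  epidemic phase.
* **Sampling.** 25 distinct diploid individuals per time point (sampling
  without replacement; requesting more individuals than the population
  holds is an error), pre at the split generation and post at the final
  generation, with per-genotype i.i.d. missingness of 0.31/0.44/0.36
  matching per-individual call rates of ~69/56/64%. Output is truth-phased.
* **Annotation.** Genes are placed by a Poisson process (mean spacing
  150 kb, length 20 kb); 10% carry one target GO term, calibrated so that
  a random 200 kb region pair contains a target-term gene ~25% of the
  time; a target-term gene is placed at the selected site.

What it does **not** emulate: genotyping-error structure, allele dropout,
variable RAD-locus depth, population structure beyond a clean three-way
split, linked selection at more than one site, mutation during the
epidemic, overlapping generations, or real gene/GO structure. Passing
recovery tests on this generator therefore demonstrates correctness of the
statistical machinery under the stated design, not robustness to every
artefact of real RAD data.

## Power at the study design (an honest note)

At the study's own scale the concordance criterion is weakly powered. With
Ne ≤ 37 and only ~4 epidemic generations, the *realized* rise of a selected
standing variant (s = 0.5, p0 ≈ 0.2) exceeds the neutral top-2.5%
|Δp| threshold in only ~40–55% of Wright–Fisher replicates per population —
drift noise at these effective sizes is of the same order as the selected
response. Requiring a concordant window in all three populations compounds
this: end-to-end recovery of the true selected interval occurs in roughly a
fifth of simulated replicates, and even a noiseless observer would be
bounded near ~0.4. Separately, because populations share standing
variation, their marker-informativeness landscapes are correlated, so the
neutral rate of cross-population window overlap runs ~1.5–2× above the
independence expectation computed from marginal window coverage. Both
effects are properties of the study design itself and are reported by the
acceptance machinery rather than hidden by tuning.

## Problem sizes used in tests and the acceptance script

Simulated genomes use 6–12 scaffolds of 5 Mb (~0.9–1.8k SNPs) — large
enough for stable quantile thresholds (hundreds of windows) while keeping a
full pipeline run below a second. Recovery benchmarks use 100–200
replicates (selection) and 50–100 replicates × 5,000 loci (Ne); the
composite-null calibration uses 2,000 windows × 50–100 seeded repetitions.
Deterministic seeding makes every reported number bit-reproducible.

## Numerical conventions and degenerate inputs

* Missing genotypes are −1 in integer matrices and NaN in float statistics;
  a half-missing VCF genotype ("./1") is treated as fully missing.
* Quantiles are strictly interior to (0,1); adjusted P values are clipped
  away from exact 0 before logs (a no-op under the quantile convention).
* r² is undefined (NaN) for monomorphic or <2 jointly-called pairs, and a
  NaN never triggers pruning.
* EHHS requires ≥4 haplotypes and, by default, focal MAF ≥ 0.05 (a
  `maf_min=0` override exists for degenerate/diagnostic inputs where the
  focal site may be monomorphic); a SNP eligible in only one stratum is
  excluded from Rsb.
* Fisher combination rejects p ≤ 0; windows with no eligible combination
  get a missing combined P.
* Ties in the selection-likelihood grid resolve to the grid point; repeated
  fits on identical input are bit-identical (no randomness in the fit).
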