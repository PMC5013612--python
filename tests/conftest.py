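import numpy as np
import pandas as pd
import pytest

from devilscan.io import GenotypeTable, SAMPLE_COLUMNS, SNP_COLUMNS


def make_table(
    calls,
    pos=None,
    scaffold="s1",
    scaffolds=None,
    locus_ids=None,
    populations=None,
    years=None,
    phased=True,
    scaffold_lengths=None,
):
    """Build a GenotypeTable from a dosage matrix (-1 = missing).

    Heterozygotes are stored as (0,1); scalar `scaffold` applies to all SNPs.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, v = calls.shape
    if pos is None:
        pos = np.arange(v) * 1000
    if np.isscalar(scaffold):
        scaffold = [scaffold] * v
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n)],
            "population": populations if populations is not None else ["P"] * n,
            "year": years if years is not None else [2000] * n,
        }
    )[SAMPLE_COLUMNS]
    snps = pd.DataFrame(
        {
            "snp_id": [f"v{j}" for j in range(v)],
            "scaffold": scaffold,
            "chromosome": "chr1",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "locus_id": locus_ids if locus_ids is not None else [f"L{j}" for j in range(v)],
        }
    )[SNP_COLUMNS]
    a1 = np.where(calls == 2, 1, 0).astype(np.int8)
    a2 = np.where(calls >= 1, 1, 0).astype(np.int8)
    a1[calls < 0] = -1
    a2[calls < 0] = -1
    scaffold_df = None
    if scaffold_lengths is not None:
        scaffold_df = pd.DataFrame(
            {
                "scaffold": list(scaffold_lengths),
                "chromosome": "chr1",
                "rank": np.arange(len(scaffold_lengths)),
                "length": [scaffold_lengths[s] for s in scaffold_lengths],
            }
        )
    return GenotypeTable(
        samples=samples,
        snps=snps,
        a1=a1,
        a2=a2,
        phased=np.full(calls.shape, phased),
        scaffolds=scaffold_df,
    )


def make_haplotypes(rows, pos=None, scaffold="s1", stratum="pre"):
    """HaplotypeSet from a list of haplotype rows (-1 = missing site)."""
    from devilscan.io import HaplotypeSet

    H = np.asarray(rows, dtype=np.int8)
    v = H.shape[1]
    if pos is None:
        pos = np.arange(v) * 1000
    snps = pd.DataFrame(
        {
            "snp_id": [f"v{j}" for j in range(v)],
            "scaffold": scaffold,
            "chromosome": "chr1",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "locus_id": [f"L{j}" for j in range(v)],
        }
    )[SNP_COLUMNS]
    return HaplotypeSet(haplotypes=H, snps=snps, stratum=stratum)


@pytest.fixture(scope="session")
def sim_result():
    """One moderately sized simulated dataset shared across tests."""
    from devilscan.simulate import SimConfig, simulate

    return simulate(SimConfig(seed=11, n_scaffolds=6))
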