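import numpy as np
import pandas as pd
import pytest

from devilscan.afchange import (
    allele_frequencies,
    empirical_quantiles,
    intersect_populations,
    ld_decay_curve,
    ld_prune,
    ld_r2_genotypic,
    scan_population,
    sliding_window_mean_delta,
    snp_windows,
)
from devilscan.io import Interval
from conftest import make_table


class TestAlleleFrequencies:
    def test_basic(self):
        g = make_table(np.array([[0], [1], [2]]))
        assert allele_frequencies(g)[0] == 0.5

    def test_missing_excluded_from_denominator(self):
        g = make_table(np.array([[2], [2], [-1]]))
        assert allele_frequencies(g)[0] == 1.0

    def test_all_missing_is_nan(self):
        g = make_table(np.array([[-1], [-1]]))
        assert np.isnan(allele_frequencies(g)[0])


class TestLdR2:
    def test_identical_vectors(self):
        assert ld_r2_genotypic([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ld_r2_genotypic([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_monomorphic_is_nan(self):
        assert np.isnan(ld_r2_genotypic([1, 1, 1], [0, 1, 2]))

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.choice([0, 1, 2, -1], size=50).astype(float)
        b = rng.choice([0, 1, 2, -1], size=50).astype(float)
        m = (a >= 0) & (b >= 0)
        expected = np.corrcoef(a[m], b[m])[0, 1] ** 2
        assert ld_r2_genotypic(a, b) == pytest.approx(expected, abs=1e-12)


class TestLdPrune:
    def test_duplicate_within_limits_removes_second(self):
        calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        g = make_table(calls, pos=[0, 10_000])
        out, removed = ld_prune(g)
        assert out.snps["snp_id"].tolist() == ["v0"] and removed == ["v1"]

    def test_duplicate_beyond_50kb_kept(self):
        calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        g = make_table(calls, pos=[0, 60_000])
        out, removed = ld_prune(g)
        assert out.n_snps == 2 and removed == []

    def test_r2_exactly_at_threshold_kept(self):
        calls = np.array([[0, 0], [1, 1], [2, 2]])
        g = make_table(calls, pos=[0, 1000])
        out, _ = ld_prune(g, r2_max=1.0)  # r2 == 1.0, strict > keeps it
        assert out.n_snps == 2

    def test_chain_of_three_identical_leaves_one(self):
        col = np.array([0, 1, 2, 1, 0])
        calls = np.stack([col, col, col], axis=1)
        g = make_table(calls, pos=[0, 10_000, 20_000])
        out, removed = ld_prune(g)
        assert out.snps["snp_id"].tolist() == ["v0"] and len(removed) == 2

    def test_no_violating_pair_survives(self):
        rng = np.random.default_rng(4)
        base = rng.choice([0, 1, 2], size=(30, 10))
        # add duplicated/near-duplicated columns at various spacings
        calls = np.concatenate([base, base[:, :5]], axis=1)
        pos = np.sort(rng.choice(200_000, size=15, replace=False))
        g = make_table(calls, pos=pos)
        out, _ = ld_prune(g)
        pos2 = out.snps["pos"].to_numpy()
        d = out.calls.astype(float)
        d[d < 0] = np.nan
        for i in range(out.n_snps):
            for j in range(i + 1, out.n_snps):
                if j - i <= 20 and pos2[j] - pos2[i] <= 50_000:
                    r2 = ld_r2_genotypic(d[:, i], d[:, j])
                    assert not (np.nan_to_num(r2) > 0.99)


class TestScanPopulation:
    def make_scan_table(self, n=1000, seed=5):
        rng = np.random.default_rng(seed)
        pre = rng.choice([0, 1, 2], size=(20, n))
        post = rng.choice([0, 1, 2], size=(20, n))
        calls = np.concatenate([pre, post], axis=0)
        pos = np.sort(rng.choice(40_000_000, size=n, replace=False))
        g = make_table(
            calls,
            pos=pos,
            populations=["P"] * 40,
            years=[2000] * 20 + [2010] * 20,
            scaffold_lengths={"s1": 40_000_000},
        )
        return g

    def test_top_fraction_selects_exact_count(self):
        g = self.make_scan_table()
        table, _ = scan_population(g, "P", [2000], [2010])
        # 1000 SNPs at 2.5%: ranks 976..1000 exceed 1 - 0.025 (modulo ties)
        assert 20 <= int(table["selected"].sum()) <= 30

    def test_window_clipping(self):
        g = make_table(
            np.zeros((4, 2), int),
            pos=[500_000, 20_000],
            scaffold_lengths={"s1": 2_000_000},
        )
        g.snps.sort_values("pos", inplace=True, ignore_index=True)
        w = snp_windows(g, [1], flank=100_000)
        assert w == [Interval("s1", 400_000, 600_000)]
        w2 = snp_windows(g, [0], flank=100_000)
        assert w2 == [Interval("s1", 0, 120_000)]

    def test_too_few_snps_is_error(self):
        g = self.make_scan_table(n=30)
        with pytest.raises(ValueError, match="quantile"):
            scan_population(g, "P", [2000], [2010])

    def test_delta_abs_invariant_under_allele_flip(self):
        g = self.make_scan_table(n=60)
        table, _ = scan_population(g, "P", [2000], [2010])
        flipped = g.subset_snps(np.arange(g.n_snps))
        flipped.a1 = np.where(flipped.a1 >= 0, 1 - flipped.a1, -1).astype(np.int8)
        flipped.a2 = np.where(flipped.a2 >= 0, 1 - flipped.a2, -1).astype(np.int8)
        table2, _ = scan_population(flipped, "P", [2000], [2010])
        np.testing.assert_allclose(
            table["delta_abs"].to_numpy(), table2["delta_abs"].to_numpy(), atol=1e-12
        )


def test_quantiles_strictly_interior():
    q = empirical_quantiles(np.array([3.0, 1.0, 2.0, 2.0, np.nan]))
    assert np.nanmin(q) > 0 and np.nanmax(q) < 1
    assert np.isnan(q[-1])


class TestIntersectPopulations:
    def test_three_population_overlap(self):
        lists = {
            "a": [Interval("s1", 0, 200_000)],
            "b": [Interval("s1", 150_000, 350_000)],
            "c": [Interval("s1", 180_000, 380_000)],
        }
        regions = intersect_populations(lists)
        assert [r.interval for r in regions] == [Interval("s1", 180_000, 200_000)]

    def test_disjoint_gives_empty(self):
        lists = {"a": [Interval("s1", 0, 10)], "b": [Interval("s1", 20, 30)]}
        assert intersect_populations(lists) == []

    def test_commutative_over_populations(self):
        rng = np.random.default_rng(6)

        def rand_list():
            out = []
            for _ in range(5):
                s = int(rng.integers(0, 900_000))
                out.append(Interval("s1", s, s + int(rng.integers(1, 100_000))))
            return out

        lists = {"a": rand_list(), "b": rand_list(), "c": rand_list()}
        r1 = intersect_populations(dict(sorted(lists.items())))
        r2 = intersect_populations(dict(sorted(lists.items(), reverse=True)))
        assert [r.interval for r in r1] == [r.interval for r in r2]


def test_sliding_window_mean_matches_hand_computation():
    g = make_table(
        np.zeros((4, 5), int),
        pos=[10_000, 60_000, 110_000, 260_000, 410_000],
        scaffold_lengths={"s1": 500_000},
    )
    scan = g.snps.copy()
    scan["delta_abs"] = [0.1, 0.2, 0.3, 0.4, 0.5]
    out = sliding_window_mean_delta(scan, g.scaffolds, window=200_000, step=50_000)
    first = out.iloc[0]  # [0, 200k): SNPs 0,1,2 -> mean 0.2
    assert first["mean_delta_abs"] == pytest.approx(0.2)
    lone = out[(out["start"] == 250_000)].iloc[0]  # [250k,450k): SNPs 3,4
    assert lone["mean_delta_abs"] == pytest.approx(0.45)
    empty = out[(out["start"] == 150_000)].iloc[0]  # [150k,350k) contains SNP 3 only
    assert empty["mean_delta_abs"] == pytest.approx(0.4)


class TestLdDecay:
    def test_duplicated_columns_give_unit_bins(self):
        col = np.array([0, 0, 1, 2, 2, 1, 0, 2])
        calls = np.stack([col, col, col], axis=1)
        g = make_table(calls, pos=[0, 30_000, 90_000])
        out = ld_decay_curve(g, max_dist=100_000, n_bins=4)
        filled = out.dropna(subset=["mean_r2"])
        assert np.allclose(filled["mean_r2"], 1.0)

    def test_single_snp_empty_curve(self):
        g = make_table(np.array([[0], [1], [2], [1]]))
        out = ld_decay_curve(g, max_dist=10_000, n_bins=2)
        assert out["n_pairs"].sum() == 0
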