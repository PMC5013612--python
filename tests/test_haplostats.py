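import numpy as np
import pandas as pd
import pytest

from devilscan.haplostats import (
    EhhCurve,
    ehhs,
    ehhs_bruteforce,
    ies,
    rsb,
    rsb_table,
    standardize_rsb,
)
from conftest import make_haplotypes


def random_haps(rng, n=12, L=20, missing=0.1):
    H = rng.integers(0, 2, size=(n, L)).astype(np.int8)
    H[rng.random((n, L)) < missing] = -1
    # make sure a mid MAF focal exists
    H[: n // 2, L // 2] = 0
    H[n // 2 :, L // 2] = 1
    pos = np.sort(rng.choice(200_000, size=L, replace=False))
    return make_haplotypes(H, pos=pos)


class TestEhhs:
    def test_identical_haplotypes_give_unit_curve(self):
        row = [0, 1, 0, 1, 1, 0, 1, 0, 1, 0]
        h = make_haplotypes([row, row, row, row])
        c = ehhs(h, 5, maf_min=0.0)
        assert np.allclose(c.values, 1.0)
        assert len(c.positions) == 10

    def test_offset_zero_is_one(self):
        rng = np.random.default_rng(7)
        h = random_haps(rng)
        c = ehhs(h, 10)
        assert c.values[np.searchsorted(c.positions, 0)] == 1.0

    def test_six_constructed_haplotypes_match_pairwise_counting(self):
        H = [
            [0, 0, 1, 0, 0],
            [0, 0, 1, 0, 0],
            [1, 0, 1, 1, 0],
            [1, 0, 1, 1, 1],
            [0, 1, 0, 0, 1],
            [0, 1, 0, 1, 1],
        ]
        h = make_haplotypes(H, pos=[0, 100, 200, 300, 400])
        c = ehhs(h, 2, truncation=0.0)
        p_ref, v_ref = ehhs_bruteforce(h, 2, truncation=0.0)
        np.testing.assert_array_equal(c.positions, p_ref)
        np.testing.assert_allclose(c.values, v_ref, atol=1e-12)

    def test_monomorphic_focal_is_error(self):
        h = make_haplotypes([[0, 0], [0, 1], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic|MAF"):
            ehhs(h, 0)

    def test_invariant_under_row_permutation_and_relabeling(self):
        rng = np.random.default_rng(8)
        h = random_haps(rng)
        c = ehhs(h, 10)
        perm = rng.permutation(h.n_haplotypes)
        h2 = make_haplotypes(h.haplotypes[perm], pos=h.positions)
        c2 = ehhs(h2, 10)
        H3 = np.where(h.haplotypes >= 0, 1 - h.haplotypes, -1)
        h3 = make_haplotypes(H3, pos=h.positions)
        c3 = ehhs(h3, 10)
        np.testing.assert_allclose(c.values, c2.values, atol=1e-12)
        np.testing.assert_allclose(c.values, c3.values, atol=1e-12)

    def test_curve_non_increasing_from_focal(self):
        rng = np.random.default_rng(9)
        h = random_haps(rng)
        c = ehhs(h, 10, truncation=0.0)
        zero = int(np.searchsorted(c.positions, 0))
        right = c.values[zero:]
        left = c.values[: zero + 1][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)


class TestIes:
    def test_rectangle(self):
        c = EhhCurve(0, np.array([-5000.0, 0.0, 5000.0]), np.array([1.0, 1.0, 1.0]))
        assert ies(c) == pytest.approx(10_000.0)

    def test_single_point_is_zero(self):
        c = EhhCurve(0, np.array([0.0]), np.array([1.0]))
        assert ies(c) == 0.0

    def test_piecewise_linear_hand_sum(self):
        # right flank: (0,1) -> (1000,0.5) -> (3000,0.25)
        c = EhhCurve(
            0,
            np.array([0.0, 1000.0, 3000.0]),
            np.array([1.0, 0.5, 0.25]),
        )
        expected = (1 + 0.5) / 2 * 1000 + (0.5 + 0.25) / 2 * 2000
        assert ies(c) == pytest.approx(expected)

    def test_mismatch_reduces_ies(self):
        row = [0, 1, 0, 1, 1, 0, 1, 0]
        H = [row] * 6
        h = make_haplotypes(H)
        base = ies(ehhs(h, 3, maf_min=0.0))
        H2 = [list(r) for r in H]
        H2[0][6] = 1 - H2[0][6]  # break right-flank homozygosity
        h2 = make_haplotypes(H2)
        assert ies(ehhs(h2, 3, maf_min=0.0)) < base


def _strata_pair(seed=10, n=16, L=30):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(300_000, size=L, replace=False))
    mk = lambda: make_haplotypes(
        np.clip(rng.integers(0, 2, size=(n, L)), 0, 1).astype(np.int8), pos=pos
    )
    return mk(), mk()


class TestRsb:
    def test_identical_strata_give_zero_raw(self):
        pre, post = _strata_pair()
        same = make_haplotypes(pre.haplotypes.copy(), pos=pre.positions, stratum="post")
        t = rsb_table(pre, same)
        assert len(t) > 0
        np.testing.assert_allclose(t["rsb_raw"], 0.0, atol=1e-12)

    def test_standardized_median_is_zero(self):
        pre, post = _strata_pair()
        t = rsb(pre, post)
        assert np.median(t["rsb_std"]) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        pre, post = _strata_pair(seed=11)
        t1 = rsb_table(pre, post)
        t2 = rsb_table(post, pre)
        merged = t1.merge(t2, on="snp_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(
            merged["rsb_raw_f"], -merged["rsb_raw_r"], atol=1e-12
        )

    def test_post_sweep_sits_in_lower_tail(self):
        # post stratum: one haplotype swept to high frequency around the mid SNPs
        rng = np.random.default_rng(12)
        L = 40
        pos = np.arange(L) * 5000
        pre_H = rng.integers(0, 2, size=(20, L)).astype(np.int8)
        pre_H[:10, L // 2] = 0
        pre_H[10:, L // 2] = 1
        core = slice(L // 4, 3 * L // 4)
        sweep_core = pre_H[0, core].copy()
        post_H = rng.integers(0, 2, size=(20, L)).astype(np.int8)
        post_H[:10, L // 2] = 0
        post_H[10:, L // 2] = 1
        post_H[:14, core] = sweep_core  # 70% share one haplotype over the core only
        post_H[:14, L // 2] = post_H[0, L // 2]
        pre = make_haplotypes(pre_H, pos=pos, stratum="pre")
        post = make_haplotypes(post_H, pos=pos, stratum="post")
        t = rsb(pre, post)
        mid = t[(t["pos"] > pos[L // 4]) & (t["pos"] < pos[3 * L // 4])]
        assert mid["rsb_std"].median() < t["rsb_std"].median()


def test_ehhs_matches_bruteforce_randomized():
    rng = np.random.default_rng(13)
    for _ in range(5):
        h = random_haps(rng, n=10, L=16, missing=0.15)
        focal = 8
        c = ehhs(h, focal)
        p_ref, v_ref = ehhs_bruteforce(h, focal)
        np.testing.assert_array_equal(c.positions, p_ref)
        np.testing.assert_allclose(c.values, v_ref, atol=1e-12)
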