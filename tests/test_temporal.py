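import numpy as np
import pytest

from devilscan.io import Interval
from devilscan.temporal import (
    SelectionFit,
    TrajectoryData,
    estimate_s,
    jorde_ryman_ne,
    jorde_ryman_ne_from_counts,
    region_mean_s,
    simulate_trajectory,
    trajectories_from_genotypes,
    wf_loglikelihood,
    wf_loglikelihood_bruteforce,
    wf_transition_matrix,
)
from conftest import make_table


class TestTransitionMatrix:
    def test_rows_sum_to_one_with_absorbing_states(self):
        T = wf_transition_matrix(20, 0.3)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T[0, 0] == 1.0 and T[-1, -1] == 1.0

    def test_ne_cap(self):
        with pytest.raises(ValueError):
            wf_transition_matrix(501, 0.0)


class TestWfLikelihood:
    def test_matches_exhaustive_path_enumeration(self):
        traj = TrajectoryData("t", [0, 1, 3], [1, 2, 3], [4, 6, 4])
        for s in (0.0, 0.25, 0.8, -0.3):
            assert wf_loglikelihood(traj, s, 2) == pytest.approx(
                wf_loglikelihood_bruteforce(traj, s, 2), abs=1e-12
            )

    def test_neutral_fits_static_data_better(self):
        traj = TrajectoryData("t", [0, 2, 4], [50, 50, 50], [100, 100, 100])
        assert wf_loglikelihood(traj, 0.0, 30) > wf_loglikelihood(traj, 0.5, 30)

    def test_single_time_point_is_flat(self):
        traj = TrajectoryData("t", [0], [5], [20])
        vals = {wf_loglikelihood(traj, s, 10) for s in (0.0, 0.3, 1.0)}
        assert max(vals) - min(vals) < 1e-12

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryData("t", [0, 1], [5, 30], [10, 20])


class TestEstimateS:
    def test_rising_frequencies_give_positive_mle(self):
        traj = TrajectoryData("t", [0, 2, 4, 6], [4, 12, 24, 34], [40, 40, 40, 40])
        fit = estimate_s(traj, 30)
        assert fit.s_hat > 0
        assert fit.ci_low <= fit.s_hat <= fit.ci_high

    def test_deterministic_given_identical_inputs(self):
        traj = TrajectoryData("t", [0, 3, 6], [8, 14, 22], [40, 40, 40])
        f1 = estimate_s(traj, 30)
        f2 = estimate_s(traj, 30)
        assert f1.s_hat == f2.s_hat and f1.ci_low == f2.ci_low

    def test_boundary_warns_and_censors(self):
        traj = TrajectoryData("t", [0, 2], [0, 40], [40, 40])
        with pytest.warns(UserWarning, match="censored"):
            fit = estimate_s(traj, 20, s_max=0.5)
        assert fit.at_boundary and fit.ci_high == 0.5


class TestRegionMeanS:
    pos = {"a": ("s1", 10), "b": ("s1", 20), "c": ("s2", 10)}

    def fit(self, snp, s):
        return SelectionFit(snp, s, s - 0.1, s + 0.1, 0.0, 30)

    def test_single_snp_region(self):
        out = region_mean_s([self.fit("a", 0.3)], self.pos, Interval("s1", 0, 100))
        assert out["mean_s"] == pytest.approx(0.3) and out["n_snps"] == 1

    def test_mean_of_two(self):
        fits = [self.fit("a", 0.1), self.fit("b", 0.3), self.fit("c", 0.9)]
        out = region_mean_s(fits, self.pos, Interval("s1", 0, 100))
        assert out["mean_s"] == pytest.approx(0.2)
        assert out["min_s"] == pytest.approx(0.1) and out["max_s"] == pytest.approx(0.3)

    def test_empty_region_missing(self):
        out = region_mean_s([self.fit("a", 0.3)], self.pos, Interval("s3", 0, 100))
        assert out["n_snps"] == 0 and np.isnan(out["mean_s"])


def test_increasing_allele_polarisation_is_label_symmetric():
    calls = np.array(
        [[0, 2], [0, 2], [1, 2], [0, 2],  # year 2000
         [2, 0], [2, 0], [2, 1], [1, 0]]  # year 2004
    )
    g = make_table(calls, years=[2000] * 4 + [2004] * 4)
    trajs = trajectories_from_genotypes(g, "P", increasing_allele=True)
    # flip labels of SNP 0: polarised counts must be unchanged
    flipped = g.subset_snps(np.arange(2))
    flipped.a1 = np.where(flipped.a1 >= 0, 1 - flipped.a1, -1).astype(np.int8)
    flipped.a2 = np.where(flipped.a2 >= 0, 1 - flipped.a2, -1).astype(np.int8)
    trajs_f = trajectories_from_genotypes(flipped, "P", increasing_allele=True)
    for t1, t2 in zip(trajs, trajs_f):
        np.testing.assert_array_equal(t1.alt_counts, t2.alt_counts)
        np.testing.assert_array_equal(t1.totals, t2.totals)


class TestJordeRyman:
    def test_no_change_gives_infinite_ne(self):
        n = np.full(50, 60)
        alt = np.tile(np.arange(10, 35, dtype=int), 2)
        with pytest.warns(UserWarning, match="infinite|drift"):
            est = jorde_ryman_ne_from_counts(alt, n, alt, n, t=4)
        assert np.isinf(est.ne_hat)

    def test_from_genotype_table(self):
        rng = np.random.default_rng(16)
        calls = rng.choice([0, 1, 2], size=(40, 300))
        g = make_table(calls, years=[2000] * 20 + [2008] * 20)
        est = jorde_ryman_ne(g, "P", [2000], [2008])
        assert est.ne_hat > 0 and est.n_loci > 100
        assert est.ci_low <= est.ne_hat <= est.ci_high

    def test_jackknife_ci_tightens_with_more_loci(self):
        from devilscan.temporal import ne_recovery_benchmark

        widths = []
        for n_loci in (500, 5000):
            df = ne_recovery_benchmark(
                true_ne=35, t=4, n_loci=n_loci, n_replicates=12, seed=17
            )
            widths.append((df["ci_high"] - df["ci_low"]).median())
        assert widths[1] < widths[0]


def test_simulated_trajectory_shapes_and_bounds():
    rng = np.random.default_rng(18)
    traj = simulate_trajectory(30, 0.4, 0.2, [0, 3, 6], 40, rng)
    assert traj.generations.tolist() == [0, 3, 6]
    assert np.all(traj.alt_counts <= traj.totals)
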