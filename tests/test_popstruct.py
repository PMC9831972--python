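"""Hudson F_ST, permutation significance, Mantel and IBD fits."""

import itertools

import numpy as np
import pytest

from reefpop.coalsim import DemographicModel, simulate_two_deme_counts
from reefpop.errors import DegenerateInputError, DimensionError, UndefinedStatisticError
from reefpop.popstruct import (
    fst_perm_test,
    hudson_fst,
    hudson_fst_from_counts,
    ibd_fit,
    mantel,
    nei_fst,
    pairwise_fst_matrix,
)


def brute_force_hudson(HA, HB):
    """Explicit double loops over haplotype pairs."""
    def mean_pairwise(X, Y, within):
        tot, cnt = 0, 0
        for i in range(len(X)):
            for j in range(len(Y)):
                if within and j <= i:
                    continue
                tot += int((X[i] != Y[j]).sum())
                cnt += 1
        return tot / cnt

    hw = (mean_pairwise(HA, HA, True) + mean_pairwise(HB, HB, True)) / 2
    hb = mean_pairwise(HA, HB, False)
    return 1 - hw / hb


class TestHudsonFst:
    def test_hand_enumeration_two_sites(self):
        HA = np.array([[0, 0], [0, 1]])
        HB = np.array([[1, 1], [1, 0]])
        assert hudson_fst(HA, HB) == pytest.approx(1 / 3, abs=1e-15)

    def test_fixed_difference_is_one(self):
        HA = np.ones((4, 1), dtype=int)
        HB = np.zeros((4, 1), dtype=int)
        assert hudson_fst(HA, HB) == pytest.approx(1.0)

    def test_identical_frequency_pops_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=500)
        HA = (rng.random((20, 500)) < p).astype(int)
        HB = (rng.random((20, 500)) < p).astype(int)
        assert abs(hudson_fst(HA, HB)) < 0.05

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            nA = int(rng.integers(2, 11))
            nB = int(rng.integers(2, 11))
            m = int(rng.integers(1, 21))
            HA = rng.integers(0, 2, (nA, m))
            HB = rng.integers(0, 2, (nB, m))
            try:
                got = hudson_fst(HA, HB)
            except UndefinedStatisticError:
                continue
            assert got == pytest.approx(brute_force_hudson(HA, HB), abs=1e-12)

    def test_counts_path_matches_matrix_path(self):
        rng = np.random.default_rng(2)
        HA = rng.integers(0, 2, (8, 30))
        HB = rng.integers(0, 2, (6, 30))
        got = hudson_fst_from_counts(HA.sum(0), HB.sum(0), 8, 6)
        assert got == pytest.approx(hudson_fst(HA, HB), abs=1e-12)

    def test_monomorphic_rejected(self):
        Z = np.zeros((3, 4), dtype=int)
        with pytest.raises(UndefinedStatisticError):
            hudson_fst(Z, Z)

    def test_nei_alternative_agrees_on_fixed_difference(self):
        HA = np.ones((4, 1), dtype=int)
        HB = np.zeros((4, 1), dtype=int)
        assert nei_fst(HA, HB) == pytest.approx(1.0)


class TestFstPermutation:
    def test_fixed_difference_reaches_p_floor(self):
        # a fixed difference plus within-population noise: only the original
        # split (or its mirror) reproduces F_obs, so p hits the floor
        rng = np.random.default_rng(12)
        HA = rng.integers(0, 2, (16, 40))
        HB = rng.integers(0, 2, (16, 40))
        HA = np.hstack([HA, np.ones((16, 10), dtype=int)])
        HB = np.hstack([HB, np.zeros((16, 10), dtype=int)])
        res = fst_perm_test(HA, HB, n_perm=200, rng=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_tiny_case_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        HA = rng.integers(0, 2, (4, 12))  # 2 diploids
        HB = rng.integers(0, 2, (4, 12))
        obs = hudson_fst(HA, HB)
        pooled = np.vstack([HA, HB])
        count = total = 0
        for combo in itertools.permutations(range(4)):
            rows = np.column_stack([2 * np.array(combo), 2 * np.array(combo) + 1]).ravel()
            P = pooled[rows]
            total += 1
            if hudson_fst(P[:4], P[4:]) >= obs:
                count += 1
        exact = count / total
        res = fst_perm_test(HA, HB, n_perm=4000, rng=7)
        # permutation p converges to the exhaustive fraction
        assert res.p_value == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / 4000) + 1e-3)

    def test_null_calibration_under_panmixia(self):
        """Rejection rate at alpha=0.05 within the exact binomial 99% band
        when both samples come from one panmictic population."""
        from scipy.stats import binom

        rng = np.random.default_rng(11)
        runs, rej = 220, 0
        for _ in range(runs):
            p = rng.uniform(0.05, 0.95, size=120)
            pool = (rng.random((24, 120)) < p).astype(int)
            res = fst_perm_test(pool[:12], pool[12:], n_perm=199, rng=rng)
            if res.p_value < 0.05:
                rej += 1
        assert binom.ppf(0.005, runs, 0.05) <= rej <= binom.ppf(0.995, runs, 0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        HA = rng.integers(0, 2, (6, 20))
        HB = rng.integers(0, 2, (6, 20))
        a = fst_perm_test(HA, HB, n_perm=100, rng=5).p_value
        b = fst_perm_test(HA, HB, n_perm=100, rng=5).p_value
        assert a == b


class TestPairwiseMatrix:
    def test_identical_pops_near_zero_and_symmetry(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 300)
        pops = [(rng.random((16, 300)) < p).astype(int) for _ in range(3)]
        F, overall = pairwise_fst_matrix(pops)
        assert np.allclose(F, F.T)
        assert np.all(np.diag(F) == 0)
        assert np.all(np.abs(F[np.triu_indices(3, 1)]) < 0.05)
        assert abs(overall) < 0.05

    def test_stepping_stone_distance_monotonicity(self):
        """F_ST grows with lattice separation in a 1-row stepping stone."""
        sst = DemographicModel(kind="SST", grid=(1, 10), N=300, m=5e-3,
                               T_col=1e6, N_anc=3000, mu=2e-6)
        f12, f13 = [], []
        for i in range(50):
            cA, cB, nA, nB = simulate_two_deme_counts(sst, (0, 0), (0, 2), 8, n_loci=30, rng=i)
            f12.append(hudson_fst_from_counts(cA, cB, nA, nB))
            cA, cB, nA, nB = simulate_two_deme_counts(sst, (0, 0), (0, 8), 8, n_loci=30,
                                                      rng=10_000 + i)
            f13.append(hudson_fst_from_counts(cA, cB, nA, nB))
        assert np.mean(f13) > np.mean(f12)


class TestMantel:
    @staticmethod
    def random_distance_matrix(rng, n):
        M = rng.random((n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        return M

    def test_affine_identity(self):
        rng = np.random.default_rng(6)
        A = self.random_distance_matrix(rng, 8)
        res = mantel(A, 2 * A + 3, n_perm=500, rng=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 501)

    def test_4x4_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        A = self.random_distance_matrix(rng, 4)
        B = self.random_distance_matrix(rng, 4)
        iu = np.tril_indices(4, -1)
        a = A[iu]
        r_obs = np.corrcoef(a, B[iu])[0, 1]
        count = total = 0
        for perm in itertools.permutations(range(4)):
            bp = B[np.ix_(perm, perm)][iu]
            total += 1
            if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
                count += 1
        exact = count / total
        res = mantel(A, B, n_perm=5000, rng=1)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_type_one_error_calibration(self):
        from scipy.stats import binom

        rng = np.random.default_rng(8)
        runs, rej = 300, 0
        for _ in range(runs):
            A = self.random_distance_matrix(rng, 10)
            B = self.random_distance_matrix(rng, 10)
            if mantel(A, B, n_perm=199, rng=rng).p_value < 0.05:
                rej += 1
        assert binom.ppf(0.005, runs, 0.05) <= rej <= binom.ppf(0.995, runs, 0.05)

    def test_constant_matrix_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(DegenerateInputError):
            mantel(A, A, n_perm=10, rng=0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            mantel(np.zeros((4, 4)), np.zeros((5, 5)), n_perm=10, rng=0)


class TestIBD:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(9)
        D = TestMantel.random_distance_matrix(rng, 6) * 100
        c = 3e-3
        x = c * D
        F = x / (1 + x)
        np.fill_diagonal(F, 0)
        slope, intercept, r = ibd_fit(F, D)
        assert slope == pytest.approx(c, rel=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_slope_scales_inversely_with_distance_units(self):
        rng = np.random.default_rng(10)
        D = TestMantel.random_distance_matrix(rng, 6)
        F = (0.1 * D) / (1 + 0.1 * D)
        np.fill_diagonal(F, 0)
        s1, _, _ = ibd_fit(F, D)
        s2, _, _ = ibd_fit(F, D * 1000)
        assert s2 == pytest.approx(s1 / 1000, rel=1e-9)

    def test_constant_distance_rejected(self):
        F = np.array([[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]])
        D = np.ones((3, 3))
        np.fill_diagonal(D, 0)
        D[:] = 5.0
        with pytest.raises(DegenerateInputError):
            ibd_fit(F, D)
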