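"""Structured-coalescent simulator: closed forms, model reductions and the
fast-kernel / naive-kernel / msprime cross-checks."""

import numpy as np
import pytest

from reefpop.coalsim import (
    DemographicModel,
    SampleSpec,
    drop_mutations,
    simulate_genealogy,
    simulate_sfs,
    simulate_two_deme_counts,
    simulate_two_deme_genotypes,
)
from reefpop.errors import ConfigError
from reefpop.popstruct import hudson_fst, hudson_fst_from_counts
from reefpop.sfs import theta_w


def constant_ns(N: float, mu: float = 1.93e-8) -> DemographicModel:
    return DemographicModel(kind="NS", mu=mu, N_mod=N, N_anc=N, T_c=1e12)


def z_equal(x, y, label=""):
    """Two-sample z-statistic for equality of means."""
    x, y = np.asarray(x), np.asarray(y)
    se = np.sqrt(x.var() / len(x) + y.var() / len(y))
    return (x.mean() - y.mean()) / se


class TestGenealogy:
    def test_single_lineage_has_zero_branch_length(self):
        g = simulate_genealogy(constant_ns(1000), SampleSpec(n_dip=1), rng=0, n_haploid=1)
        assert g.total_branch_length() == 0.0

    def test_pair_tmrca_mean_is_2N(self):
        N, reps = 1000.0, 8000
        tm = np.array([simulate_genealogy(constant_ns(N), SampleSpec(n_dip=1), rng=i).tmrca()
                       for i in range(reps)])
        se = tm.std() / np.sqrt(reps)
        assert abs(tm.mean() - 2 * N) < 3 * se

    def test_total_length_mean_is_4N_harmonic(self):
        N, n, reps = 500.0, 4, 8000
        tot = np.array([
            simulate_genealogy(constant_ns(N), SampleSpec(n_dip=n // 2), rng=i).total_branch_length()
            for i in range(reps)
        ])
        expect = 4 * N * (1 + 1 / 2 + 1 / 3)
        se = tot.std() / np.sqrt(reps)
        assert abs(tot.mean() - expect) < 3 * se

    def test_genealogy_is_ultrametric_with_single_root(self):
        g = simulate_genealogy(constant_ns(100), SampleSpec(n_dip=5), rng=7)
        assert (g.node_times[: g.n] == 0).all()
        assert (g.parent[: g.n_nodes - 1] >= 0).all() and g.parent[g.root] == -1
        assert (g.branch_lengths() >= 0).all()

    def test_deme_required_iff_structured(self):
        with pytest.raises(ConfigError):
            simulate_genealogy(constant_ns(100), SampleSpec(deme=(0, 0), n_dip=2), rng=0)
        sst = DemographicModel(kind="SST", N=100, m=0.01, T_col=1e4, N_anc=100)
        with pytest.raises(ConfigError):
            simulate_genealogy(sst, SampleSpec(deme="panmictic", n_dip=2), rng=0)


class TestMutations:
    def test_zero_rate_zero_sites(self):
        g = simulate_genealogy(constant_ns(1000), SampleSpec(n_dip=5), rng=1)
        assert drop_mutations(g, mu=0.0, rng=0).size == 0

    def test_counts_always_polymorphic_range(self):
        for i in range(30):
            g = simulate_genealogy(constant_ns(2000), SampleSpec(n_dip=4), rng=i)
            counts = drop_mutations(g, mu=1e-5, locus_len=100, rng=i)
            if counts.size:
                assert counts.min() >= 1 and counts.max() <= g.n - 1

    def test_watterson_expectation_of_segsites(self):
        # E[S] = 4 N mu L a_{n-1} per locus, via the batched SFS path
        N, mu, n_dip, n_loci, L = 1000.0, 1e-6, 5, 2000, 100
        sfs = simulate_sfs(constant_ns(N, mu), SampleSpec(n_dip=n_dip),
                           n_loci=n_loci, locus_len=L, rng=5)
        n = 2 * n_dip
        a = sum(1 / i for i in range(1, n))
        expect = 4 * N * mu * L * a * n_loci
        # S is approx Poisson-overdispersed; allow 4 sigma of the naive SE
        assert abs(sfs.S - expect) < 4 * np.sqrt(expect * 3)

    def test_theta_w_calibration(self):
        N, mu = 1000.0, 1.93e-8
        tw = [theta_w(simulate_sfs(constant_ns(N, mu), SampleSpec(n_dip=10),
                                   n_loci=300, rng=i)) for i in range(150)]
        tw = np.array(tw)
        se = tw.std() / np.sqrt(len(tw))
        assert abs(tw.mean() - 4 * N * mu) < 3 * se


class TestReproducibility:
    def test_same_seed_same_sfs(self):
        sst = DemographicModel(kind="SST", N=500, m=5e-3, T_col=1e5, N_anc=2000)
        spec = SampleSpec(deme=(4, 4), n_dip=6)
        a = simulate_sfs(sst, spec, n_loci=50, rng=123)
        b = simulate_sfs(sst, spec, n_loci=50, rng=123)
        np.testing.assert_array_equal(a.eta, b.eta)

    def test_different_seed_differs(self):
        m = constant_ns(5000, mu=1e-6)
        a = simulate_sfs(m, SampleSpec(n_dip=5), n_loci=50, rng=1)
        b = simulate_sfs(m, SampleSpec(n_dip=5), n_loci=50, rng=2)
        assert not np.array_equal(a.eta, b.eta)


class TestModelReductions:
    def test_sst_without_migration_matches_two_epoch_ns(self):
        """SST with m=0: the focal deme is an isolated deme of size N until
        T_col, then the ancestral pool — exactly a two-epoch NS history."""
        N, T, Na, mu = 800.0, 4000.0, 8000.0, 1e-6
        sst = DemographicModel(kind="SST", N=N, m=0.0, T_col=T, N_anc=Na, mu=mu)
        ns = DemographicModel(kind="NS", N_mod=N, N_anc=Na, T_c=T, mu=mu)
        s_sst = [simulate_sfs(sst, SampleSpec(deme=(4, 4), n_dip=5), n_loci=40, rng=i).S
                 for i in range(800)]
        s_ns = [simulate_sfs(ns, SampleSpec(n_dip=5), n_loci=40, rng=10_000 + i).S
                for i in range(800)]
        assert abs(z_equal(s_sst, s_ns)) < 3

    def test_strong_migration_approaches_panmixia(self):
        """SST at Nm=100 behaves like one population of size d*N in mean TMRCA."""
        d, N = 100, 200.0
        sst = DemographicModel(kind="SST", N=N, m=100 / N, T_col=1e12, N_anc=N)
        tm = np.array([simulate_genealogy(sst, SampleSpec(deme=(4, 4), n_dip=1), rng=i).tmrca()
                       for i in range(4000)])
        assert abs(tm.mean() - 2 * d * N) / (2 * d * N) < 0.10

    def test_time_rescaling_invariance(self):
        """Scaling sizes and times by c and mutation/migration rates by 1/c
        leaves the S distribution invariant."""
        base = DemographicModel(kind="SST", N=400, m=4e-3, T_col=3e4, N_anc=4000, mu=2e-6)
        c = 5.0
        scaled = DemographicModel(kind="SST", N=400 * c, m=4e-3 / c, T_col=3e4 * c,
                                  N_anc=4000 * c, mu=2e-6 / c)
        s1 = [simulate_sfs(base, SampleSpec(deme=(4, 4), n_dip=4), n_loci=30, rng=i).S
              for i in range(700)]
        s2 = [simulate_sfs(scaled, SampleSpec(deme=(4, 4), n_dip=4), n_loci=30, rng=50_000 + i).S
              for i in range(700)]
        assert abs(z_equal(s1, s2)) < 3

    def test_exchangeability_of_sampled_lineages(self):
        """Pair TMRCA has the same distribution for any two sampled lineages."""
        sst = DemographicModel(kind="SST", N=300, m=5e-3, T_col=5e4, N_anc=1000)
        t_first, t_last = [], []
        for i in range(2500):
            g = simulate_genealogy(sst, SampleSpec(deme=(4, 4), n_dip=3), rng=i)
            t_first.append(_pair_mrca_time(g, 0, 1))
            t_last.append(_pair_mrca_time(g, 2, 5))
        assert abs(z_equal(t_first, t_last)) < 3


def _pair_mrca_time(g, a, b):
    anc_a = set()
    x = a
    while x != -1:
        anc_a.add(x)
        x = g.parent[x]
    x = b
    while x not in anc_a:
        x = g.parent[x]
    return g.node_times[x]


class TestFastVsNaiveKernels:
    @pytest.mark.parametrize("kind", ["FIM", "SST"])
    def test_fast_and_naive_agree_in_distribution(self, kind):
        mdl = DemographicModel(kind=kind, N=500, m=5e-3, T_col=2e5, N_anc=5000)
        reps = 2500
        out = {}
        for naive in (False, True):
            tm, bl = [], []
            for i in range(reps):
                g = simulate_genealogy(mdl, SampleSpec(deme=(4, 4), n_dip=5),
                                       rng=i + 7, naive=naive)
                tm.append(g.tmrca())
                bl.append(g.total_branch_length())
            out[naive] = (np.array(tm), np.array(bl))
        for a, b in zip(out[False], out[True]):
            assert abs(z_equal(a, b)) < 3.5


class TestTwoDemePaths:
    def test_panmixia_limit_fst_near_zero(self):
        fim = DemographicModel(kind="FIM", N=1000, m=0.5, T_col=1e12, N_anc=1000, mu=1e-6)
        f = []
        for i in range(30):
            cA, cB, nA, nB = simulate_two_deme_counts(fim, (0, 0), (9, 9), 10,
                                                      n_loci=50, rng=i)
            f.append(hudson_fst_from_counts(cA, cB, nA, nB))
        assert abs(np.mean(f)) < 0.02

    def test_isolation_limit_fst_near_one(self):
        fim = DemographicModel(kind="FIM", N=200, m=0.0, T_col=1e7, N_anc=200, mu=1e-6)
        f = []
        for i in range(30):
            cA, cB, nA, nB = simulate_two_deme_counts(fim, (0, 0), (9, 9), 10,
                                                      n_loci=50, rng=i)
            f.append(hudson_fst_from_counts(cA, cB, nA, nB))
        assert np.mean(f) > 0.9

    def test_genotype_and_count_paths_agree_on_fst(self):
        sst = DemographicModel(kind="SST", N=500, m=2e-3, T_col=1e6, N_anc=5000, mu=1e-6)
        f_m, f_c = [], []
        for i in range(60):
            HA, HB = simulate_two_deme_genotypes(sst, (4, 4), (4, 6), 8, n_loci=40, rng=i)
            f_m.append(hudson_fst(HA, HB))
            cA, cB, nA, nB = simulate_two_deme_counts(sst, (4, 4), (4, 6), 8,
                                                      n_loci=40, rng=1000 + i)
            f_c.append(hudson_fst_from_counts(cA, cB, nA, nB))
        assert abs(z_equal(f_m, f_c)) < 3.5

    def test_same_deme_rejected(self):
        sst = DemographicModel(kind="SST", N=100, m=0.01, T_col=1e4, N_anc=100)
        with pytest.raises(ConfigError):
            simulate_two_deme_counts(sst, (1, 1), (1, 1), 5, rng=0)

    def test_deme_outside_grid_rejected(self):
        sst = DemographicModel(kind="SST", N=100, m=0.01, T_col=1e4, N_anc=100)
        with pytest.raises(IndexError):
            simulate_two_deme_counts(sst, (0, 0), (10, 10), 5, rng=0)
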