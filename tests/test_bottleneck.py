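import numpy as np
import pytest

from isopop.bottleneck import (critical_m, het_excess_test, m_ratio,
                               mode_shift, simulate_heq)
from isopop.coalescent import sim_k_het
from isopop.genotype import GenotypeTable, Locus
from isopop.mutation import MutationModel
from isopop.synthetic import (SourceSpec, make_bottlenecked_population,
                              make_source_population)

SMM = MutationModel(kind="SMM")
IAM_LIKE = MutationModel(kind="KAM", n_states=100)


def msprime_equilibrium_table(theta, n_loci, n_individuals, seed):
    """Equilibrium microsatellite data simulated with msprime (independent of
    the package's own coalescent kernel)."""
    import msprime

    model = msprime.SMM(lo=1, hi=400)
    n_genes = 2 * n_individuals
    calls = np.zeros((n_individuals, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        ts = msprime.sim_ancestry(samples=n_individuals, population_size=0.5,
                                  sequence_length=1,
                                  random_seed=seed * 1000 + j + 1)
        mts = msprime.sim_mutations(ts, rate=theta / 2, model=model,
                                    random_seed=seed * 1000 + j + 501)
        if mts.num_sites == 0:
            states = np.full(n_genes, 200)
        else:
            var = next(mts.variants())
            states = np.array([int(var.alleles[g]) for g in var.genotypes])
        calls[:, j, :] = (100 + 2 * states).reshape(n_individuals, 2)
    loci = [Locus(f"L{j}", 2) for j in range(n_loci)]
    return GenotypeTable([f"i{i}" for i in range(n_individuals)],
                         ["eq"] * n_individuals, loci, calls)


class TestCoalescentKernel:
    def test_against_msprime_oracle(self):
        """Mean allele count and heterozygosity of the stepwise coalescent
        match an independent simulator at the same scaled mutation rate."""
        import msprime

        theta, n_genes = 2.0, 30
        model = msprime.SMM(lo=1, hi=200)
        ks, hets = [], []
        for rep in range(400):
            ts = msprime.sim_ancestry(samples=n_genes // 2,
                                      population_size=0.5, sequence_length=1,
                                      random_seed=1 + rep)
            mts = msprime.sim_mutations(ts, rate=theta / 2, model=model,
                                        random_seed=10_000 + rep)
            if mts.num_sites == 0:
                states = np.zeros(n_genes)
            else:
                var = next(mts.variants())
                states = np.array([int(var.alleles[g]) for g in var.genotypes])
            _, counts = np.unique(states, return_counts=True)
            p = counts / counts.sum()
            ks.append(len(counts))
            hets.append(n_genes / (n_genes - 1) * (1 - np.sum(p**2)))
        k2, h2 = sim_k_het(3000, n_genes, theta, 0.0, 1.0, False, 123)
        assert k2.mean() == pytest.approx(np.mean(ks), rel=0.07)
        assert h2.mean() == pytest.approx(np.mean(hets), rel=0.07)
        # and both sit near the stepwise equilibrium 1 - 1/sqrt(1 + 2 theta)
        assert h2.mean() == pytest.approx(1 - 1 / np.sqrt(1 + 2 * theta),
                                          rel=0.07)


class TestSimulateHeq:
    def test_two_allele_bound(self):
        heq = simulate_heq(20, 2, SMM, reps=400, seed=1)
        assert 0.0 < heq.mean() <= 0.53

    def test_all_distinct_alleles_saturate_heterozygosity(self):
        heq = simulate_heq(8, 8, IAM_LIKE, reps=200, seed=2)
        assert heq.mean() > 0.9

    def test_smm_exceeds_iam_at_equal_allele_count(self):
        """Reaching the same allele count needs more mutations under a
        stepwise model (homoplasy), so the conditional equilibrium
        heterozygosity is higher under SMM than under an infinite-alleles
        process - which is why stepwise nulls make the excess test
        conservative."""
        h_smm = simulate_heq(100, 5, SMM, reps=400, seed=3).mean()
        h_iam = simulate_heq(100, 5, IAM_LIKE, reps=400, seed=3).mean()
        assert h_smm > h_iam

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            simulate_heq(10, 1, SMM)


class TestHetExcess:
    def test_type_one_error_calibrated(self):
        """On equilibrium data the excess probability is ~ uniform: the
        rejection rate at 0.05 stays near its nominal level."""
        ps = []
        for seed in range(40):
            t = msprime_equilibrium_table(1.5, 10, 30, seed=seed + 1)
            try:
                rep = het_excess_test(t, "eq", SMM, reps=250, seed=seed)
            except ValueError:  # too many monomorphic loci in this draw
                continue
            ps.append(rep.wilcoxon_p_excess)
        assert len(ps) >= 30
        assert np.mean(np.array(ps) < 0.05) <= 0.15
        assert 0.3 <= np.mean(ps) <= 0.75

    def test_power_on_recent_bottleneck(self):
        """A severe recent crash produces a detectable heterozygosity excess
        under an infinite-alleles-like null in most replicates."""
        hits = []
        for seed in range(8):
            spec = SourceSpec(n_individuals=500, n_loci=14,
                              n_allelic_states=11, target_he=0.81, seed=seed)
            t = make_bottlenecked_population(spec, 0.05, 2)
            rep = het_excess_test(t, "crashed", IAM_LIKE, reps=250, seed=seed)
            hits.append(rep.wilcoxon_p_excess < 0.05)
        assert np.mean(hits) > 0.5

    def test_report_is_consistent(self):
        t = msprime_equilibrium_table(1.5, 8, 30, seed=99)
        rep = het_excess_test(t, "eq", SMM, reps=200, seed=5)
        assert rep.n_deficiency + rep.n_excess <= len(rep.loci)
        assert 0.0 <= rep.wilcoxon_p_excess <= 1.0
        assert rep.standardized.shape == rep.he_observed.shape

    def test_equilibrium_spectrum_shows_no_mode_shift(self):
        t = make_source_population(
            SourceSpec(n_individuals=300, n_loci=14, seed=4))
        assert not mode_shift(t, "source")


class TestMRatio:
    def test_hand_example(self):
        calls = np.array([[[120, 124]], [[124, 126]]])
        t = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 2)], calls)
        res = m_ratio(t, "p")
        assert res.k[0] == 3 and res.r[0] == 4
        assert res.m_per_locus[0] == pytest.approx(0.75)

    def test_gapless_locus_has_m_one(self):
        calls = np.array([[[100, 102]], [[104, 102]]])
        t = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 2)], calls)
        assert m_ratio(t, "p").m_per_locus[0] == 1.0

    def test_monomorphic_included_as_one_with_warning(self):
        calls = np.full((3, 1, 2), 100)
        t = GenotypeTable(list("abc"), ["p"] * 3, [Locus("L", 2)], calls)
        with pytest.warns(UserWarning, match="monomorphic"):
            res = m_ratio(t, "p")
        assert res.mean_m == 1.0

    def test_invariant_under_size_shift_and_motif_rescale(self):
        calls = np.array([[[120, 124]], [[124, 130]]])
        t = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 2)], calls)
        shifted = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 2)],
                                calls + 10)
        rescaled = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 3)],
                                 (calls - 120) // 2 * 3 + 120)
        base = m_ratio(t, "p").mean_m
        assert m_ratio(shifted, "p").mean_m == base
        assert m_ratio(rescaled, "p").mean_m == base


class TestCriticalM:
    def test_mc_monotone_in_multistep_parameters(self):
        mc_base, _ = critical_m(0.176, 278, 14, 3.1, 0.1, reps=2000, seed=1)
        mc_pg, _ = critical_m(0.176, 278, 14, 3.1, 0.2, reps=2000, seed=1)
        mc_dg, _ = critical_m(0.176, 278, 14, 3.5, 0.1, reps=2000, seed=1)
        assert mc_pg < mc_base
        assert mc_dg < mc_base

    def test_observed_m_of_one_is_never_extreme(self):
        _, p = critical_m(0.176, 100, 10, 3.1, 0.1, reps=1000, seed=2,
                          observed_m=1.0)
        assert p > 0.95

    def test_depauperate_m_is_extreme(self):
        _, p = critical_m(0.176, 278, 14, 3.1, 0.1, reps=2000, seed=3,
                          observed_m=0.699)
        assert p < 0.01

    @pytest.mark.parametrize("kwargs", [
        {"theta": 1e-6}, {"delta_g": 1.5}, {"reps": 100},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        args = {"theta": 0.176, "n_genes": 50, "n_loci": 5,
                "delta_g": 3.1, "p_g": 0.1, "reps": 1000}
        args.update(kwargs)
        with pytest.raises(ValueError):
            critical_m(**args)
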