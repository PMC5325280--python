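import numpy as np
import pytest

from isopop.genotype import GenotypeTable, Locus
from isopop.sumstats import (UndefinedStatistic, allelic_richness,
                             bootstrap_ci, fis, heterozygosities, jost_d,
                             mean_relatedness, pairwise_fst)
from isopop.synthetic import SourceSpec, make_source_population

from . import oracles
from .conftest import random_table


class TestHeterozygosities:
    def test_hand_example(self, tiny_table):
        ho, he, ho_m, he_m = heterozygosities(tiny_table, "pop1")
        assert ho_m == 0.5
        assert he_m == pytest.approx((4 / 3) * (1 - 0.75**2 - 0.25**2))

    def test_monomorphic_population(self):
        calls = np.full((3, 2, 2), 100)
        t = GenotypeTable(list("abc"), ["p"] * 3,
                          [Locus("L1"), Locus("L2")], calls)
        _, _, ho, he = heterozygosities(t, "p")
        assert ho == he == 0.0


class TestAllelicRichness:
    def test_combinatorial_hand_example(self):
        # allele counts {A: 2, B: 2}, g = 2 -> 2 * (1 - C(2,2)/C(4,2)) = 5/3
        calls = np.array([[[100, 100]], [[102, 102]]])
        t = GenotypeTable(["a", "b"], ["p", "p"], [Locus("L", 2)], calls)
        na, _ = allelic_richness(t, "p", g=2)
        assert na[0] == pytest.approx(5 / 3)

    def test_full_sample_gives_observed_count(self, tiny_table):
        na, _ = allelic_richness(tiny_table, "pop1", g=4)
        assert na[0] == pytest.approx(2.0)

    def test_monomorphic_is_one(self):
        calls = np.full((4, 1, 2), 100)
        t = GenotypeTable(list("abcd"), ["p"] * 4, [Locus("L")], calls)
        for g in (2, 4, 8):
            na, _ = allelic_richness(t, "p", g=g)
            assert na[0] == 1.0

    def test_monotone_in_g(self):
        t = random_table(np.random.default_rng(5), missing_rate=0.0)
        last = 0.0
        for g in (2, 4, 8):
            _, na = allelic_richness(t, "p1", g=g)
            assert na >= last - 1e-12
            last = na

    def test_g_too_large_rejected(self, tiny_table):
        with pytest.raises(UndefinedStatistic):
            allelic_richness(tiny_table, "pop1", g=99)


class TestDifferentiation:
    def test_fixed_difference_limits(self, two_pop_table):
        # locus 1 alone is a fixed difference
        sub = GenotypeTable(two_pop_table.individuals,
                            two_pop_table.populations,
                            two_pop_table.loci[:1],
                            two_pop_table.calls[:, :1, :])
        assert pairwise_fst(sub, "A", "B") == pytest.approx(1.0)
        assert jost_d(sub, "A", "B") == pytest.approx(1.0, abs=1e-9)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([100, 102, 104], size=(200, 5, 2))
        pops = ["A"] * 100 + ["B"] * 100
        t = GenotypeTable([f"i{i}" for i in range(200)], pops,
                          [Locus(f"L{j}", 2) for j in range(5)], calls)
        assert abs(pairwise_fst(t, "A", "B")) < 0.01
        assert abs(jost_d(t, "A", "B")) < 0.02

    def test_panmictic_null(self):
        """Two samples from one synthetic panmictic population give FST ~ 0."""
        t = make_source_population(
            SourceSpec(n_individuals=400, n_loci=14, seed=4))
        pops = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        t2 = GenotypeTable(t.individuals, pops, t.loci, t.calls)
        assert -0.01 <= pairwise_fst(t2, "A", "B") <= 0.01

    def test_no_shared_polymorphic_locus(self):
        calls = np.full((4, 1, 2), 100)
        t = GenotypeTable(list("abcd"), ["A", "A", "B", "B"],
                          [Locus("L")], calls)
        with pytest.raises(UndefinedStatistic):
            pairwise_fst(t, "A", "B")


class TestFis:
    def test_all_homozygous_polymorphic_gives_one(self):
        calls = np.array([[[100, 100]], [[102, 102]], [[100, 100]]])
        t = GenotypeTable(list("abc"), ["p"] * 3, [Locus("L", 2)], calls)
        assert fis(t, "p", "nei") == pytest.approx(1.0)
        assert fis(t, "p", "weir") == pytest.approx(1.0)

    def test_hwe_null_both_methods(self):
        t = make_source_population(
            SourceSpec(n_individuals=500, n_loci=14, seed=21))
        for method in ("nei", "weir"):
            assert abs(fis(t, "source", method)) < 0.05


class TestRelatedness:
    def test_unrelated_hwe_individuals_near_zero(self):
        t = make_source_population(
            SourceSpec(n_individuals=200, n_loci=14, seed=8))
        assert -0.05 <= mean_relatedness(t, "source") <= 0.05

    def test_identical_genotypes_near_one(self):
        rng = np.random.default_rng(3)
        base = rng.choice([100, 102, 104, 106], size=(1, 10, 2))
        background = rng.choice([100, 102, 104, 106], size=(30, 10, 2))
        calls = np.concatenate([base, base, background])
        t = GenotypeTable([f"i{i}" for i in range(32)], ["p"] * 32,
                          [Locus(f"L{j}", 2) for j in range(10)], calls)
        from isopop.sumstats import relatedness_matrix

        r = relatedness_matrix(t, "p")
        assert r[0] > 0.8  # the twin pair is the first condensed entry

    def test_single_individual_undefined(self):
        calls = np.array([[[100, 102]]])
        t = GenotypeTable(["a"], ["p"], [Locus("L", 2)], calls)
        with pytest.raises(UndefinedStatistic):
            mean_relatedness(t, "p")


@pytest.mark.parametrize("seed", range(6))
def test_brute_force_oracle_equivalence(seed):
    """All eight indices agree with naive loop implementations on small tables."""
    rng = np.random.default_rng(1000 + seed)
    t = random_table(rng, n_individuals=10, n_loci=3, missing_rate=0.08)

    ho, he, _, _ = heterozygosities(t, "p1")
    j_used = [j for j in range(3)]
    for out_j, j in enumerate(j_used):
        assert ho[out_j] == pytest.approx(oracles.obs_het(t, "p1", j))
        assert he[out_j] == pytest.approx(oracles.exp_het_unbiased(t, "p1", j))

    na, _ = allelic_richness(t, "p1", g=3)
    for out_j, j in enumerate(j_used):
        assert na[out_j] == pytest.approx(oracles.rarefied_na(t, "p1", j, 3))

    assert pairwise_fst(t, "p1", "p2") == pytest.approx(
        oracles.wc_fst(t, "p1", "p2"))
    assert jost_d(t, "p1", "p2") == pytest.approx(
        oracles.jost_d(t, "p1", "p2"))
    assert fis(t, "p1", "nei") == pytest.approx(oracles.fis_nei(t, "p1"))
    assert mean_relatedness(t, "p1") == pytest.approx(
        oracles.qg_relatedness_mean(t, "p1"))


class TestBootstrap:
    def test_constant_statistic_zero_width(self, two_pop_table):
        ci = bootstrap_ci(lambda _t: 0.5, two_pop_table, reps=200, seed=1)
        assert ci.lower == ci.upper == 0.5

    @pytest.mark.parametrize("seed", range(3))
    def test_ci_contains_point_estimate(self, seed):
        t = random_table(np.random.default_rng(50 + seed),
                         n_individuals=12, n_loci=6, missing_rate=0.0)
        ci = bootstrap_ci(lambda x: pairwise_fst(x, "p1", "p2"), t,
                          reps=300, seed=seed)
        assert ci.lower <= ci.point <= ci.upper

    def test_deterministic_under_seed(self, two_pop_table):
        f = lambda x: pairwise_fst(x, "A", "B")  # noqa: E731
        a = bootstrap_ci(f, two_pop_table, reps=200, seed=9)
        b = bootstrap_ci(f, two_pop_table, reps=200, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_too_few_reps_rejected(self, two_pop_table):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda _t: 0.0, two_pop_table, reps=10, seed=0)
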