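"""Diversity and F-statistics: hand-computed values, oracle equivalence,
invariances, and permutation-null behaviour."""

import numpy as np
import pytest

from tempsel.datatypes import GenotypeSample, Locus
from tempsel.popgen import (
    PopgenError,
    allele_frequencies,
    heterozygosities,
    locus_summaries,
    pairwise_fst,
    permutation_test_fis,
    permutation_test_fst,
    wc_f_statistics,
)

from .conftest import make_sample
from .oracles import anova_f_statistics, random_genotype_dataset


def pops_to_samples(pops):
    return [
        make_sample(pop, site=f"p{i}", year=i) for i, pop in enumerate(pops)
    ]


class TestAlleleFrequencies:
    def test_fixed_locus(self):
        s = make_sample([("A", "A")] * 4)
        assert allele_frequencies(s, "L1") == {"A": 1.0}

    def test_three_genotypes_half_half(self):
        s = make_sample([("A", "A"), ("A", "B"), ("B", "B")])
        assert allele_frequencies(s, "L1") == {"A": 0.5, "B": 0.5}

    def test_missing_dropped_and_all_missing_errors(self):
        s = make_sample([("A", "B"), None, None])
        assert allele_frequencies(s, "L1") == {"A": 0.5, "B": 0.5}
        with pytest.raises(PopgenError, match="no typed"):
            allele_frequencies(make_sample([None, None]), "L1")

    def test_sums_to_one(self, rng):
        for _ in range(20):
            genos = [
                tuple(sorted(rng.choice(["A", "B", "C", "D"], 2))) for _ in range(15)
            ]
            freqs = allele_frequencies(make_sample(genos), "L1")
            assert abs(sum(freqs.values()) - 1.0) < 1e-12


class TestHeterozygosities:
    def test_monomorphic_is_zero_zero(self):
        assert heterozygosities(make_sample([("A", "A")] * 5), "L1") == (0.0, 0.0)

    def test_two_heterozygotes(self):
        ho, he = heterozygosities(make_sample([("A", "B"), ("A", "B")]), "L1")
        assert ho == 1.0
        assert he == pytest.approx(2 / 3, abs=1e-12)

    def test_one_het_of_four(self):
        genos = [("A", "A")] * 3 + [("A", "B")]
        ho, he = heterozygosities(make_sample(genos), "L1")
        assert ho == 0.25
        assert he == pytest.approx(0.25, abs=1e-12)

    def test_requires_two_individuals(self):
        with pytest.raises(PopgenError):
            heterozygosities(make_sample([("A", "B")]), "L1")


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        a = make_sample([("A", "A")] * 6, site="a")
        b = make_sample([("B", "B")] * 6, site="b", year=1)
        assert wc_f_statistics([a, b]).theta == pytest.approx(1.0)

    def test_f_at_exact_hwe_counts_small_sample(self):
        # 1 AA, 2 AB, 1 BB: the small-sample WC f is 1/7, not 0 —
        # the unbiased expected heterozygosity exceeds the observed 0.5
        pops = [[("A", "A"), ("A", "B"), ("A", "B"), ("B", "B")]]
        stats = wc_f_statistics(pops_to_samples(pops))
        f_oracle, _ = anova_f_statistics(pops)
        assert stats.f == pytest.approx(1 / 7, abs=1e-12)
        assert stats.f == pytest.approx(f_oracle, abs=1e-12)

    def test_matches_anova_oracle_on_random_data(self, rng):
        for _ in range(40):
            pops = random_genotype_dataset(rng)
            f_o, t_o = anova_f_statistics(pops)
            stats = wc_f_statistics(pops_to_samples(pops))
            if f_o is not None:
                assert stats.f == pytest.approx(f_o, abs=1e-10)
            if t_o is not None:
                assert stats.theta == pytest.approx(t_o, abs=1e-10)

    def test_invariant_to_relabeling_and_order(self, rng):
        pops = random_genotype_dataset(rng, max_pops=3)
        while len(pops) < 2:
            pops = random_genotype_dataset(rng, max_pops=3)
        base = wc_f_statistics(pops_to_samples(pops))
        relabel = {a: c for a, c in zip("0123456789", "zyxwvutsrq")}
        swapped = [
            [tuple(sorted(relabel.get(str(x), str(x)) for x in g)) for g in pop]
            for pop in pops
        ]
        perm = wc_f_statistics(pops_to_samples(swapped[::-1]))
        assert perm.theta == pytest.approx(base.theta, abs=1e-12)
        assert perm.f == pytest.approx(base.f, abs=1e-12)

    def test_multilocus_is_component_sum_not_mean(self):
        loci = [Locus("A", "microsatellite"), Locus("B", "microsatellite")]
        # two populations, two loci with different information content
        g1 = [[(1, 1)] * 8 + [(1, 2)] * 2, [(2, 2)] * 8 + [(1, 2)] * 2]
        g2 = [[(1, 2)] * 5 + [(1, 1)] * 5, [(1, 2)] * 5 + [(1, 1)] * 5]
        samples = [
            GenotypeSample(
                site=f"s{i}",
                year=i,
                loci=loci,
                genotypes=[[a, b] for a, b in zip(g1[i], g2[i])],
            )
            for i in range(2)
        ]
        stats = wc_f_statistics(samples)
        comp = {
            loc: stats.per_locus[loc] for loc in ("A", "B")
        }
        num = comp["A"]["a"] + comp["B"]["a"]
        den = sum(comp[l][k] for l in ("A", "B") for k in ("a", "b", "c"))
        assert stats.theta == pytest.approx(num / den, abs=1e-12)
        mean_theta = np.mean([comp["A"]["a"] / sum(comp["A"][k] for k in "abc"),
                              comp["B"]["a"] / sum(comp["B"][k] for k in "abc")])
        assert stats.theta != pytest.approx(mean_theta, abs=1e-6)

    def test_monomorphic_loci_excluded_and_all_monomorphic_errors(self):
        loci = [Locus("mono", "microsatellite"), Locus("poly", "microsatellite")]
        samples = [
            GenotypeSample(
                site=f"s{i}", year=i, loci=loci,
                genotypes=[[(5, 5), g] for g in pop],
            )
            for i, pop in enumerate([[(1, 1), (1, 2)], [(2, 2), (1, 2)]])
        ]
        stats = wc_f_statistics(samples)
        assert stats.excluded_monomorphic == ["mono"]
        mono_only = [
            GenotypeSample(site="s", year=0, loci=[loci[0]], genotypes=[[(5, 5)]] * 4)
        ]
        with pytest.raises(PopgenError, match="monomorphic"):
            wc_f_statistics(mono_only)


class TestPermutationFis:
    def test_extreme_heterozygote_deficit(self):
        s = make_sample([(1, 1)] * 10 + [(2, 2)] * 10)
        p = permutation_test_fis(s, "L1", n_perm=2000, seed=11)
        assert p <= 0.01

    def test_p_never_zero_and_nperm_validated(self):
        s = make_sample([(1, 1)] * 10 + [(2, 2)] * 10)
        p = permutation_test_fis(s, "L1", n_perm=50, seed=3)
        assert p >= 1 / 51
        with pytest.raises(PopgenError):
            permutation_test_fis(s, "L1", n_perm=0)

    def test_null_p_values_valid_and_informative(self, rng):
        # Samples drawn under random mating: the permutation p must be a
        # valid p-value, P(p <= t) <= t.  Exact uniformity cannot hold —
        # f given the allele counts is a function of the heterozygote
        # count alone, so its permutation distribution is heavily tied and
        # the test is conservative at these sample sizes.
        pvals = []
        for i in range(200):
            genos = [
                tuple(sorted(rng.choice([1, 2], 2, p=[0.5, 0.5]))) for _ in range(40)
            ]
            s = make_sample(genos)
            if len(allele_frequencies(s, "L1")) < 2:
                continue
            pvals.append(
                permutation_test_fis(s, "L1", n_perm=200, seed=int(rng.integers(2**31)))
            )
        pvals = np.asarray(pvals)
        n = len(pvals)
        for t in (0.05, 0.10, 0.25):
            rate = (pvals <= t).mean()
            se = np.sqrt(t * (1 - t) / n)
            assert rate <= t + 3 * se, f"anticonservative at {t}: {rate}"
        assert (pvals <= 0.5).mean() > 0.1  # not degenerate

    def test_two_sided_mode(self):
        s = make_sample([(1, 2)] * 20)  # extreme heterozygote excess
        p_def = permutation_test_fis(s, "L1", n_perm=500, seed=5, tail="deficit")
        p_two = permutation_test_fis(s, "L1", n_perm=500, seed=5, tail="two-sided")
        assert p_def > 0.5  # excess is the wrong tail for the deficit test
        assert p_two <= 0.05


class TestPermutationFst:
    def test_fixed_samples_minimal_p(self):
        a = make_sample([(1, 1)] * 20, site="a")
        b = make_sample([(2, 2)] * 20, site="b", year=1)
        p = permutation_test_fst(a, b, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_identical_samples_large_p(self):
        genos = [(1, 1), (1, 2), (2, 2), (1, 2)] * 5
        a = make_sample(genos, site="a")
        b = make_sample(genos, site="b", year=1)
        assert permutation_test_fst(a, b, n_perm=200, seed=2) > 0.5

    def test_no_shared_polymorphic_locus_errors(self):
        a = make_sample([(1, 1)] * 4, site="a")
        b = make_sample([(1, 1)] * 4, site="b", year=1)
        with pytest.raises(PopgenError):
            permutation_test_fst(a, b, n_perm=10, seed=0)


class TestReportWrappers:
    def test_locus_summaries_flags_monomorphic(self):
        loci = [Locus("mono", "microsatellite"), Locus("poly", "microsatellite")]
        s = GenotypeSample(
            site="s", year=0, loci=loci,
            genotypes=[[(5, 5), (1, 2)], [(5, 5), (1, 1)], [(5, 5), (2, 2)]],
        )
        out = {ls.locus: ls for ls in locus_summaries(s, n_perm=50, seed=1)}
        assert out["mono"].monomorphic and out["mono"].fis is None
        assert not out["poly"].monomorphic and out["poly"].p_fis > 0

    def test_pairwise_fst_shape_and_symmetry(self, rng):
        samples = [
            make_sample(
                [tuple(sorted(rng.choice([1, 2, 3], 2))) for _ in range(12)],
                site="s", year=y,
            )
            for y in range(3)
        ]
        pw = pairwise_fst(samples, n_perm=50, seed=4)
        assert pw.theta.shape == (3, 3)
        assert np.allclose(pw.theta, pw.theta.T)
        assert np.all(np.diag(pw.theta) == 0)
        off = ~np.eye(3, dtype=bool)
        assert (pw.p_values[off] > 0).all() and (pw.p_values[off] <= 1).all()
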