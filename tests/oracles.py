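"""Independent brute-force oracles used only by the test suite.

The F-statistics oracle takes the nested-ANOVA route: each allele is coded
as an indicator variable over gene copies (copies within individuals within
populations), mean squares are accumulated with explicit Python loops, and
variance components are recovered from the classical expected-mean-square
equations.  This is an independent derivation path from the closed-form
estimator formulas used by the package.
"""

from __future__ import annotations


def anova_f_statistics(pops):
    """Weir-Cockerham f and theta from an explicit indicator-variable ANOVA.

    *pops* is a list of populations, each a list of (allele, allele)
    genotype tuples (no missing data).  Returns (f, theta); theta is None
    for a single population.  Monomorphic data raise ValueError.
    """
    alleles = sorted({a for pop in pops for g in pop for a in g}, key=repr)
    if len(alleles) < 2:
        raise ValueError("monomorphic data")
    r = len(pops)
    n = [len(pop) for pop in pops]
    N = sum(n)
    sum_a = sum_b = sum_c = 0.0
    for allele in alleles:
        # indicator data x[pop][ind][copy]
        x = [[[1.0 if a == allele else 0.0 for a in g] for g in pop] for pop in pops]
        ind_means = [[sum(copies) / 2.0 for copies in pop] for pop in x]
        pop_means = [sum(m for m in pm) / len(pm) if pm else 0.0 for pm in ind_means]
        # pop mean over gene copies equals mean of individual means
        grand = sum(n[i] * pop_means[i] for i in range(r)) / N
        ss_within = 0.0  # copies within individuals
        for pi in range(r):
            for ii in range(n[pi]):
                for copy in x[pi][ii]:
                    ss_within += (copy - ind_means[pi][ii]) ** 2
        ms_g = ss_within / N  # df = N individuals * (2 - 1)
        ss_ind = 0.0  # individuals within populations
        for pi in range(r):
            for ii in range(n[pi]):
                ss_ind += 2.0 * (ind_means[pi][ii] - pop_means[pi]) ** 2
        sig_g = ms_g
        if r > 1:
            ms_i = ss_ind / (N - r)
            ss_pop = 0.0
            for pi in range(r):
                ss_pop += 2.0 * n[pi] * (pop_means[pi] - grand) ** 2
            ms_p = ss_pop / (r - 1)
            nc = (N - sum(v * v for v in n) / N) / (r - 1)
            sig_i = (ms_i - ms_g) / 2.0
            sig_p = (ms_p - ms_i) / (2.0 * nc)
            sum_a += sig_p
        else:
            ms_i = ss_ind / (N - 1)
            sig_i = (ms_i - ms_g) / 2.0
        sum_b += sig_i
        sum_c += sig_g
    f = 1.0 - sum_c / (sum_b + sum_c) if (sum_b + sum_c) != 0 else None
    if r > 1:
        denom = sum_a + sum_b + sum_c
        theta = sum_a / denom if denom != 0 else None
    else:
        theta = None
    return f, theta


def random_genotype_dataset(rng, max_pops=3, max_n=20, max_alleles=4):
    """Random small multi-population single-locus dataset (no missing data)."""
    r = int(rng.integers(1, max_pops + 1))
    k = int(rng.integers(2, max_alleles + 1))
    while True:
        pops = []
        for _ in range(r):
            n = int(rng.integers(2, max_n + 1))
            freqs = rng.dirichlet([1.0] * k)
            draws = rng.choice(k, size=(n, 2), p=freqs)
            pops.append([tuple(sorted(g)) for g in draws])
        alleles = {a for pop in pops for g in pop for a in g}
        if len(alleles) >= 2:
            return pops
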