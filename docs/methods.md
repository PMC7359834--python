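# Methods

## Study design the package targets

Two localities of a riverine fish with a one-year generation time: one
affected by untreated wastewater (MEL) and one control (SFM). Diploid
genotype samples of ~21–24 individuals per site are available for two
years before and two years after a pollution-remediation intervention, at
one candidate locus (six haplotype alleles; the "focal" allele is the one
whose homozygote dominated the affected site before remediation) and at
eight microsatellites used as neutral controls (two of which are
monomorphic and excluded from F-statistics). Auxiliary data are
per-individual candidate-gene read counts from two RNA-seq campaigns and
replicate water-chemistry measurements.

## Estimators and tests

**Heterozygosity.** Ho is the fraction of heterozygous individuals among
those typed; He is Nei's unbiased estimator `(2n/(2n−1))(1 − Σ p_i²)`.
Monomorphic loci report (0, 0) and an undefined (flagged) F_IS rather than
propagating NaN.

**Weir–Cockerham F-statistics.** Per allele and locus the a (among
samples), b (among individuals within samples) and c (within individuals)
variance components are computed from the standard closed forms with
sample-size weights n̄ and n_c. Multi-locus and multi-allele estimates are
ratios of summed components — `θ = Σa / Σ(a+b+c)`, `f = 1 − Σc / Σ(b+c)` —
never means of per-locus ratios. For a single sample the among-sample
component is dropped and `f` uses b and c only. The test suite verifies
equality (1e-10) with an independent indicator-variable nested-ANOVA
implementation on random datasets. Note that at exact Hardy–Weinberg
genotype counts the small-sample `f` is not zero (e.g. +1/7 for 1 AA, 2
AB, 1 BB): the unbiased He exceeds Ho in small samples.

**Permutation nulls.** F_IS: allele copies are shuffled among individuals
within the sample, independently per locus, preserving allele counts while
destroying Hardy–Weinberg departure; the default tail is the
heterozygote-deficit direction, with a two-sided mode available. F_ST:
whole individuals are permuted between the two samples, preserving sample
sizes; one-tailed (θ_perm ≥ θ_obs). Both use `p = (hits + 1)/(n_perm + 1)`,
so p is never 0 and the tests are (slightly) conservative. Because θ and f
are functions of low-dimensional sufficient statistics, the permutation
distributions are discrete with heavy ties; null p-values are therefore
valid but super-uniform, and the suite tests validity (P(p ≤ t) ≤ t) rather
than strict uniformity. Defaults follow the desktop-software conventions
the design mimics: 5,000 permutations for F_IS, 1,000 for F_ST.

**Exact Fisher r×c.** Two-sided by probability ordering: p is the total
hypergeometric probability (margins fixed) of all tables no more probable
than the observed one (relative tolerance 1e-9 on log-probabilities). The
universe is enumerated recursively when a dynamic-programming count says it
has at most `max_tables` tables (default 10⁶, chosen for interpreter-speed
reasons; every table this pipeline produces is ≤ ~10⁵); otherwise a seeded
Monte-Carlo estimate over ≥10⁵ tables is returned with its standard error.
Enumeration also returns the total probability mass as a self-check.

**Exact Mann–Whitney.** `U = #{x_i < y_j} + ½·ties`; two-sided
`p = 2·min(P(U ≤ u), P(U ≥ u))` capped at 1, over all C(n₁+n₂, n₁)
assignments of the pooled observations (ties handled exactly via midranks
of the observed multiset). With n₁ = n₂ = 4, complete separation gives
p = 2/70 ≈ 0.0286 and U = 6 gives 48/70 ≈ 0.6857.

**Genotype categories and fitness.** Four categories relative to the focal
allele; Fisher tests run on the unpooled four-category counts (pooling is
applied only to fitness, where it exists to avoid zero denominators —
whether the original analysis pooled for the homogeneity tests too is not
documented, so the four-category table is the default). Fitness of a
pooled category is `freq_after / freq_before` for each of the four
(before, after) year pairs; a zero before-frequency after pooling raises a
named error rather than yielding infinities. Category fitness values are
compared pairwise with the exact Mann–Whitney test, uncorrected for
multiplicity (three tests, reported as-is).

**Expression.** Reads per million: `mapped/total × 10⁶`. The ratio of
change is the ratio of per-site means of normalised values (not a mean of
per-pair ratios: group sizes differ between sites and years, so a pairing
would be arbitrary). No significance test is attached to this statistic —
the design provides only a point ratio per epoch — and the report says so.

**Water PCA.** Correlation-matrix PCA (scale=True default, forced by the
mixed units) via SVD of the standardised data, eigenvalues `s²/(n−1)`
summing to the number of variables; loading signs fixed so each
component's largest-magnitude loading is positive. Rows with missing
values are dropped with a logged count; zero-variance variables are a
named error. Group centroids and per-axis centroid distances are reported
without a significance test.

## The simulator

Two demes of constant diploid size, discrete non-overlapping generations.
Per generation, for each offspring slot in deme *i*: a source deme *j* is
drawn with probability `migration[i][j]` (backward rates, rows sum to 1;
both parents come from the same source deme); two parents are drawn with
replacement from deme *j* weighted by the current-epoch viability of their
candidate genotype; each parent transmits one uniformly chosen allele per
locus; transmitted microsatellite alleles mutate ±1 repeat with probability
`mu_stepwise`, reflecting at a floor of 1 repeat. The candidate locus does
not mutate (six alleles over twelve years makes mutation negligible at
this scale). Offspring of generation g experience the `before` fitness
regime while `g ≤ switch_generation`. Sampling draws individuals without
replacement from the standing newborn population; generation 0 is the
initial population, drawn in Hardy–Weinberg proportions from the
configured allele frequencies. All randomness flows from one seeded numpy
Generator, so identical configs give byte-identical samples. The life-cycle
order (migration → selection → mating) is fixed by design so the
deterministic oracle matches by construction.

`deterministic_trajectory` is the infinite-population oracle: it tracks
full genotype-frequency matrices per deme (so Wahlund-type departures from
Hardy–Weinberg created by selection and migrant mixing propagate exactly)
and applies the same operation order. The suite checks that the mean of
200 replicates at deme size 10⁴ stays within 3 Monte-Carlo SE of the
recursion at every sampled generation.

**Expression generator.** `total_reads` log-uniform within configured
bounds; `mapped_reads` gamma-Poisson (negative binomial) with mean
`μ·total/10⁶` and size = dispersion. **Water generator.** Multivariate
normal per (site, epoch) with configurable means/covariances and
replicates per year.

## Frozen study-like scenario

`tempsel.scenarios` holds the reference conditions used by the demo
pipeline and the acceptance-level tests: demes of 2,000 (real census sizes
are unknown; 2,000 keeps twelve generations of microsatellite drift,
E[F_ST] ≈ t/2N ≈ 0.003, safely below detectability at n = 24 while
remaining cheap to simulate), reciprocal migration 0.15 (within the
0.13–0.29 range estimated for the real populations), viability 0.5 for the
focal homozygote at the affected site before the switch, focal-allele
frequencies 0.65/0.35, six polymorphic + two monomorphic microsatellites,
stepwise mutation 5×10⁻⁴, samples of 24 at generations 0, 1 (before the
switch at generation 6) and 12, 13. The initial frequencies and sampling
generations were chosen once, via the deterministic recursion, to make the
affected deme's frequency change clearly detectable while keeping every
genotype category represented in before-samples of 24: pushing the initial
focal frequency above ~0.72 makes the pooled no-focal category rarer than
0.08 and zero-count failures frequent, while lower frequencies shrink the
before/after contrast.

What the generator does *not* emulate: the heterozygote deficit observed
at the affected site before remediation (an inbreeding/structure feature
that Hardy–Weinberg initialisation plus viability selection against a
homozygote cannot produce), age structure, sex, linkage, null alleles and
genotyping error. Consequences: passing scenario tests demonstrate that
the pipeline detects a relaxing viability regime against drifting neutral
controls; they do not certify behaviour on data with within-site
substructure. The heterozygote category's fitness ratio is close to 1 on
the simulated trajectory (2pq is nearly stationary while p crosses 0.5),
unlike in the motivating dataset where the pre-intervention heterozygote
deficit inflated it — see the scenario acceptance test for the quantitative
consequence.

## Numerical choices and edge cases

* Allele pairs are stored sorted; statistics are invariant to allele
  relabelling and sample order (property-tested).
* Missing genotypes are dropped locus-wise; an individual missing one
  locus still contributes at the others. Genepop missing sentinel is
  000/00.
* Monomorphic loci are excluded from all F-statistics and flagged in
  reports.
* Permutation and enumeration comparisons use absolute tolerances
  (1e-12 on θ, relative 1e-9 on log-probabilities) to absorb float error
  in tie detection.
* Fisher enumeration falls back to seeded Monte-Carlo above 10⁶ tables;
  exact Mann–Whitney refuses beyond 5×10⁵ assignments.
* The pipeline derives per-module seeds from one root via
  `SeedSequence.spawn`-style generation, so enabling or disabling one
  analysis does not perturb another's results.

## Known limitations

* F_IS permutation p-values are conservative (discrete null); no exact
  mid-p option is exposed.
* No bootstrap confidence intervals over loci, no null-allele estimation,
  no linkage-disequilibrium tests, no migration-rate re-estimation (the
  simulator's rates are inputs).
* The expression module implements per-million scaling only — no
  differential-expression model — matching the statistic it reproduces.
* Genepop support covers the common dialect (title, locus lines, POP
  blocks, 2/3-digit codes); sub-dialects with per-population names on the
  POP line are not parsed.
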