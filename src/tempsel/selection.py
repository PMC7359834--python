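"""Candidate-gene selection inference: categories, exact tests, fitness ratios.

Diploid genotypes at the candidate locus are classified into four categories
relative to a focal allele (the haplotype whose homozygote dominated the
affected site before the intervention): focal homozygote, focal
heterozygote, other homozygote, other heterozygote.  Temporal homogeneity of
category counts is tested with an exact Fisher r x c test; the
genotype-survival fitness component of each (pooled) category is the ratio
of its sample frequency after versus before the intervention, and fitness
values are compared between categories with the exact Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb, lgamma

import numpy as np

from .datatypes import (
    CATEGORIES,
    FOCAL_HETEROZYGOTE,
    FOCAL_HOMOZYGOTE,
    OTHER_HETEROZYGOTE,
    OTHER_HOMOZYGOTE,
    POOLED_CATEGORIES,
    CategoryCounts,
    FitnessEstimates,
    GenotypeSample,
)


class SelectionError(ValueError):
    pass


class ZeroBeforeFrequencyError(SelectionError):
    """A pooled category has frequency zero in a before-year.

    The homozygote/heterozygote-without-focal pooling exists precisely to
    avoid zero denominators; hitting one anyway signals pathological input.
    """


# ---------------------------------------------------------------------------
# genotype categories
# ---------------------------------------------------------------------------


def classify_genotype(allele_pair, focal_allele: str) -> str:
    """Category of an unordered allele pair relative to the focal allele."""
    if allele_pair is None:
        raise SelectionError("missing genotype cannot be classified")
    a, b = allele_pair
    if a is None or b is None:
        raise SelectionError("missing allele cannot be classified")
    if a == focal_allele and b == focal_allele:
        return FOCAL_HOMOZYGOTE
    if a == focal_allele or b == focal_allele:
        return FOCAL_HETEROZYGOTE
    if a == b:
        return OTHER_HOMOZYGOTE
    return OTHER_HETEROZYGOTE


def category_counts(
    sample: GenotypeSample, focal_allele: str, locus: str | None = None
) -> CategoryCounts:
    """Counts of the four categories at the candidate locus of *sample*.

    Missing genotypes are excluded (dropped upstream of classification).
    """
    if locus is None:
        cand = [l.name for l in sample.loci if l.kind == "candidate"]
        if len(cand) != 1:
            raise SelectionError(
                f"sample {sample.site}/{sample.year} has {len(cand)} candidate "
                "loci; pass locus= explicitly"
            )
        locus = cand[0]
    counts = {cat: 0 for cat in CATEGORIES}
    for g in sample.typed_genotypes(locus):
        counts[classify_genotype(g, focal_allele)] += 1
    return CategoryCounts(
        site=sample.site, year=sample.year, focal_allele=focal_allele, counts=counts
    )


# ---------------------------------------------------------------------------
# exact Fisher r x c test
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p: float
    method: str  # "enumeration" or "monte_carlo"
    n_tables: int  # tables enumerated, or Monte-Carlo draws
    se: float | None = None  # Monte-Carlo standard error
    total_probability: float | None = None  # enumerated mass, ~1 (diagnostic)


def fisher_exact_rxc(
    table,
    max_tables: int = 1_000_000,
    n_mc: int = 100_000,
    seed=None,
) -> FisherResult:
    """Exact Fisher test for an r x c table of non-negative integers.

    Two-sided by the probability-ordering criterion: ``p`` is the total
    multivariate-hypergeometric probability (margins fixed) of all tables no
    more probable than the observed one.  The table universe is fully
    enumerated when its size is at most *max_tables*; otherwise a seeded
    Monte-Carlo estimate over *n_mc* random tables is returned together with
    its standard error.
    """
    obs = np.asarray(table)
    if obs.ndim != 2:
        raise SelectionError("table must be two-dimensional")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.all(np.asarray(obs, float) == np.floor(np.asarray(obs, float))):
            raise SelectionError("table entries must be integers")
        obs = obs.astype(np.int64)
    if (obs < 0).any():
        raise SelectionError("table entries must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.size == 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        return FisherResult(p=1.0, method="enumeration", n_tables=1, total_probability=1.0)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    N = int(obs.sum())
    lg = [lgamma(i + 1) for i in range(N + 1)]
    const = sum(lg[r] for r in rows) + sum(lg[c] for c in cols) - lg[N]

    def log_prob(t: np.ndarray) -> float:
        return const - sum(lg[int(v)] for v in t.ravel())

    lp_obs = log_prob(obs)
    universe = _count_tables(tuple(rows), tuple(cols), max_tables)
    if universe is not None:
        total = 0.0
        hit = 0.0
        n_seen = 0
        tol = lp_obs + 1e-9
        r, c = obs.shape
        work = np.zeros((r, c), dtype=np.int64)

        def recurse(row_idx: int, rem_cols: tuple, partial: float) -> None:
            nonlocal total, hit, n_seen
            if row_idx == r - 1:
                last = np.asarray(rem_cols, dtype=np.int64)
                lp = partial - sum(lg[int(v)] for v in last)
                pr = math.exp(lp)
                total += pr
                n_seen += 1
                if lp <= tol:
                    hit += pr
                return
            target = int(rows[row_idx])
            cells = np.zeros(c, dtype=np.int64)

            def fill(ci: int, remaining: int, part: float) -> None:
                if ci == c - 1:
                    if remaining > rem_cols[ci]:
                        return
                    cells[ci] = remaining
                    recurse(
                        row_idx + 1,
                        tuple(rem_cols[j] - cells[j] for j in range(c)),
                        part - lg[remaining],
                    )
                    return
                hi = min(remaining, rem_cols[ci])
                lo = max(0, remaining - sum(rem_cols[ci + 1 :]))
                for v in range(lo, hi + 1):
                    cells[ci] = v
                    fill(ci + 1, remaining - v, part - lg[v])

            fill(0, target, partial)

        del work
        recurse(0, tuple(int(v) for v in cols), const)
        return FisherResult(
            p=min(hit, 1.0),
            method="enumeration",
            n_tables=n_seen,
            total_probability=total,
        )

    # Monte-Carlo fallback: random tables via permutation of column labels
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    r, c = obs.shape
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros((r, c), dtype=np.int64)
        np.add.at(t, (row_labels, perm), 1)
        if log_prob(t) <= lp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p=p, method="monte_carlo", n_tables=n_mc, se=se)


def _count_tables(rows: tuple, cols: tuple, cap: int):
    """Number of tables with the given margins, or None if it exceeds *cap*.

    Dynamic programme over rows with memoised remaining column margins;
    aborts (returns None) as soon as the count exceeds the cap.
    """
    from functools import lru_cache

    cols = tuple(sorted(cols))

    @lru_cache(maxsize=None)
    def count(row_idx: int, rem: tuple) -> int:
        if row_idx == len(rows) - 1:
            return 1
        target = rows[row_idx]
        c = len(rem)
        total = 0

        def fill(ci: int, remaining: int, rem_list: list) -> int:
            if ci == c - 1:
                if remaining > rem_list[ci]:
                    return 0
                return count(row_idx + 1, _subtract(rem_list, ci, remaining))
            sub = 0
            hi = min(remaining, rem_list[ci])
            lo = max(0, remaining - sum(rem_list[ci + 1 :]))
            for v in range(lo, hi + 1):
                rem_list[ci] -= v
                sub += fill(ci + 1, remaining - v, rem_list)
                rem_list[ci] += v
                if sub > cap:
                    return sub
            return sub

        def _subtract(rem_list, ci, v):
            out = list(rem_list)
            out[ci] -= v
            return tuple(sorted(out))  # column order is irrelevant to the count

        total = fill(0, target, list(rem))
        return total

    try:
        n = count(0, cols)
    except RecursionError:  # pathological shapes
        return None
    return n if n <= cap else None


# ---------------------------------------------------------------------------
# exact Mann-Whitney U test
# ---------------------------------------------------------------------------


def mann_whitney_exact(x, y, max_assignments: int = 500_000) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    ``U = #{(i, j): x_i < y_j} + 0.5 * #{ties}``; the two-sided p-value is
    ``2 * min(P(U <= u), P(U >= u))`` capped at 1, over all
    ``C(n1 + n2, n1)`` assignments of the pooled observations to the two
    groups (permutation distribution of the observed multiset, so ties are
    handled exactly via midranks).
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise SelectionError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    n_assign = comb(n1 + n2, n1)
    if n_assign > max_assignments:
        raise SelectionError(
            f"{n_assign} assignments exceed the exact-enumeration limit"
        )
    pooled = x + y

    def u_stat(xs, ys) -> float:
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi < yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    idx = range(n1 + n2)
    le = ge = 0
    for chosen in itertools.combinations(idx, n1):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        u = u_stat(xs, ys)
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    p = 2.0 * min(le, ge) / n_assign
    return u_obs, min(p, 1.0)


# ---------------------------------------------------------------------------
# genotype-survival fitness ratios
# ---------------------------------------------------------------------------


def fitness_ratios(
    category_tables: list[CategoryCounts],
    before_years: list[int],
    after_years: list[int],
) -> FitnessEstimates:
    """Genotype-survival fitness components for one site.

    Categories are pooled to three (the two categories lacking the focal
    allele are merged); for every (before, after) year pair the fitness of a
    category is its sample frequency after divided by before.  With two
    before and two after years this yields four values per category.
    """
    if not category_tables:
        raise SelectionError("no category tables supplied")
    sites = {t.site for t in category_tables}
    if len(sites) != 1:
        raise SelectionError(f"tables mix sites {sorted(sites)}")
    focal = {t.focal_allele for t in category_tables}
    if len(focal) != 1:
        raise SelectionError("tables mix focal alleles")
    by_year = {t.year: t for t in category_tables}
    needed = list(before_years) + list(after_years)
    missing = [y for y in needed if y not in by_year]
    if missing:
        raise SelectionError(f"missing category tables for years {missing}")
    freqs: dict[int, dict[str, float]] = {}
    for year in needed:
        t = by_year[year]
        total = t.total
        if total == 0:
            raise SelectionError(f"year {year} has zero typed individuals")
        freqs[year] = {cat: cnt / total for cat, cnt in t.pooled().items()}
    values: dict[str, list[float]] = {cat: [] for cat in POOLED_CATEGORIES}
    for cat in POOLED_CATEGORIES:
        for b in before_years:
            if freqs[b][cat] == 0.0:
                raise ZeroBeforeFrequencyError(
                    f"category {cat!r} has frequency 0 in before-year {b} "
                    f"at site {category_tables[0].site}"
                )
            for a in after_years:
                values[cat].append(freqs[a][cat] / freqs[b][cat])
    medians = {cat: float(np.median(v)) for cat, v in values.items()}
    return FitnessEstimates(
        site=category_tables[0].site,
        focal_allele=focal.pop(),
        before_years=list(before_years),
        after_years=list(after_years),
        values=values,
        medians=medians,
    )


def compare_fitness(estimates: FitnessEstimates) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise exact Mann-Whitney tests among the three pooled categories.

    No multiplicity correction is applied (three tests are reported as-is).
    """
    out = {}
    cats = list(POOLED_CATEGORIES)
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            u, p = mann_whitney_exact(
                estimates.values[cats[i]], estimates.values[cats[j]]
            )
            out[(cats[i], cats[j])] = (u, p)
    return out
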