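"""Two-deme Wright-Fisher forward simulator and companion generators.

The simulator emulates a before/after remediation study design: two demes
(an affected and a control site) exchanging migrants every generation, one
candidate locus under viability selection in one deme during the ``before``
epoch only, and a panel of neutral microsatellites evolving under drift and
stepwise mutation.  Generations are discrete and non-overlapping (the study
organism has a 1-year generation time), deme sizes are constant, and all
loci are unlinked.

Life cycle per generation, fixed by design so the deterministic oracle
matches by construction:

1. migration — for every offspring slot in deme *i* a source deme *j* is
   drawn with probability ``migration[i][j]`` (backward, destination-based
   rates; both parents come from the same source deme);
2. selection — the two parents are drawn with replacement from deme *j*
   weighted by the current-epoch viability of their candidate genotype;
3. mating — each parent transmits one uniformly chosen allele per locus;
4. mutation — each transmitted microsatellite allele mutates by +-1 repeat
   with probability ``mu_stepwise``, reflecting at a floor of 1 repeat.
   The candidate locus does not mutate.

All randomness flows from a single ``numpy`` Generator seeded by
``config.seed``; identical configurations produce byte-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .datatypes import (
    CANDIDATE,
    CATEGORIES,
    FOCAL_HETEROZYGOTE,
    FOCAL_HOMOZYGOTE,
    MICROSATELLITE,
    OTHER_HETEROZYGOTE,
    OTHER_HOMOZYGOTE,
    GenotypeSample,
    Locus,
)

BEFORE = "before"
AFTER = "after"


class SimulationError(RuntimeError):
    """Raised when a simulated population cannot produce offspring."""


@dataclass
class MicrosatLocus:
    """Initial allele set (repeat numbers) and frequencies for one locus."""

    alleles: list[int]
    freqs: list[float]

    def validate(self, name: str) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ValueError(f"{name}: alleles and freqs differ in length")
        if any(a < 1 for a in self.alleles):
            raise ValueError(f"{name}: microsatellite alleles must be >= 1 repeat")
        _check_freqs(self.freqs, name)


def _check_freqs(freqs: Sequence[float], what: str, tol: float = 1e-9) -> None:
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{what}: frequency vector is empty")
    if (arr < 0).any():
        raise ValueError(f"{what}: negative frequency")
    if abs(arr.sum() - 1.0) > tol:
        raise ValueError(f"{what}: frequencies sum to {arr.sum()}, not 1")


@dataclass
class SimulationConfig:
    """Full parameterisation of the two-deme Wright-Fisher world.

    ``fitness_by_epoch`` maps ``(deme_index, epoch)`` to a genotype ->
    relative-viability map.  Genotype keys may be an explicit unordered
    allele pair written ``"A/B"``, one of the four genotype categories
    (``focal_homozygote`` etc., resolved through ``focal_allele``), or
    ``"default"``.  Explicit pairs override categories, which override the
    default of 1.0.  Offspring born in generation ``g`` experience the
    ``before`` fitness regime while ``g <= switch_generation``.
    """

    deme_sizes: tuple[int, int]
    migration: Any  # 2x2, row = destination deme, rows sum to 1
    candidate_alleles: list[str]
    candidate_init_freqs: Any  # (2, n_alleles), one row per deme
    fitness_by_epoch: dict[tuple[int, str], dict[str, float]] = field(default_factory=dict)
    focal_allele: str | None = None
    n_microsats: int = 0
    microsat_init_alleles: list[MicrosatLocus] = field(default_factory=list)
    mu_stepwise: float = 0.0
    n_generations: int = 1
    switch_generation: int = 1
    sampling_plan: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0
    deme_names: tuple[str, str] = ("deme0", "deme1")
    candidate_locus_name: str = "candidate"
    microsat_names: list[str] | None = None
    year_zero: int = 0

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if len(self.deme_sizes) != 2 or any(int(n) <= 0 for n in self.deme_sizes):
            raise ValueError("deme_sizes must be two positive integers")
        mig = np.asarray(self.migration, dtype=float)
        if mig.shape != (2, 2) or (mig < 0).any():
            raise ValueError("migration must be a non-negative 2x2 matrix")
        if np.abs(mig.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("migration rows must sum to 1 within 1e-12")
        if len(self.candidate_alleles) != len(set(self.candidate_alleles)):
            raise ValueError("candidate allele labels must be unique")
        freqs = np.asarray(self.candidate_init_freqs, dtype=float)
        if freqs.shape != (2, len(self.candidate_alleles)):
            raise ValueError("candidate_init_freqs must be (2, n_alleles)")
        for d in range(2):
            _check_freqs(freqs[d], f"candidate_init_freqs deme {d}")
        if self.focal_allele is not None and self.focal_allele not in self.candidate_alleles:
            raise ValueError(f"focal allele {self.focal_allele!r} not in candidate_alleles")
        if len(self.microsat_init_alleles) != self.n_microsats:
            raise ValueError("microsat_init_alleles must have n_microsats entries")
        for li, loc in enumerate(self.microsat_init_alleles):
            loc.validate(f"microsatellite {li}")
        if not 0.0 <= self.mu_stepwise < 1.0:
            raise ValueError("mu_stepwise must be in [0, 1)")
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")
        if not 0 <= self.switch_generation <= self.n_generations:
            raise ValueError("switch_generation must be in [0, n_generations]")
        for gen, deme, size in self.sampling_plan:
            if not 0 <= gen <= self.n_generations:
                raise ValueError(f"sampling generation {gen} outside [0, n_generations]")
            if deme not in (0, 1):
                raise ValueError(f"sampling deme {deme} must be 0 or 1")
            if size < 1 or size > self.deme_sizes[deme]:
                raise ValueError(
                    f"sample size {size} exceeds deme {deme} size "
                    f"{self.deme_sizes[deme]} (or is < 1)"
                )
        for (deme, epoch), _w in self.fitness_by_epoch.items():
            if deme not in (0, 1) or epoch not in (BEFORE, AFTER):
                raise ValueError(f"bad fitness key {(deme, epoch)!r}")
        for deme in (0, 1):
            for epoch in (BEFORE, AFTER):
                w = self.viability_matrix(deme, epoch)
                if (w < 0).any():
                    raise ValueError(f"negative viability for deme {deme} epoch {epoch}")
                if not (w > 0).any():
                    raise ValueError(
                        f"all viabilities zero for deme {deme} epoch {epoch}"
                    )

    # -- derived quantities ---------------------------------------------

    def epoch(self, generation: int) -> str:
        return BEFORE if generation <= self.switch_generation else AFTER

    def viability_matrix(self, deme: int, epoch: str) -> np.ndarray:
        """(k, k) symmetric matrix of viabilities over candidate genotypes."""
        alleles = self.candidate_alleles
        k = len(alleles)
        spec = self.fitness_by_epoch.get((deme, epoch), {})
        w = np.full((k, k), float(spec.get("default", 1.0)))
        focal = self.focal_allele
        if focal is not None:
            fi = alleles.index(focal)
            for cat in CATEGORIES:
                if cat not in spec:
                    continue
                val = float(spec[cat])
                for i in range(k):
                    for j in range(k):
                        if _category_of(i, j, fi) == cat:
                            w[i, j] = val
        elif any(cat in spec for cat in CATEGORIES):
            raise ValueError("category fitness keys require focal_allele to be set")
        for key, val in spec.items():
            if key == "default" or key in CATEGORIES:
                continue
            try:
                a, b = key.split("/")
                i, j = alleles.index(a), alleles.index(b)
            except (ValueError, AttributeError) as exc:
                raise ValueError(f"bad fitness genotype key {key!r}") from exc
            w[i, j] = w[j, i] = float(val)
        return w

    def locus_list(self) -> list[Locus]:
        names = self.microsat_names or [
            f"ms{li + 1:02d}" for li in range(self.n_microsats)
        ]
        if len(names) != self.n_microsats:
            raise ValueError("microsat_names must have n_microsats entries")
        return [Locus(self.candidate_locus_name, CANDIDATE)] + [
            Locus(nm, MICROSATELLITE) for nm in names
        ]


def _category_of(i: int, j: int, focal: int) -> str:
    if i == focal and j == focal:
        return FOCAL_HOMOZYGOTE
    if i == focal or j == focal:
        return FOCAL_HETEROZYGOTE
    if i == j:
        return OTHER_HOMOZYGOTE
    return OTHER_HETEROZYGOTE


# ---------------------------------------------------------------------------
# individual-based simulation
# ---------------------------------------------------------------------------


def simulate_two_deme(config: SimulationConfig) -> list[GenotypeSample]:
    """Forward-simulate the configured world and return the planned samples.

    One :class:`GenotypeSample` is returned per ``sampling_plan`` entry, in
    plan order.  Sampling draws individuals without replacement from the
    standing (newborn) population of the requested generation; generation 0
    is the initial population drawn from the configured allele frequencies
    under Hardy-Weinberg proportions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mig = np.asarray(config.migration, dtype=float)
    k = len(config.candidate_alleles)
    init_freqs = np.asarray(config.candidate_init_freqs, dtype=float)
    n_ms = config.n_microsats

    # state arrays per deme: cand (N, 2) allele indices, micro (N, n_ms, 2) repeats
    cand: list[np.ndarray] = []
    micro: list[np.ndarray] = []
    for d in range(2):
        n = int(config.deme_sizes[d])
        cand.append(rng.choice(k, size=(n, 2), p=init_freqs[d]))
        ms = np.empty((n, n_ms, 2), dtype=np.int64)
        for li, loc in enumerate(config.microsat_init_alleles):
            idx = rng.choice(len(loc.alleles), size=(n, 2), p=np.asarray(loc.freqs))
            ms[:, li, :] = np.asarray(loc.alleles, dtype=np.int64)[idx]
        micro.append(ms)

    plan_by_gen: dict[int, list[int]] = {}
    for pi, (gen, _deme, _size) in enumerate(config.sampling_plan):
        plan_by_gen.setdefault(gen, []).append(pi)
    results: dict[int, GenotypeSample] = {}
    loci = config.locus_list()

    def take_samples(gen: int) -> None:
        for pi in plan_by_gen.get(gen, []):
            _g, deme, size = config.sampling_plan[pi]
            idx = rng.choice(config.deme_sizes[deme], size=size, replace=False)
            results[pi] = _build_sample(config, loci, cand[deme][idx], micro[deme][idx], deme, gen)

    take_samples(0)
    for gen in range(1, config.n_generations + 1):
        epoch = config.epoch(gen)
        weights = []
        for d in range(2):
            w = config.viability_matrix(d, epoch)
            weights.append(w[cand[d][:, 0], cand[d][:, 1]])
        new_cand, new_micro = [], []
        for dest in range(2):
            n = int(config.deme_sizes[dest])
            src = np.where(rng.random(n) < mig[dest, 1 - dest], 1 - dest, dest)
            child_c = np.empty((n, 2), dtype=cand[0].dtype)
            child_m = np.empty((n, n_ms, 2), dtype=np.int64)
            for j in (dest, 1 - dest):
                mask = src == j
                cnt = int(mask.sum())
                if cnt == 0:
                    continue
                wsum = weights[j].sum()
                if wsum <= 0:
                    raise SimulationError(
                        f"no viable parents in deme {j} ({config.deme_names[j]}) "
                        f"at generation {gen}"
                    )
                parents = rng.choice(
                    config.deme_sizes[j], size=(cnt, 2), p=weights[j] / wsum
                )
                for side in range(2):
                    pick = rng.integers(0, 2, size=cnt)
                    child_c[mask, side] = cand[j][parents[:, side], pick]
                    picks = rng.integers(0, 2, size=(cnt, n_ms))
                    gam = np.take_along_axis(
                        micro[j][parents[:, side]], picks[:, :, None], axis=2
                    )[:, :, 0]
                    child_m[mask, :, side] = gam
            if n_ms and config.mu_stepwise > 0:
                hit = rng.random(child_m.shape) < config.mu_stepwise
                steps = rng.integers(0, 2, size=child_m.shape) * 2 - 1
                mutated = child_m + np.where(hit, steps, 0)
                child_m = np.where(mutated < 1, 2 - mutated, mutated)
            new_cand.append(child_c)
            new_micro.append(child_m)
        cand, micro = new_cand, new_micro
        take_samples(gen)

    return [results[pi] for pi in range(len(config.sampling_plan))]


def _build_sample(
    config: SimulationConfig,
    loci: list[Locus],
    cand_rows: np.ndarray,
    micro_rows: np.ndarray,
    deme: int,
    gen: int,
) -> GenotypeSample:
    labels = config.candidate_alleles
    genotypes = []
    for i in range(cand_rows.shape[0]):
        row: list[tuple] = [(labels[cand_rows[i, 0]], labels[cand_rows[i, 1]])]
        for li in range(config.n_microsats):
            row.append((int(micro_rows[i, li, 0]), int(micro_rows[i, li, 1])))
        genotypes.append(row)
    return GenotypeSample(
        site=config.deme_names[deme],
        year=config.year_zero + gen,
        loci=list(loci),
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# deterministic (infinite-population) oracle
# ---------------------------------------------------------------------------


def deterministic_trajectory(config: SimulationConfig) -> np.ndarray:
    """Expected candidate allele-frequency trajectory, ignoring drift.

    Tracks full genotype-frequency matrices per deme so that departures from
    Hardy-Weinberg created by selection and migrant mixing are propagated
    exactly; the same migration -> selection -> mating order as the
    individual-based simulator is applied.  Returns an array of shape
    ``(n_generations + 1, 2, n_alleles)`` whose ``[g, d]`` entry is the
    allele-frequency vector of the standing population of deme ``d`` at
    generation ``g`` (``g = 0`` is the initial state).
    """
    config.validate()
    mig = np.asarray(config.migration, dtype=float)
    k = len(config.candidate_alleles)
    freqs = np.asarray(config.candidate_init_freqs, dtype=float)
    # genotype frequency matrices, initially Hardy-Weinberg
    G = [np.outer(freqs[d], freqs[d]) for d in range(2)]
    traj = np.empty((config.n_generations + 1, 2, k))
    traj[0] = freqs
    for gen in range(1, config.n_generations + 1):
        epoch = config.epoch(gen)
        post_sel = []
        for d in range(2):
            w = config.viability_matrix(d, epoch)
            sel = G[d] * w
            wbar = sel.sum()
            if wbar <= 0:
                raise SimulationError(
                    f"mean fitness 0 in deme {d} at generation {gen}"
                )
            post_sel.append(sel.sum(axis=1) / wbar)  # gamete frequencies
        G = [
            sum(mig[d, j] * np.outer(post_sel[j], post_sel[j]) for j in range(2))
            for d in range(2)
        ]
        for d in range(2):
            traj[gen, d] = G[d].sum(axis=1)
    return traj


# ---------------------------------------------------------------------------
# expression-count generator
# ---------------------------------------------------------------------------


@dataclass
class ExpressionGroup:
    """One (site, epoch) cell of the expression design."""

    mu: float  # mean normalized expression, reads per million
    dispersion: float  # negative-binomial size parameter (larger = tighter)
    n_individuals: int
    total_reads_range: tuple[float, float]  # log-uniform bounds

    def validate(self, key: str) -> None:
        if self.mu <= 0:
            raise ValueError(f"{key}: mean expression must be > 0")
        if self.dispersion <= 0:
            raise ValueError(f"{key}: dispersion must be > 0")
        if self.n_individuals < 1:
            raise ValueError(f"{key}: need at least one individual")
        lo, hi = self.total_reads_range
        if lo < 1 or hi < lo:
            raise ValueError(f"{key}: bad total_reads_range {self.total_reads_range}")


@dataclass
class ExpressionConfig:
    """Design for per-individual mapped/total read counts."""

    groups: dict[tuple[str, str], ExpressionGroup]  # (site, epoch) -> spec
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("expression config has no groups")
        for key, grp in self.groups.items():
            grp.validate(str(key))


def generate_expression(config: ExpressionConfig):
    """Draw an expression table (one row per individual).

    ``total_reads`` is log-uniform within the configured bounds;
    ``mapped_reads`` is negative-binomial (gamma-Poisson) with mean
    ``mu * total_reads / 1e6`` and size ``dispersion``.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for (site, epoch), grp in sorted(config.groups.items()):
        lo, hi = grp.total_reads_range
        totals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=grp.n_individuals))
        totals = np.maximum(totals.astype(np.int64), 1)
        means = grp.mu * totals / 1e6
        lam = rng.gamma(shape=grp.dispersion, scale=means / grp.dispersion)
        mapped = np.minimum(rng.poisson(lam), totals)
        for i in range(grp.n_individuals):
            rows.append(
                {
                    "individual": f"{site}-{epoch}-{i + 1}",
                    "site": site,
                    "epoch": epoch,
                    "mapped_reads": int(mapped[i]),
                    "total_reads": int(totals[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# water-chemistry generator
# ---------------------------------------------------------------------------

DEFAULT_WATER_VARIABLES = ["EC", "pH", "TDS", "NO3", "NH4", "Na", "K", "Ca", "Mg", "DO"]


@dataclass
class WaterGroup:
    """One (site, epoch) cell of the water-chemistry design."""

    mean: Any  # length n_variables
    cov: Any  # (n_variables, n_variables), symmetric PSD
    years: list[int]
    replicates: int = 3

    def validate(self, key: str, n_vars: int) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (n_vars,):
            raise ValueError(f"{key}: mean must have {n_vars} entries")
        if cov.shape != (n_vars, n_vars):
            raise ValueError(f"{key}: covariance must be {n_vars}x{n_vars}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError(f"{key}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
            raise ValueError(f"{key}: covariance not positive semidefinite")
        if self.replicates < 1:
            raise ValueError(f"{key}: replicates must be >= 1")
        if not self.years:
            raise ValueError(f"{key}: at least one sampling year required")


@dataclass
class WaterConfig:
    """Design for replicate water-chemistry measurements."""

    groups: dict[tuple[str, str], WaterGroup]  # (site, epoch) -> spec
    variables: list[str] = field(default_factory=lambda: list(DEFAULT_WATER_VARIABLES))
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("water config has no groups")
        for key, grp in self.groups.items():
            grp.validate(str(key), len(self.variables))


def generate_water(config: WaterConfig):
    """Draw replicate water-chemistry rows, multivariate normal per group."""
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for (site, epoch), grp in sorted(config.groups.items()):
        mean = np.asarray(grp.mean, dtype=float)
        cov = np.asarray(grp.cov, dtype=float)
        for year in grp.years:
            draws = rng.multivariate_normal(
                mean, cov, size=grp.replicates, method="svd"
            )
            for rep in range(grp.replicates):
                row = {"site": site, "year": year, "epoch": epoch}
                row.update(
                    {v: float(draws[rep, vi]) for vi, v in enumerate(config.variables)}
                )
                rows.append(row)
    return pd.DataFrame(rows)
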