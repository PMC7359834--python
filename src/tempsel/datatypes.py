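"""Core in-memory containers shared across the package.

The unit of every population-genetic computation is the
:class:`GenotypeSample`: all diploid multi-locus genotypes collected at one
site in one sampling year.  Alleles are hashable labels — strings for the
candidate-gene haplotypes (e.g. ``"GTCGC"``) and integers (repeat numbers)
for microsatellites.  A genotype is stored as an unordered pair, normalised
so that ``allele1 <= allele2``; a genotype that failed to type is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, NamedTuple, Optional

Allele = Any  # str for the candidate locus, int for microsatellites
Genotype = Optional[tuple]  # (allele1, allele2) with allele1 <= allele2, or None

CANDIDATE = "candidate"
MICROSATELLITE = "microsatellite"

#: The four genotype categories used for the candidate gene.
FOCAL_HOMOZYGOTE = "focal_homozygote"
FOCAL_HETEROZYGOTE = "focal_heterozygote"
OTHER_HOMOZYGOTE = "other_homozygote"
OTHER_HETEROZYGOTE = "other_heterozygote"
CATEGORIES = (
    FOCAL_HOMOZYGOTE,
    FOCAL_HETEROZYGOTE,
    OTHER_HOMOZYGOTE,
    OTHER_HETEROZYGOTE,
)
#: Categories after pooling all genotypes without the focal allele.
POOLED_CATEGORIES = (FOCAL_HOMOZYGOTE, FOCAL_HETEROZYGOTE, "other")


class Locus(NamedTuple):
    name: str
    kind: str = MICROSATELLITE


def normalize_pair(pair: Iterable[Allele] | None) -> Genotype:
    """Return the unordered allele pair in canonical (sorted) storage order."""
    if pair is None:
        return None
    a, b = pair
    if a is None or b is None:
        return None
    return (a, b) if not _gt(a, b) else (b, a)


def _gt(a: Allele, b: Allele) -> bool:
    try:
        return a > b
    except TypeError:  # mixed types: order by repr, stable and total
        return repr(a) > repr(b)


@dataclass
class GenotypeSample:
    """Diploid multi-locus genotypes from one site in one sampling year."""

    site: str
    year: int
    loci: list[Locus]
    genotypes: list[list[Genotype]]  # genotypes[individual][locus_index]

    def __post_init__(self) -> None:
        if len(self.genotypes) < 1:
            raise ValueError(f"sample {self.site}/{self.year} has no individuals")
        n_loci = len(self.loci)
        for i, row in enumerate(self.genotypes):
            if len(row) != n_loci:
                raise ValueError(
                    f"individual {i} in {self.site}/{self.year} has {len(row)} "
                    f"loci, expected {n_loci}"
                )
            self.genotypes[i] = [normalize_pair(g) for g in row]

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus_index(self, locus: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == locus:
                return i
        raise KeyError(f"locus {locus!r} not in sample {self.site}/{self.year}")

    def genotypes_at(self, locus: str) -> list[Genotype]:
        idx = self.locus_index(locus)
        return [row[idx] for row in self.genotypes]

    def typed_genotypes(self, locus: str) -> list[tuple]:
        """Non-missing genotypes at *locus* (missing dropped locus-wise)."""
        return [g for g in self.genotypes_at(locus) if g is not None]

    def key(self) -> tuple[str, int]:
        return (self.site, self.year)


@dataclass
class LocusSummary:
    """Per-locus diversity summary for one sample."""

    locus: str
    n_typed: int
    n_alleles: int
    ho: float
    he: float
    fis: float | None  # None for monomorphic loci (flagged, not NaN)
    p_fis: float | None
    monomorphic: bool = False


@dataclass
class PairwiseFst:
    """Pairwise multi-locus Weir-Cockerham theta with permutation p-values."""

    labels: list[tuple[str, int]]
    theta: "Any"  # square numpy array, diagonal 0 by convention
    p_values: "Any"  # square numpy array, diagonal NaN
    n_permutations: int
    loci: list[str] = field(default_factory=list)


@dataclass
class CategoryCounts:
    """Counts of the four candidate-gene genotype categories in one sample."""

    site: str
    year: int
    focal_allele: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.counts.setdefault(cat, 0)
        bad = set(self.counts) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("category counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pooled(self) -> dict[str, int]:
        """Pool the two categories without the focal allele into ``other``."""
        return {
            FOCAL_HOMOZYGOTE: self.counts[FOCAL_HOMOZYGOTE],
            FOCAL_HETEROZYGOTE: self.counts[FOCAL_HETEROZYGOTE],
            "other": self.counts[OTHER_HOMOZYGOTE] + self.counts[OTHER_HETEROZYGOTE],
        }


@dataclass
class FitnessEstimates:
    """Genotype-survival fitness components for one site.

    For each pooled category the four values are the after/before frequency
    ratios for every (before year, after year) pair, in (b1,a1), (b1,a2),
    (b2,a1), (b2,a2) order, together with their median.
    """

    site: str
    focal_allele: str
    before_years: list[int]
    after_years: list[int]
    values: dict[str, list[float]]  # pooled category -> ratio per year pair
    medians: dict[str, float]
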