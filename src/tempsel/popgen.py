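"""Diversity statistics and Weir-Cockerham F-statistics with permutation nulls.

Estimators follow Weir & Cockerham (1984): per-allele variance components
``a`` (among samples), ``b`` (among individuals within samples) and ``c``
(within individuals), combined across alleles and loci as ratios of summed
components — not as means of per-locus ratios.  ``theta`` (F_ST) is
``sum(a) / sum(a + b + c)`` and ``f`` (F_IS) is ``1 - sum(c) / sum(b + c)``.

Permutation nulls follow the conventions of the Genetix software: F_IS is
tested by shuffling allele copies among individuals within a sample (which
destroys Hardy-Weinberg departures while preserving allele frequencies),
F_ST by permuting whole individuals between two samples (sample sizes
preserved).  Reported p-values use +1 smoothing, so they are never exactly
zero.  Missing genotypes are dropped locus-wise: an individual missing one
locus still contributes at the others.  Monomorphic loci are excluded from
all F-statistics and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeSample, LocusSummary, PairwiseFst


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _allele_codes(samples: list[GenotypeSample], locus: str) -> list:
    alleles = set()
    for s in samples:
        for g in s.typed_genotypes(locus):
            alleles.update(g)
    return sorted(alleles, key=repr)


def _encode(samples: list[GenotypeSample], locus: str):
    """Integer-encode genotypes at *locus*; missing rows are dropped.

    Returns (list of (n_i, 2) arrays, allele label list).
    """
    alleles = _allele_codes(samples, locus)
    index = {a: i for i, a in enumerate(alleles)}
    arrays = []
    for s in samples:
        typed = s.typed_genotypes(locus)
        arr = np.array([[index[a], index[b]] for a, b in typed], dtype=np.int64)
        arrays.append(arr.reshape(-1, 2))
    return arrays, alleles


# ---------------------------------------------------------------------------
# basic diversity
# ---------------------------------------------------------------------------


def allele_frequencies(sample: GenotypeSample, locus: str) -> dict:
    """Allele frequencies over typed individuals; missing data excluded."""
    typed = sample.typed_genotypes(locus)
    if not typed:
        raise PopgenError(
            f"no typed individuals at locus {locus!r} in {sample.site}/{sample.year}"
        )
    counts: dict = {}
    for a, b in typed:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(typed)
    return {a: c / total for a, c in sorted(counts.items(), key=lambda kv: repr(kv[0]))}


def heterozygosities(sample: GenotypeSample, locus: str) -> tuple[float, float]:
    """(Ho, He): observed and Nei-unbiased expected heterozygosity.

    ``He = (2n / (2n - 1)) * (1 - sum p_i^2)`` with ``n`` the number of
    typed individuals.  A monomorphic locus returns (0, 0).
    """
    typed = sample.typed_genotypes(locus)
    n = len(typed)
    if n < 2:
        raise PopgenError(
            f"need >= 2 typed individuals at {locus!r} in {sample.site}/{sample.year}"
        )
    freqs = allele_frequencies(sample, locus)
    if len(freqs) < 2:
        return 0.0, 0.0
    ho = sum(1 for a, b in typed if a != b) / n
    he = (2 * n / (2 * n - 1)) * (1.0 - sum(p * p for p in freqs.values()))
    return ho, he


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------


def _counts_from_arrays(arrays: list[np.ndarray], n_alleles: int):
    """Per-sample allele counts, heterozygote-carrier counts, typed sizes."""
    r = len(arrays)
    counts = np.zeros((r, n_alleles))
    het = np.zeros((r, n_alleles))
    n = np.zeros(r)
    for i, arr in enumerate(arrays):
        n[i] = arr.shape[0]
        if arr.shape[0] == 0:
            continue
        counts[i] = np.bincount(arr.ravel(), minlength=n_alleles)
        hz = arr[arr[:, 0] != arr[:, 1]]
        if hz.size:
            het[i] = np.bincount(hz.ravel(), minlength=n_alleles)
    return counts, het, n


def _wc_components(counts, het, n):
    """WC84 per-allele components.

    ``counts``/``het`` may be (r, k) for one dataset or (m, r, k) for a batch
    (e.g. permutations); ``n`` correspondingly (r,) or (m, r).  Returns
    (a, b, c) arrays of shape (..., k); ``a`` is zero-filled when r == 1.
    """
    counts = np.asarray(counts, dtype=float)
    het = np.asarray(het, dtype=float)
    n = np.asarray(n, dtype=float)
    r = counts.shape[-2]
    N = np.asarray(n.sum(axis=-1), dtype=float)  # (...,), 0-d for one dataset
    nbar = N / r
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / (2 * n[..., None])
        h = het / n[..., None]
    p = np.nan_to_num(p)
    h = np.nan_to_num(h)
    pbar = (n[..., None, :] @ p)[..., 0, :] / N[..., None]
    hbar = (n[..., None, :] @ h)[..., 0, :] / N[..., None]
    pq = pbar * (1 - pbar)
    if r > 1:
        s2 = ((n[..., None] * (p - pbar[..., None, :]) ** 2).sum(axis=-2)) / (
            (r - 1) * nbar[..., None]
        )
        nc = (N - (n**2).sum(axis=-1) / N) / (r - 1)
        inner = pq - (r - 1) / r * s2[..., :] - hbar / 4
        a = (nbar / nc)[..., None] * (
            s2 - inner / (nbar[..., None] - 1)
        )
        b = (nbar / (nbar - 1))[..., None] * (
            pq - (r - 1) / r * s2 - (2 * nbar - 1)[..., None] / (4 * nbar[..., None]) * hbar
        )
    else:
        a = np.zeros_like(pbar)
        b = (nbar / (nbar - 1))[..., None] * (
            pq - (2 * nbar - 1)[..., None] / (4 * nbar[..., None]) * hbar
        )
    c = hbar / 2
    return a, b, c


@dataclass
class FStatistics:
    """Per-locus and multi-locus Weir-Cockerham estimates."""

    per_locus: dict[str, dict[str, float | None]]
    f: float | None  # multi-locus F_IS
    theta: float | None  # multi-locus F_ST (None when < 2 samples)
    excluded_monomorphic: list[str] = field(default_factory=list)


def wc_f_statistics(samples, loci=None) -> FStatistics:
    """Weir-Cockerham ``f`` (F_IS) and ``theta`` (F_ST) across *samples*.

    Monomorphic loci (a single allele across the included samples) are
    excluded and listed in ``excluded_monomorphic``.  Multi-locus estimates
    weight loci by their variance components (component-sum ratios).
    """
    samples = list(samples)
    if not samples:
        raise PopgenError("need at least one sample")
    if loci is None:
        loci = samples[0].locus_names
    r = len(samples)
    per_locus: dict[str, dict[str, float | None]] = {}
    excluded = []
    tot = {"a": 0.0, "b": 0.0, "c": 0.0}
    any_poly = False
    for locus in loci:
        arrays, alleles = _encode(samples, locus)
        if len(alleles) < 2:
            excluded.append(locus)
            continue
        any_poly = True
        counts, het, n = _counts_from_arrays(arrays, len(alleles))
        a, b, c = _wc_components(counts, het, n)
        sa, sb, sc = a.sum(), b.sum(), c.sum()
        tot["a"] += sa
        tot["b"] += sb
        tot["c"] += sc
        per_locus[locus] = {
            "f": 1 - sc / (sb + sc) if (sb + sc) != 0 else None,
            "theta": (sa / (sa + sb + sc) if (sa + sb + sc) != 0 else None)
            if r > 1
            else None,
            "a": sa,
            "b": sb,
            "c": sc,
        }
    if not any_poly:
        raise PopgenError("all loci monomorphic; F-statistics undefined")
    denom_f = tot["b"] + tot["c"]
    denom_t = tot["a"] + tot["b"] + tot["c"]
    return FStatistics(
        per_locus=per_locus,
        f=1 - tot["c"] / denom_f if denom_f != 0 else None,
        theta=(tot["a"] / denom_t if denom_t != 0 else None) if r > 1 else None,
        excluded_monomorphic=excluded,
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _perm_matrix(rng, n_perm: int, n: int) -> np.ndarray:
    """(n_perm, n) array of uniformly random permutations of range(n)."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def permutation_test_fis(
    sample: GenotypeSample,
    locus: str | None = None,
    n_perm: int = 5000,
    seed=None,
    tail: str = "deficit",
) -> float:
    """Permutation p-value for Hardy-Weinberg departure via WC ``f``.

    The null is built by shuffling allele copies among individuals within
    the sample, independently at each locus.  ``tail='deficit'`` (default,
    the heterozygote-deficit direction Genetix reports) counts permutations
    with ``f_perm >= f_obs``; ``tail='two-sided'`` compares ``|f|``.
    """
    if n_perm < 1:
        raise PopgenError("n_perm must be >= 1")
    if tail not in ("deficit", "two-sided"):
        raise PopgenError(f"unknown tail {tail!r}")
    loci = [locus] if locus is not None else sample.locus_names
    rng = np.random.default_rng(seed)
    b_obs = c_obs = 0.0
    b_perm = np.zeros(n_perm)
    c_perm = np.zeros(n_perm)
    any_poly = False
    for loc in loci:
        arrays, alleles = _encode([sample], loc)
        k = len(alleles)
        if k < 2:
            continue
        any_poly = True
        arr = arrays[0]
        n = arr.shape[0]
        counts, het, nn = _counts_from_arrays([arr], k)
        a, b, c = _wc_components(counts, het, nn)
        b_obs += b.sum()
        c_obs += c.sum()
        flat = arr.ravel()
        perms = _perm_matrix(rng, n_perm, flat.size)
        shuffled = flat[perms].reshape(n_perm, n, 2)
        het_mask = shuffled[:, :, 0] != shuffled[:, :, 1]  # (n_perm, n)
        hcounts = np.zeros((n_perm, 1, k))
        for allele in range(k):
            carrier = (shuffled[:, :, 0] == allele) | (shuffled[:, :, 1] == allele)
            hcounts[:, 0, allele] = (het_mask & carrier).sum(axis=1)
        ccounts = np.broadcast_to(counts[None, :, :], (n_perm, 1, k))
        nns = np.broadcast_to(nn[None, :], (n_perm, 1))
        pa, pb, pc = _wc_components(ccounts, hcounts, nns)
        b_perm += pb.sum(axis=(1, 2)) if pb.ndim == 3 else pb.sum(axis=-1)
        c_perm += pc.sum(axis=(1, 2)) if pc.ndim == 3 else pc.sum(axis=-1)
    if not any_poly:
        raise PopgenError("F_IS permutation test requires a polymorphic locus")
    f_obs = 1 - c_obs / (b_obs + c_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = 1 - c_perm / (b_perm + c_perm)
    f_perm = np.nan_to_num(f_perm)
    if tail == "deficit":
        hits = int((f_perm >= f_obs - 1e-12).sum())
    else:
        hits = int((np.abs(f_perm) >= abs(f_obs) - 1e-12).sum())
    return (hits + 1) / (n_perm + 1)


def _pair_theta_batches(sample_a, sample_b, loci, membership):
    """Multi-locus theta for each row of *membership*.

    ``membership`` is a boolean (m, N) matrix assigning each of the pooled
    individuals to sample A; sizes are fixed by construction.  Loci where a
    permuted sample has no typed individual contribute nothing for that row.
    """
    m = membership.shape[0]
    num = np.zeros(m)
    den = np.zeros(m)
    used_locus = False
    for locus in loci:
        arrays, alleles = _encode([sample_a, sample_b], locus)
        k = len(alleles)
        if k < 2:
            continue
        used_locus = True
        # pooled per-individual matrices, ordered A then B over *typed* rows —
        # membership indexes pooled individuals, so expand to genotype slots
        full_a = sample_a.genotypes_at(locus)
        full_b = sample_b.genotypes_at(locus)
        pooled = full_a + full_b
        idx = {a: i for i, a in enumerate(alleles)}
        N = len(pooled)
        C = np.zeros((N, k))
        H = np.zeros((N, k))
        typed = np.zeros(N)
        for i, g in enumerate(pooled):
            if g is None:
                continue
            typed[i] = 1.0
            C[i, idx[g[0]]] += 1
            C[i, idx[g[1]]] += 1
            if g[0] != g[1]:
                H[i, idx[g[0]]] += 1
                H[i, idx[g[1]]] += 1
        memb = membership.astype(float)
        cA = memb @ C
        hA = memb @ H
        nA = memb @ typed
        cB = C.sum(axis=0) - cA
        hB = H.sum(axis=0) - hA
        nB = typed.sum() - nA
        counts = np.stack([cA, cB], axis=1)  # (m, 2, k)
        het = np.stack([hA, hB], axis=1)
        nn = np.stack([nA, nB], axis=1)  # (m, 2)
        valid = (nn >= 1).all(axis=1) & (nn.sum(axis=1) >= 3)
        a, b, c = _wc_components(counts, het, nn)
        contrib_num = a.sum(axis=-1)
        contrib_den = (a + b + c).sum(axis=-1)
        num += np.where(valid, contrib_num, 0.0)
        den += np.where(valid, contrib_den, 0.0)
    if not used_locus:
        raise PopgenError("no shared polymorphic locus between the two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = num / den
    return np.nan_to_num(theta)


def pair_theta(sample_a, sample_b, loci=None) -> float:
    """Multi-locus WC theta between two samples."""
    if loci is None:
        loci = [l for l in sample_a.locus_names if l in sample_b.locus_names]
    nA = sample_a.n_individuals
    N = nA + sample_b.n_individuals
    membership = np.zeros((1, N), dtype=bool)
    membership[0, :nA] = True
    return float(_pair_theta_batches(sample_a, sample_b, loci, membership)[0])


def permutation_test_fst(
    sample_a: GenotypeSample,
    sample_b: GenotypeSample,
    loci=None,
    n_perm: int = 1000,
    seed=None,
) -> float:
    """One-tailed permutation p-value for differentiation between two samples.

    The null permutes whole individuals between the samples (sizes
    preserved); ``p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise PopgenError("n_perm must be >= 1")
    if loci is None:
        loci = [l for l in sample_a.locus_names if l in sample_b.locus_names]
    if not loci:
        raise PopgenError("no shared loci between the two samples")
    rng = np.random.default_rng(seed)
    nA = sample_a.n_individuals
    N = nA + sample_b.n_individuals
    obs_memb = np.zeros((1, N), dtype=bool)
    obs_memb[0, :nA] = True
    theta_obs = _pair_theta_batches(sample_a, sample_b, loci, obs_memb)[0]
    perms = _perm_matrix(rng, n_perm, N)
    membership = perms < nA  # uniformly random subsets of size nA
    theta_perm = _pair_theta_batches(sample_a, sample_b, loci, membership)
    hits = int((theta_perm >= theta_obs - 1e-12).sum())
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# report-level wrappers
# ---------------------------------------------------------------------------


def locus_summaries(
    sample: GenotypeSample, n_perm: int = 5000, seed=None, tail: str = "deficit"
) -> list[LocusSummary]:
    """Per-locus diversity and F_IS summary for one sample."""
    rng = np.random.default_rng(seed)
    out = []
    for locus in sample.locus_names:
        typed = sample.typed_genotypes(locus)
        freqs = allele_frequencies(sample, locus) if typed else {}
        n_alleles = len(freqs)
        if n_alleles < 2:
            out.append(
                LocusSummary(
                    locus=locus,
                    n_typed=len(typed),
                    n_alleles=n_alleles,
                    ho=0.0,
                    he=0.0,
                    fis=None,
                    p_fis=None,
                    monomorphic=True,
                )
            )
            continue
        ho, he = heterozygosities(sample, locus)
        stats = wc_f_statistics([sample], [locus])
        p = permutation_test_fis(
            sample, locus, n_perm=n_perm, seed=rng.integers(2**31), tail=tail
        )
        out.append(
            LocusSummary(
                locus=locus,
                n_typed=len(typed),
                n_alleles=n_alleles,
                ho=ho,
                he=he,
                fis=stats.f,
                p_fis=p,
            )
        )
    return out


def pairwise_fst(
    samples: list[GenotypeSample], loci=None, n_perm: int = 1000, seed=None
) -> PairwiseFst:
    """All pairwise multi-locus theta values with permutation p-values."""
    rng = np.random.default_rng(seed)
    m = len(samples)
    theta = np.zeros((m, m))
    pvals = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            t = pair_theta(samples[i], samples[j], loci)
            p = permutation_test_fst(
                samples[i], samples[j], loci, n_perm=n_perm, seed=rng.integers(2**31)
            )
            theta[i, j] = theta[j, i] = t
            pvals[i, j] = pvals[j, i] = p
    return PairwiseFst(
        labels=[s.key() for s in samples],
        theta=theta,
        p_values=pvals,
        n_permutations=n_perm,
        loci=list(loci) if loci is not None else [],
    )
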