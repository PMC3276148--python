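"""Between-species divergence: shared/fixed/private polymorphism
classification, Hudson's F_ST with a permutation test, and per-SNP exact
tests of Hardy-Weinberg equilibrium.

F_ST is the Hudson estimator 1 - H_w/H_b (mean within-species pairwise
difference over mean between-species pairwise difference), used both for
observed data and as the two-population ABC summary statistic.  The
hierarchical AMOVA of the original analysis is replaced by this estimator;
the permutation logic (individuals permuted across species, both haplotypes
moving together) preserves the significance test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .diversity import site_allele_counts


@dataclass
class DivergenceStats:
    L: int
    n1: int
    n2: int
    S1: int
    S2: int
    shared: int
    fixed: int
    private1: int
    private2: int
    fst: float = math.nan
    p_perm: float = math.nan


def classify_polymorphisms(aln1: Alignment, aln2: Alignment) -> DivergenceStats:
    """Per-column classification of variation in two species sampled over
    identical alignment columns.

    shared: segregating in both species; fixed: monomorphic in both but for
    different bases; private: segregating in exactly one species.
    """
    if aln1.L != aln2.L:
        raise ValueError("alignments must cover identical columns")
    c1 = site_allele_counts(aln1)
    c2 = site_allele_counts(aln2)
    seg1 = (c1 > 0).sum(axis=1) >= 2
    seg2 = (c2 > 0).sum(axis=1) >= 2
    mono_base1 = np.argmax(c1, axis=1)
    mono_base2 = np.argmax(c2, axis=1)
    fixed = (~seg1) & (~seg2) & (mono_base1 != mono_base2)
    shared = seg1 & seg2
    private1 = seg1 & ~seg2
    private2 = seg2 & ~seg1
    return DivergenceStats(
        L=aln1.L,
        n1=aln1.n,
        n2=aln2.n,
        S1=int(seg1.sum()),
        S2=int(seg2.sum()),
        shared=int(shared.sum()),
        fixed=int(fixed.sum()),
        private1=int(private1.sum()),
        private2=int(private2.sum()),
    )


def _mean_pairwise_within(counts: np.ndarray, n: int) -> float:
    n_pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=1)
    return float(((n_pairs - same) / n_pairs).sum())


def _mean_pairwise_between(c1: np.ndarray, c2: np.ndarray, n1: int, n2: int) -> float:
    same = (c1 * c2).sum(axis=1)
    return float(((n1 * n2 - same) / (n1 * n2)).sum())


def hudson_fst(aln1: Alignment, aln2: Alignment) -> float:
    """Hudson's F_ST = 1 - H_w / H_b.

    H_w is the unweighted mean of the two within-species mean pairwise
    difference counts and H_b the between-species mean pairwise difference
    count (both totalled over sites).  NaN when H_b = 0.
    """
    if aln1.n < 2 or aln2.n < 2:
        raise ValueError("each species needs n >= 2 haplotypes")
    c1 = site_allele_counts(aln1)
    c2 = site_allele_counts(aln2)
    return _fst_from_counts(c1, c2, aln1.n, aln2.n)


def _fst_from_counts(c1, c2, n1, n2) -> float:
    hw = 0.5 * (_mean_pairwise_within(c1, n1) + _mean_pairwise_within(c2, n2))
    hb = _mean_pairwise_between(c1, c2, n1, n2)
    if hb == 0:
        return math.nan
    return 1.0 - hw / hb


def fst_permutation_test(
    aln1: Alignment,
    aln2: Alignment,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation significance of the observed F_ST.

    Individuals (haplotype pairs: consecutive rows) are permuted across
    species labels; p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    Returns (F_obs, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if aln1.n % 2 or aln2.n % 2:
        raise ValueError("haplotype counts must be even (diploid individuals)")
    f_obs = hudson_fst(aln1, aln2)
    if math.isnan(f_obs):
        return f_obs, 1.0
    pooled = np.vstack([aln1.sequences, aln2.sequences])
    n_ind1 = aln1.n // 2
    n_ind = (aln1.n + aln2.n) // 2
    count = 0
    ids = [f"h{i}" for i in range(pooled.shape[0])]
    for _ in range(n_perm):
        perm = rng.permutation(n_ind)
        rows1 = ((2 * perm[:n_ind1])[:, None] + np.array([0, 1])).ravel()
        rows2 = ((2 * perm[n_ind1:])[:, None] + np.array([0, 1])).ravel()
        a1 = Alignment(pooled[rows1], [ids[r] for r in rows1])
        a2 = Alignment(pooled[rows2], [ids[r] for r in rows2])
        if hudson_fst(a1, a2) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (n_perm + 1)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Exact conditional test of Hardy-Weinberg equilibrium for a biallelic
    SNP from genotype counts.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of configurations no more
    probable than the observed one.  Returns (p, direction) where direction
    is observed minus expected heterozygosity (negative = heterozygote
    deficit, the usual signature of inbreeding or partial selfing).
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0, 0.0
    rare = min(nA, na)
    probs = {}
    # heterozygote count has the parity of the rare allele count
    for het in range(rare % 2, rare + 1, 2):
        homo_rare = (rare - het) // 2
        homo_common = (max(nA, na) - het) // 2
        logp = (
            _lfact(n)
            - _lfact(homo_rare)
            - _lfact(homo_common)
            - _lfact(het)
            + het * math.log(2.0)
            + _lfact(nA)
            + _lfact(na)
            - _lfact(2 * n)
        )
        probs[het] = math.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    exp_het = nA * na / (2.0 * n - 1.0) / n  # E[het] under HWE (conditional)
    direction = n_Aa / n - exp_het
    return min(p, 1.0), direction


def _lfact(k: int) -> float:
    return math.lgamma(k + 1)
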