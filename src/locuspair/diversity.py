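"""Per-segment nucleotide diversity statistics.

Implements the classical per-segment estimators: segregating sites and
singletons, Watterson's theta, pairwise nucleotide diversity (pi),
Tajima's D, haplotype number and diversity, and synonymous/nonsynonymous
site counting and diversity by the Nei-Gojobori (1986) pathway method.

All per-site estimators use the uncorrected (no Jukes-Cantor) formulas and
divide pi by C(n,2); multi-allelic columns count once in S.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .alignment import Alignment

# ---------------------------------------------------------------------------
# allele-count machinery


def _to_codes(aln: Alignment) -> np.ndarray:
    """Map an A/C/G/T character matrix to small integer codes."""
    lut = np.zeros(128, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[aln.sequences.view(np.uint32).astype(np.int64) & 0x7F]


def site_allele_counts(aln: Alignment) -> np.ndarray:
    """(L, 4) matrix of allele counts per column, order A,C,G,T."""
    codes = _to_codes(aln)
    counts = np.zeros((aln.L, 4), dtype=np.int64)
    for a in range(4):
        counts[:, a] = (codes == a).sum(axis=0)
    return counts


def segregating_sites(aln: Alignment) -> tuple[int, int, np.ndarray]:
    """Return (S, n_singleton, per-site allele counts).

    A column is segregating when >=2 distinct bases occur (multi-allelic
    columns count once); it contains a singleton when some allele occurs
    exactly once.
    """
    counts = site_allele_counts(aln)
    n_alleles = (counts > 0).sum(axis=1)
    seg = n_alleles >= 2
    has_singleton = seg & (counts == 1).any(axis=1)
    return int(seg.sum()), int(has_singleton.sum()), counts


@lru_cache(maxsize=None)
def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator per site: theta = S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2 haplotypes")
    if L < 1:
        raise ValueError("L must be >= 1")
    return S / (harmonic(n - 1) * L)


def mean_pairwise_differences(counts: np.ndarray, n: int) -> float:
    """Average number of pairwise differences (Pi, totalled over sites)
    from per-site allele counts; handles multi-allelic sites naturally."""
    n_pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=1)
    return float(((n_pairs - same) / n_pairs).sum())


def nucleotide_diversity(aln: Alignment) -> float:
    """Pairwise nucleotide diversity pi per site."""
    if aln.n < 2:
        raise ValueError("pi requires n >= 2")
    counts = site_allele_counts(aln)
    return mean_pairwise_differences(counts, aln.n) / aln.L


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> tuple[float, float]:
    """Tajima (1989) normalizing coefficients (e1, e2) for sample size n."""
    a1 = harmonic(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajimas_d_from_counts(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating-site count and the total
    (per-locus, not per-site) mean pairwise difference."""
    if S < 1:
        return math.nan
    a1 = harmonic(n - 1)
    e1, e2 = tajima_constants(n)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    return (pi_total - S / a1) / denom


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D; NaN when the alignment has no segregating site."""
    S, _, counts = segregating_sites(aln)
    if S == 0:
        return math.nan
    return tajimas_d_from_counts(aln.n, S, mean_pairwise_differences(counts, aln.n))


def haplotype_stats(aln: Alignment) -> tuple[int, float]:
    """(N_h, H_e): number of distinct haplotypes and haplotype diversity
    H_e = n/(n-1) (1 - sum p_k^2)."""
    if aln.n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    _, freq = np.unique(aln.sequences, axis=0, return_counts=True)
    n = aln.n
    p = freq / n
    he = n / (n - 1.0) * (1.0 - float((p**2).sum()))
    return int(len(freq)), he


@dataclass
class SegmentStats:
    """One diversity-table row for a gene segment."""

    n: int
    L: int
    S: int
    n_singleton: int
    theta_per_site: float
    pi_per_site: float
    N_h: int
    H_e: float
    tajima_D: float  # NaN when S == 0


def segment_stats(aln: Alignment) -> SegmentStats:
    S, n_single, counts = segregating_sites(aln)
    pi_total = mean_pairwise_differences(counts, aln.n)
    nh, he = haplotype_stats(aln)
    return SegmentStats(
        n=aln.n,
        L=aln.L,
        S=S,
        n_singleton=n_single,
        theta_per_site=watterson_theta(S, aln.n, aln.L),
        pi_per_site=pi_total / aln.L,
        N_h=nh,
        H_e=he,
        tajima_D=tajimas_d_from_counts(aln.n, S, pi_total) if S else math.nan,
    )


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous sites (Nei & Gojobori 1986)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


def codon_syn_sites(codon: str) -> float:
    """Fraction-weighted count of synonymous sites in one codon: each
    position contributes (# synonymous single-base changes)/3."""
    aa = CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon}")
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn


def classify_codon_sites(aln: Alignment) -> tuple[float, float]:
    """(L_syn, L_nonsyn) by Nei-Gojobori site counting, averaged over all
    haplotypes of a coding alignment (whose coding_mask marks codon phases
    0,1,2 over an in-frame region of length divisible by 3)."""
    codons_per_hap = _extract_codons(aln)
    n_codons = len(codons_per_hap[0])
    syn_tot = 0.0
    for hap_idx, codons in enumerate(codons_per_hap):
        for ci, codon in enumerate(codons):
            if CODON_TABLE[codon] == "*":
                raise ValueError(
                    f"internal stop codon at codon {ci + 1} in haplotype {hap_idx}"
                )
            syn_tot += codon_syn_sites(codon)
    L_syn = syn_tot / len(codons_per_hap)
    return L_syn, 3.0 * n_codons - L_syn


def _extract_codons(aln: Alignment) -> list[list[str]]:
    if aln.coding_mask is None:
        raise ValueError("alignment lacks a coding_mask")
    coding = np.flatnonzero(aln.coding_mask >= 0)
    if coding.size == 0 or coding.size % 3:
        raise ValueError("coding region length must be a positive multiple of 3")
    phases = aln.coding_mask[coding]
    if not np.array_equal(phases, np.tile([0, 1, 2], coding.size // 3)):
        raise ValueError("coding_mask phases must run 0,1,2 per codon")
    sub = aln.sequences[:, coding]
    return [
        ["".join(row[i:i + 3]) for i in range(0, coding.size, 3)]
        for row in sub
    ]


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over all stop-free minimal
    mutational pathways between two codons (equal pathway weighting)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*":
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nsyn))
    if not results:
        warnings.warn(
            f"no stop-free pathway between codons {c1} and {c2}; pair skipped"
        )
        return 0.0, 0.0
    s = sum(r[0] for r in results) / len(results)
    a = sum(r[1] for r in results) / len(results)
    return s, a


@dataclass
class CodingStats:
    """Synonymous/nonsynonymous diversity for one coding segment."""

    n: int
    L_syn: float
    L_nonsyn: float
    S_syn: int
    S_nonsyn: int
    theta_syn: float
    theta_nonsyn: float
    pi_syn: float
    pi_nonsyn: float


def syn_nonsyn_diversity(aln: Alignment) -> CodingStats:
    """Classify coding-region variation into synonymous and nonsynonymous
    components and compute theta and pi per syn/nonsyn site.

    Segregating coding sites are attributed via Nei-Gojobori pathway
    counting between observed codon alleles; pairwise differences are
    likewise split per codon pair and summed over all haplotype pairs.
    """
    codons_per_hap = _extract_codons(aln)
    n = len(codons_per_hap)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    L_syn, L_nonsyn = classify_codon_sites(aln)
    n_codons = len(codons_per_hap[0])

    # per-codon allele counts
    S_syn = 0.0
    S_nonsyn = 0.0
    pi_syn_tot = 0.0
    pi_nonsyn_tot = 0.0
    n_pairs = n * (n - 1) / 2.0
    for ci in range(n_codons):
        alleles: dict[str, int] = {}
        for codons in codons_per_hap:
            alleles[codons[ci]] = alleles.get(codons[ci], 0) + 1
        keys = list(alleles)
        if len(keys) == 1:
            continue
        # site classification: count syn/nonsyn changes along pathways of
        # each distinct codon pair once per polymorphic position
        seg_positions = {
            i for a in keys for b in keys for i in range(3) if a[i] != b[i]
        }
        # attribute each segregating position syn-or-nonsyn by the average
        # over allele pairs differing there (a site with a 1-step syn change
        # in one pair and nonsyn in another is split fractionally)
        syn_frac = {i: [] for i in seg_positions}
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                a, b = keys[x], keys[y]
                diff = [i for i in range(3) if a[i] != b[i]]
                s, ns = _pathway_counts(a, b)
                tot = s + ns
                if tot == 0:
                    continue
                for i in diff:
                    syn_frac[i].append(s / tot)
        for i in seg_positions:
            if syn_frac[i]:
                f = sum(syn_frac[i]) / len(syn_frac[i])
            else:
                f = 0.0
            S_syn += f
            S_nonsyn += 1.0 - f
        # pairwise-difference split
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                a, b = keys[x], keys[y]
                s, ns = _pathway_counts(a, b)
                w = alleles[a] * alleles[b]
                pi_syn_tot += s * w
                pi_nonsyn_tot += ns * w
    pi_syn_tot /= n_pairs
    pi_nonsyn_tot /= n_pairs
    a1 = harmonic(n - 1)
    return CodingStats(
        n=n,
        L_syn=L_syn,
        L_nonsyn=L_nonsyn,
        S_syn=int(round(S_syn)),
        S_nonsyn=int(round(S_nonsyn)),
        theta_syn=S_syn / (a1 * L_syn) if L_syn > 0 else 0.0,
        theta_nonsyn=S_nonsyn / (a1 * L_nonsyn) if L_nonsyn > 0 else 0.0,
        pi_syn=pi_syn_tot / L_syn if L_syn > 0 else 0.0,
        pi_nonsyn=pi_nonsyn_tot / L_nonsyn if L_nonsyn > 0 else 0.0,
    )


def snp_density(L: float, S: int) -> int:
    """The '1 SNP every k bp' summary: round(L / S)."""
    if S <= 0:
        raise ValueError("no SNPs")
    return int(round(L / S))
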