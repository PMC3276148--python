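"""Linkage disequilibrium: pairwise r-squared, Fisher-exact significance
with Bonferroni correction, and least-squares estimation of the population
recombination parameter rho from the decay of r-squared with distance.

The decay fit uses the Hill & Weir (1988) sample-size-adjusted expectation

    E[r^2] = (10+C)/((2+C)(11+C)) * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]

with C = rho * distance, the formula behind the standard nonlinear-
regression procedure for LD decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .alignment import Alignment
from .diversity import site_allele_counts


@dataclass
class LDPair:
    site_i: int  # bp position, gene coordinates (1-based in reports)
    site_j: int
    dist_bp: int
    r2: float
    p_fisher: float
    significant: bool = False


def biallelic_sites(aln: Alignment, maf_min: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Columns that are strictly biallelic with minor allele frequency
    above ``maf_min``.  Returns (site indices, minor-allele boolean matrix
    of shape n x n_sites: True where the haplotype carries the minor
    allele)."""
    counts = site_allele_counts(aln)
    n = aln.n
    n_alleles = (counts > 0).sum(axis=1)
    keep = n_alleles == 2
    maf = np.where(keep, np.sort(counts, axis=1)[:, -2] / n, 0.0)
    keep &= maf > maf_min
    sites = np.flatnonzero(keep)
    lut = np.zeros(128, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[aln.sequences.view(np.uint32).astype(np.int64) & 0x7F]
    minor = np.zeros((n, sites.size), dtype=bool)
    for k, s in enumerate(sites):
        minor_allele = int(np.argsort(counts[s])[-2])
        minor[:, k] = codes[:, s] == minor_allele
    return sites, minor


def r2_from_haplotypes(x: np.ndarray, y: np.ndarray) -> float:
    """Squared allelic correlation r^2 = D^2 / (pA pa pB pb) for two binary
    haplotype vectors."""
    n = len(x)
    pA = x.mean()
    pB = y.mean()
    fAB = (x & y).sum() / n
    D = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        return math.nan
    return D * D / denom


def fisher_association(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Fisher exact p for the 2x2 haplotype table of two sites."""
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def pairwise_r2(
    aln: Alignment,
    positions: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> list[LDPair]:
    """All pairwise LD measures among retained biallelic SNPs.

    ``positions`` maps alignment columns to physical bp coordinates (gene
    coordinates, so distances across paired segments include the
    inter-segment gap); defaults to the column index.
    """
    sites, minor = biallelic_sites(aln, maf_min)
    if sites.size < 2:
        return []
    if positions is None:
        positions = np.arange(aln.L)
    pairs: list[LDPair] = []
    for i in range(sites.size):
        for j in range(i + 1, sites.size):
            pi, pj = int(positions[sites[i]]), int(positions[sites[j]])
            pairs.append(
                LDPair(
                    site_i=pi,
                    site_j=pj,
                    dist_bp=abs(pj - pi),
                    r2=r2_from_haplotypes(minor[:, i], minor[:, j]),
                    p_fisher=fisher_association(minor[:, i], minor[:, j]),
                )
            )
    return pairs


def bonferroni(pvals: list[float], alpha: float = 0.05) -> list[bool]:
    """Family-wise flags: p < alpha / m with m the family size (the number
    of pairwise comparisons actually tested)."""
    m = len(pvals)
    if m == 0:
        return []
    thresh = alpha / m
    return [p < thresh for p in pvals]


def annotate_significance(pairs: list[LDPair], alpha: float = 0.05) -> list[LDPair]:
    flags = bonferroni([p.p_fisher for p in pairs], alpha)
    for pair, f in zip(pairs, flags):
        pair.significant = f
    return pairs


def hill_weir_expectation(C: np.ndarray | float, n: int) -> np.ndarray | float:
    """Expected r^2 under drift-recombination equilibrium, adjusted for
    sample size n (Hill & Weir 1988)."""
    C = np.asarray(C, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = term1 * term2
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    rho_per_bp: float
    n: int
    rss: float
    n_pairs: int
    crossing_bp_r2_02: float  # distance at which the fitted curve crosses 0.2


def fit_rho_decay(pairs: list[LDPair], n: int) -> DecayFit:
    """Nonlinear least squares of observed r^2 on the Hill-Weir curve
    E[r^2](rho * dist), optimized over log10(rho) from a restart grid to
    avoid the rho = 0 boundary."""
    pairs = [p for p in pairs if not math.isnan(p.r2)]
    if len(pairs) < 5:
        raise ValueError("need >= 5 pairs for a decay fit")
    dist = np.array([p.dist_bp for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs], dtype=float)
    if np.unique(dist).size < 2:
        raise ValueError("all pair distances equal; rho is not identifiable")

    def resid(log_rho: np.ndarray) -> np.ndarray:
        # clamp: the LM steps are unbounded, the curve is flat outside
        rho = 10.0 ** float(np.clip(log_rho[0], -12.0, 6.0))
        return hill_weir_expectation(rho * dist, n) - r2

    best = None
    for start in (-5.0, -4.0, -3.0, -2.0, -1.0, 0.0):
        sol = optimize.least_squares(resid, x0=[start], method="lm")
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1] - 1e-12:
            best = (float(sol.x[0]), rss)
    if best is None or not math.isfinite(best[1]):
        raise RuntimeError("decay fit failed to converge from all restarts")
    rho = 10.0 ** float(np.clip(best[0], -12.0, 6.0))

    # distance where fitted curve crosses r^2 = 0.2
    def f(d: float) -> float:
        return float(hill_weir_expectation(rho * d, n)) - 0.2

    if f(0.0) <= 0:
        crossing = 0.0
    else:
        hi = 10.0
        while f(hi) > 0 and hi < 1e12:
            hi *= 10.0
        crossing = (
            math.inf if f(hi) > 0 else float(optimize.brentq(f, 1e-9, hi))
        )
    return DecayFit(
        rho_per_bp=rho, n=n, rss=best[1], n_pairs=len(pairs), crossing_bp_r2_02=crossing
    )


def plot_decay(pairs: list[LDPair], fit: DecayFit, path: str) -> None:
    """Scatter of r^2 against distance with the fitted decay curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = [p.dist_bp for p in pairs if not math.isnan(p.r2)]
    r2 = [p.r2 for p in pairs if not math.isnan(p.r2)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(dist, r2, s=8, alpha=0.4, color="gray")
    grid = np.linspace(1, max(dist), 300)
    ax.plot(grid, hill_weir_expectation(fit.rho_per_bp * grid, fit.n),
            color="black")
    ax.axhline(0.2, ls=":", color="black", lw=0.8)
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"$r^2$")
    ax.set_title(f"LD decay, rho = {fit.rho_per_bp:.2e}/bp")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
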