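"""ms-style neutral coalescent simulation under four demographic models.

Models: constant-size neutral, exponential growth, instantaneous
bottleneck, and a two-population split with optional symmetric migration
and an ancestral size change (plus the degenerate no-split variant used as
a null model in species-divergence inference).

Conventions match ms: time in units of 4*N0 generations; theta = 4*N0*mu
and rho = 4*N0*r are per site and scaled by the locus length L; mutations
follow the infinite-sites model, output as a binary haplotype matrix with
positions in (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .diversity import harmonic, tajimas_d_from_counts

_PLANE_BITS = _kernel._PLANE_BITS


# ---------------------------------------------------------------------------
# parameter sets


@dataclass
class NeutralParams:
    """Constant-size model: theta = 4 N0 mu and rho = 4 N0 r, per site."""

    theta: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    def _epochs(self):
        return _epochs(starts=[0.0], sizes=[(1.0, 1.0)], grows=[(0.0, 0.0)],
                       migs=[0.0], merges=[0])


@dataclass
class GrowthParams(NeutralParams):
    """Exponential growth: backward in time the size is exp(-alpha t)."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def _epochs(self):
        return _epochs(starts=[0.0], sizes=[(1.0, 1.0)],
                       grows=[(self.alpha, 0.0)], migs=[0.0], merges=[0])


@dataclass
class BottleneckParams(NeutralParams):
    """Instantaneous bottleneck: size drops to f*N0 on (t_b, t_b + d),
    backward in time, and is N0 otherwise.  Severity f defaults to the
    fixed study value 0.02."""

    t_b: float = 0.1
    d: float = 0.1
    f: float = 0.02

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.t_b < 0 or self.d < 0:
            raise ValueError("t_b and d must be >= 0")
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")

    def _epochs(self):
        if self.d == 0:
            return NeutralParams(self.theta, self.rho)._epochs()
        return _epochs(
            starts=[0.0, self.t_b, self.t_b + self.d],
            sizes=[(1.0, 1.0), (self.f, 1.0), (1.0, 1.0)],
            grows=[(0.0, 0.0)] * 3,
            migs=[0.0] * 3,
            merges=[0, 0, 0],
        )


@dataclass
class SplitParams:
    """Two-population split: demes of relative sizes 1 and N2 exchanging
    migrants at per-lineage rate M (= 4 N0 m) merge at time t_s into an
    ancestral deme of relative size N_anc."""

    theta: float
    rho: float = 0.0
    N2: float = 1.0
    N_anc: float = 1.0
    M: float = 0.0
    t_s: float = 1.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.N2 <= 0 or self.N_anc <= 0:
            raise ValueError("relative sizes must be > 0")
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.t_s < 0:
            raise ValueError("t_s must be >= 0")

    def _epochs(self):
        if self.t_s == 0:
            return _epochs(starts=[0.0], sizes=[(self.N_anc, 1.0)],
                           grows=[(0.0, 0.0)], migs=[0.0], merges=[0],
                           merge_now=True)
        return _epochs(
            starts=[0.0, self.t_s],
            sizes=[(1.0, self.N2), (self.N_anc, 1.0)],
            grows=[(0.0, 0.0)] * 2,
            migs=[self.M, 0.0],
            merges=[0, 1],
        )


@dataclass
class NoSplitParams(SplitParams):
    """Null model for species divergence: one panmictic population whose
    size changes to N_anc at t_s; both samples are drawn from it."""

    def _epochs(self):
        if self.t_s == 0:
            return _epochs(starts=[0.0], sizes=[(self.N_anc, 1.0)],
                           grows=[(0.0, 0.0)], migs=[0.0], merges=[0],
                           merge_now=True)
        return _epochs(
            starts=[0.0, self.t_s],
            sizes=[(1.0, 1.0), (self.N_anc, 1.0)],
            grows=[(0.0, 0.0)] * 2,
            migs=[0.0, 0.0],
            merges=[0, 1],
        )

    @property
    def panmictic(self) -> bool:
        return True


def _epochs(starts, sizes, grows, migs, merges, merge_now=False):
    return (
        np.asarray(starts, dtype=np.float64),
        np.asarray(sizes, dtype=np.float64),
        np.asarray(grows, dtype=np.float64),
        np.asarray(migs, dtype=np.float64),
        np.asarray(merges, dtype=np.int64),
        merge_now,
    )


@dataclass
class LocusSpec:
    """Sample sizes (haplotypes per population) and locus length in bp."""

    n_per_pop: tuple[int, ...]
    L: int

    def __post_init__(self) -> None:
        if sum(self.n_per_pop) < 2:
            raise ValueError("total sample size must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if sum(self.n_per_pop) > 2 * _PLANE_BITS:
            raise ValueError(f"at most {2 * _PLANE_BITS} haplotypes supported")


@dataclass
class HaplotypeMatrix:
    """Infinite-sites output: binary (haplotypes x segregating sites)
    matrix, positions in (0,1) scaled to L, and population labels."""

    matrix: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    L: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# simulation


def simulate_locus(params, locus: LocusSpec, rng: np.random.Generator) -> HaplotypeMatrix:
    """Simulate one locus under the given demographic parameter set.

    ``params`` is one of NeutralParams, GrowthParams, BottleneckParams,
    SplitParams or NoSplitParams.  Single-population parameter sets expect
    a one-population LocusSpec; split models place samples in two demes
    (the no-split null draws both samples from one deme but keeps labels).
    """
    ep_start, ep_size, ep_grow, ep_mig, ep_merge, merge_now = params._epochs()
    n_pops = len(locus.n_per_pop)
    labels = np.repeat(np.arange(n_pops), locus.n_per_pop)
    if isinstance(params, SplitParams):
        if n_pops != 2:
            raise ValueError("split models need two sample sizes")
        panmictic = getattr(params, "panmictic", False) or merge_now
        sample_pop = np.zeros(labels.size, dtype=np.int64) if panmictic else labels.astype(np.int64)
    else:
        if n_pops != 1:
            raise ValueError("single-population models need one sample size")
        sample_pop = np.zeros(labels.size, dtype=np.int64)

    n = labels.size
    L = locus.L
    theta_site = params.theta
    rho_site = params.rho
    max_lin = 2 * n + 64 + int(8 * rho_site * L)
    mut_cap = max(512, int(12 * theta_site * L * (harmonic(n - 1) + 4.0)))
    while True:
        sites, m0, m1, status = _kernel.simulate_kernel(
            rng, n, sample_pop, L, theta_site, rho_site,
            len(ep_start), ep_start, ep_size, ep_grow, ep_mig, ep_merge,
            max_lin, mut_cap,
        )
        if status == _kernel.STATUS_OK:
            break
        if status == _kernel.STATUS_MUT_OVERFLOW:
            mut_cap *= 4
        else:
            max_lin *= 4
    S = sites.size
    if S == 0:
        return HaplotypeMatrix(
            np.zeros((n, 0), dtype=np.uint8), np.zeros(0), labels, L
        )
    positions = (sites + rng.random(S)) / L
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    m0 = m0[order]
    m1 = m1[order]
    H = np.zeros((n, S), dtype=np.uint8)
    for i in range(n):
        if i < _PLANE_BITS:
            bit = np.int64(1) << i
            H[i] = (m0 & bit) != 0
        else:
            bit = np.int64(1) << (i - _PLANE_BITS)
            H[i] = (m1 & bit) != 0
    return HaplotypeMatrix(H, positions, labels, L)


def simulate_replicates(params, locus: LocusSpec, n_reps: int,
                        rng: np.random.Generator) -> list[HaplotypeMatrix]:
    return [simulate_locus(params, locus, rng) for _ in range(n_reps)]


# ---------------------------------------------------------------------------
# summary statistics on binary matrices (fast paths reused by the ABC engine)


def binary_summaries(hap: HaplotypeMatrix) -> tuple[float, float, int]:
    """(Watterson's theta per site, Tajima's D, number of distinct
    haplotypes) for one binary locus.

    Only columns segregating within the given sample count towards S --
    a sub-population slice of a two-population locus may carry columns
    monomorphic in that population."""
    n = hap.n
    if hap.S == 0:
        return 0.0, math.nan, 1
    c = hap.matrix.sum(axis=0).astype(float)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    theta = S / (harmonic(n - 1) * hap.L)
    if S == 0:
        return 0.0, math.nan, count_haplotypes(hap.matrix)
    pi_total = float((c * (n - c)).sum()) / (n * (n - 1) / 2.0)
    D = tajimas_d_from_counts(n, S, pi_total)
    return theta, D, count_haplotypes(hap.matrix)


def count_haplotypes(matrix: np.ndarray) -> int:
    if matrix.shape[1] == 0:
        return 1
    packed = np.packbits(matrix, axis=1)
    m = np.ascontiguousarray(packed)
    return len(np.unique(m.view([("", m.dtype)] * m.shape[1])))


def binary_twopop_counts(hap: HaplotypeMatrix) -> tuple[int, int, int, int, float]:
    """(shared, fixed, private1, private2, F_ST) from a two-population
    binary haplotype matrix, mirroring the nucleotide classification."""
    mask1 = hap.pop_labels == 0
    mask2 = hap.pop_labels == 1
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both populations must be sampled")
    if hap.S == 0:
        return 0, 0, 0, 0, math.nan
    c1 = hap.matrix[mask1].sum(axis=0).astype(float)
    c2 = hap.matrix[mask2].sum(axis=0).astype(float)
    seg1 = (c1 > 0) & (c1 < n1)
    seg2 = (c2 > 0) & (c2 < n2)
    shared = int((seg1 & seg2).sum())
    fixed = int((~seg1 & ~seg2 & ((c1 > 0) != (c2 > 0))).sum())
    private1 = int((seg1 & ~seg2).sum())
    private2 = int((seg2 & ~seg1).sum())
    hw1 = float((c1 * (n1 - c1)).sum()) / (n1 * (n1 - 1) / 2.0)
    hw2 = float((c2 * (n2 - c2)).sum()) / (n2 * (n2 - 1) / 2.0)
    hb = float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum()) / (n1 * n2)
    fst = math.nan if hb == 0 else 1.0 - 0.5 * (hw1 + hw2) / hb
    return shared, fixed, private1, private2, fst


def to_nucleotides(hap: HaplotypeMatrix, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Map a binary infinite-sites matrix onto A/G nucleotide sequences of
    length L (ancestral base A, derived base G at every SNP).  Positions
    are rounded to distinct integer bp; colliding sites are re-drawn.

    Returns (character matrix n x L, integer bp positions of the SNPs).
    """
    n, S = hap.n, hap.S
    L = hap.L
    seq = np.full((n, L), "A", dtype="U1")
    used: set[int] = set()
    bp = np.zeros(S, dtype=int)
    for j in range(S):
        p = int(hap.positions[j] * L)
        p = min(p, L - 1)
        while p in used:
            p = int(rng.random() * L)
        used.add(p)
        bp[j] = p
        seq[hap.matrix[:, j] == 1, p] = "G"
    return seq, bp


# ---------------------------------------------------------------------------
# ms-format interop


def write_ms(reps: list[HaplotypeMatrix], path: str | Path,
             command: str = "locuspair simulate") -> None:
    """Write replicates in Hudson's ms text format."""
    with open(path, "w") as fh:
        fh.write(f"{command}\n0 0 0\n")
        for rep in reps:
            fh.write("\n//\n")
            fh.write(f"segsites: {rep.S}\n")
            if rep.S:
                pos = " ".join(f"{p:.6f}" for p in rep.positions)
                fh.write(f"positions: {pos}\n")
                for row in rep.matrix:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")


def read_ms(path: str | Path, L: int = 1,
            n_per_pop: tuple[int, ...] | None = None) -> list[HaplotypeMatrix]:
    """Parse an ms-format file back into haplotype matrices."""
    reps: list[HaplotypeMatrix] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    rep_idx = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        rep_idx += 1
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise ValueError(f"replicate {rep_idx}: missing 'segsites:' line")
        S = int(lines[i].split(":")[1])
        i += 1
        if S == 0:
            reps.append(HaplotypeMatrix(
                np.zeros((0, 0), dtype=np.uint8), np.zeros(0),
                np.zeros(0, dtype=int), L))
            continue
        if i >= len(lines) or not lines[i].startswith("positions:"):
            raise ValueError(f"replicate {rep_idx}: missing 'positions:' line")
        positions = np.array([float(x) for x in lines[i].split(":")[1].split()])
        if positions.size != S:
            raise ValueError(f"replicate {rep_idx}: position count != segsites")
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if not set(row) <= {"0", "1"}:
                raise ValueError(f"replicate {rep_idx}: malformed haplotype row")
            if len(row) != S:
                raise ValueError(f"replicate {rep_idx}: row length != segsites")
            rows.append([int(ch) for ch in row])
            i += 1
        matrix = np.array(rows, dtype=np.uint8)
        if n_per_pop is None:
            labels = np.zeros(matrix.shape[0], dtype=int)
        else:
            labels = np.repeat(np.arange(len(n_per_pop)), n_per_pop)
        reps.append(HaplotypeMatrix(matrix, positions, labels, L))
    if rep_idx == 0:
        raise ValueError("no replicates found in ms file")
    return reps
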