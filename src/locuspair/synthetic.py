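"""Study-like synthetic dataset generation.

Emulates the locus-pair resequencing design: for each gene, one coalescent
simulation spans the whole gene (so linkage between the paired segments is
genealogically consistent), and two short segments A and B are cut out at
a known physical separation.  Haplotypes are mapped to nucleotides
(ancestral A, derived G -- the diversity statistics used downstream are
allele-label invariant), paired into diploid individuals, and written both
as phased haplotype FASTA and as IUPAC-collapsed diploid FASTA, together
with segment metadata and a machine-readable truth record of the
generating demography.  Whole-individual segment dropouts emulate failed
amplifications, producing the variable per-segment sample sizes seen in
real resequencing tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import Alignment, SegmentMeta, collapse_to_diploid, write_fasta, write_segment_table
from .coalescent import LocusSpec, SplitParams, simulate_locus, to_nucleotides


@dataclass
class StudyDesign:
    """Design parameters for a synthetic two-segment resequencing study."""

    n_genes: int = 18
    segments_per_gene: int = 2
    segment_length: tuple[int, int] = (300, 900)
    inter_segment_distance: tuple[int, int] = (1500, 6000)
    diploids_per_species: int = 24
    demography: object = None  # coalescent parameter set; default split model
    two_species: bool = True
    missing_rate: float = 0.0
    species_names: tuple[str, str] = ("schwerinii", "viminalis")

    def __post_init__(self) -> None:
        lo, hi = self.segment_length
        if not (100 <= lo <= hi <= 1500):
            raise ValueError("segment lengths must lie in [100, 1500]")
        if self.diploids_per_species < 2:
            raise ValueError("need >= 2 diploids per species")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.segments_per_gene not in (1, 2):
            raise ValueError("1 or 2 segments per gene")
        if self.demography is None:
            # default truth: the fitted split-with-migration demography
            self.demography = SplitParams(theta=0.0016, rho=0.017, N2=0.8,
                                          N_anc=3.99, M=0.036, t_s=0.44)


@dataclass
class SyntheticSegment:
    meta: SegmentMeta
    phased: Alignment
    start_bp: int  # segment start in gene coordinates


@dataclass
class SyntheticDataset:
    design: StudyDesign
    segments: list[SyntheticSegment]
    truth: dict

    def by_species(self, species: str) -> list[SyntheticSegment]:
        return [s for s in self.segments if s.meta.species == species]


def _gene_layout(design: StudyDesign, rng: np.random.Generator) -> tuple[int, int, int]:
    """(length A, gap, length B) for one gene; B empty for 1-segment genes."""
    lo, hi = design.segment_length
    len_a = int(rng.integers(lo, hi + 1))
    if design.segments_per_gene == 1:
        return len_a, 0, 0
    len_b = int(rng.integers(lo, hi + 1))
    gap = int(rng.integers(*design.inter_segment_distance))
    return len_a, gap, len_b


def generate_dataset(design: StudyDesign,
                     rng: np.random.Generator) -> SyntheticDataset:
    """Generate the full synthetic study in memory."""
    species = (design.species_names if design.two_species
               else design.species_names[:1])
    n_dip = design.diploids_per_species
    n_hap = 2 * n_dip
    segments: list[SyntheticSegment] = []
    for g in range(design.n_genes):
        gene_id = f"G{g + 1:02d}"
        len_a, gap, len_b = _gene_layout(design, rng)
        gene_len = len_a + gap + len_b
        if design.two_species:
            spec = LocusSpec((n_hap, n_hap), gene_len)
        else:
            spec = LocusSpec((n_hap,), gene_len)
        hap = simulate_locus(design.demography, spec, rng)
        seqs, _ = to_nucleotides(hap, rng)
        windows = [("A", 0, len_a)]
        if len_b:
            windows.append(("B", len_a + gap, len_a + gap + len_b))
        for sp_idx, sp in enumerate(species):
            rows = np.flatnonzero(hap.pop_labels == sp_idx)
            for seg_id, start, stop in windows:
                ids = []
                for d in range(n_dip):
                    for h in (1, 2):
                        ids.append(f"{sp[:2]}_{d + 1:03d}|{sp}|hap{h}")
                aln = Alignment(seqs[rows, start:stop], ids)
                meta = SegmentMeta(gene_id=gene_id, segment_id=seg_id,
                                   species=sp, distance_bp=gap, frame=-1)
                segments.append(SyntheticSegment(meta, aln, start))
    truth = {"model": type(design.demography).__name__}
    truth.update(asdict(design.demography))
    dataset = SyntheticDataset(design, segments, truth)
    if design.missing_rate > 0:
        dataset = apply_missingness(dataset, design.missing_rate, rng)
    return dataset


def apply_missingness(dataset: SyntheticDataset, rate: float,
                      rng: np.random.Generator) -> SyntheticDataset:
    """Drop whole individuals from segments at the given rate (both
    haplotypes of a dropped individual disappear from that segment)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return dataset
    new_segments = []
    for seg in dataset.segments:
        n_dip = seg.phased.n // 2
        keep_rows = []
        for d in range(n_dip):
            if rng.random() >= rate:
                keep_rows.extend([2 * d, 2 * d + 1])
        if len(keep_rows) < 4:  # keep at least two individuals
            keep_rows = [0, 1, 2, 3]
        new_segments.append(SyntheticSegment(
            seg.meta, seg.phased.subset(keep_rows), seg.start_bp))
    return SyntheticDataset(dataset.design, new_segments, dataset.truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write phased and IUPAC-collapsed diploid FASTA per segment and
    species, segment metadata, and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for seg in dataset.segments:
        m = seg.meta
        stem = f"{m.gene_id}{m.segment_id}_{m.species}"
        write_fasta(outdir / f"{stem}_phased.fasta",
                    seg.phased.sample_ids, seg.phased.haplotype_strings())
        dip_ids, dip_seqs = collapse_to_diploid(seg.phased)
        write_fasta(outdir / f"{stem}_diploid.fasta", dip_ids, dip_seqs)
        metas.append(m)
    write_segment_table(outdir / "segments.tsv", metas)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
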