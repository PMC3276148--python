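"""Sequence alignment containers and IO.

Reads FASTA alignments of directly sequenced diploid PCR products (with
IUPAC ambiguity codes at heterozygous positions), expands them to haplotype
pairs, and applies the complete-deletion site filter (columns containing a
gap or N in any sequence are removed) so that downstream statistics run on
fully resolved A/C/G/T columns only.

Coordinates are 0-based half-open internally; positions in reports are
1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

#: two-allele IUPAC ambiguity codes -> the unordered allele pair
IUPAC2 = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
#: inverse map: frozenset of two bases -> ambiguity code
BASES2IUPAC = {frozenset(v): k for k, v in IUPAC2.items()}

IUPAC34 = frozenset("BDHV")


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Matrix of haplotype sequences over {A,C,G,T} plus sample labels.

    sequences: (n_haplotypes, L) array of single characters.
    sample_ids: per-haplotype label "<individual>|<species>|<hap>".
    coding_mask: optional per-site annotation; -1 intron, 0/1/2 codon
        position within a reading frame.
    """

    sequences: np.ndarray
    sample_ids: list[str]
    coding_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="U1")
        if self.sequences.ndim != 2:
            raise AlignmentError("sequences must be a 2-D character matrix")
        if len(self.sample_ids) != self.sequences.shape[0]:
            raise AlignmentError("sample_ids length must match haplotype count")
        if self.coding_mask is not None:
            self.coding_mask = np.asarray(self.coding_mask, dtype=int)
            if self.coding_mask.shape != (self.sequences.shape[1],):
                raise AlignmentError("coding_mask length must equal L")

    @property
    def n(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    def individuals(self) -> list[str]:
        """Distinct individual labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(sid.split("|")[0], None)
        return list(seen)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            parts = sid.split("|")
            seen.setdefault(parts[1] if len(parts) > 1 else "", None)
        return list(seen)

    def subset(self, rows: Sequence[int]) -> "Alignment":
        rows = list(rows)
        return Alignment(
            self.sequences[rows],
            [self.sample_ids[i] for i in rows],
            None if self.coding_mask is None else self.coding_mask.copy(),
        )

    def haplotype_strings(self) -> list[str]:
        return ["".join(row) for row in self.sequences]


@dataclass
class SegmentMeta:
    """Metadata for one resequenced gene segment."""

    gene_id: str
    segment_id: str  # "A" or "B"
    species: str
    distance_bp: int = 0  # physical distance between the paired A/B segments
    frame: int = -1  # -1 = non-coding; 0/1/2 = codon phase of first site

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise AlignmentError("inter-segment distance must be >= 0")


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA file.

    Returns (ids, sequences), upper-cased, in file order. All records must
    have equal length; the offending record is named otherwise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"empty FASTA file: {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    L = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L:
            raise AlignmentError(
                f"record {rid!r} has length {len(s)}, expected {L}: "
                "sequences must be aligned"
            )
    return ids, seqs


def write_fasta(path: str | Path, ids: Sequence[str], seqs: Sequence[str]) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def parse_header(header: str) -> tuple[str, str]:
    """Split a FASTA id of the form 'sample|species[|hap]' into its parts."""
    parts = header.split("|")
    if len(parts) < 2:
        raise AlignmentError(
            f"header {header!r} does not encode 'sample|species'"
        )
    return parts[0], parts[1]


def expand_iupac(ids: Sequence[str], seqs: Sequence[str]) -> Alignment:
    """Expand diploid consensus sequences into two haplotypes each.

    Heterozygous positions carry two-allele IUPAC codes; the alphabetically
    earlier base goes to haplotype 1 (a fixed convention -- real phase is
    unknown from direct sequencing, so haplotype-level statistics computed
    from such expansions are phase-naive).  Three/four-allele codes cannot
    represent a diploid genotype and are rejected.
    """
    out_ids: list[str] = []
    out_seqs: list[str] = []
    for rid, seq in zip(ids, seqs):
        h1 = []
        h2 = []
        for pos, ch in enumerate(seq):
            if ch in VALID_BASES or ch in "N-":
                h1.append(ch)
                h2.append(ch)
            elif ch in IUPAC2:
                a, b = sorted(IUPAC2[ch])
                h1.append(a)
                h2.append(b)
            elif ch in IUPAC34:
                raise AlignmentError(
                    f"record {rid!r} position {pos + 1}: code {ch!r} implies "
                    ">2 alleles and cannot represent a diploid genotype"
                )
            else:
                raise AlignmentError(
                    f"record {rid!r} position {pos + 1}: invalid character {ch!r}"
                )
        out_ids.append(f"{rid}|hap1")
        out_ids.append(f"{rid}|hap2")
        out_seqs.append("".join(h1))
        out_seqs.append("".join(h2))
    matrix = np.array([list(s) for s in out_seqs], dtype="U1")
    return Alignment(matrix, out_ids)


def collapse_to_diploid(aln: Alignment) -> tuple[list[str], list[str]]:
    """Inverse of :func:`expand_iupac`: re-collapse haplotype pairs.

    Assumes consecutive rows 2i, 2i+1 are the two haplotypes of one
    individual (ids '<sample>|hap1' / '<sample>|hap2').
    """
    if aln.n % 2:
        raise AlignmentError("odd haplotype count; cannot pair into diploids")
    ids: list[str] = []
    seqs: list[str] = []
    for i in range(0, aln.n, 2):
        base_id = re.sub(r"\|hap[12]$", "", aln.sample_ids[i])
        row1, row2 = aln.sequences[i], aln.sequences[i + 1]
        out = []
        for a, b in zip(row1, row2):
            if a == b:
                out.append(a)
            else:
                key = frozenset((a, b))
                if key not in BASES2IUPAC:
                    raise AlignmentError(
                        f"cannot encode heterozygote {a}/{b} as IUPAC"
                    )
                out.append(BASES2IUPAC[key])
        ids.append(base_id)
        seqs.append("".join(out))
    return ids, seqs


def filter_columns(aln: Alignment) -> tuple[Alignment, np.ndarray]:
    """Complete-deletion site filter.

    Removes every column containing '-' or 'N' in any haplotype (indels and
    missing data are excluded from all analyses).  Returns the filtered
    alignment and the array of retained original column indices (the
    old -> new coordinate map: new column j was old column keep[j]).
    """
    bad = np.zeros(aln.L, dtype=bool)
    for ch in ("-", "N"):
        bad |= (aln.sequences == ch).any(axis=0)
    # anything outside ACGT (residual ambiguity codes) is also unresolvable
    resolved = np.isin(aln.sequences, list(VALID_BASES))
    bad |= ~resolved.all(axis=0)
    keep = np.flatnonzero(~bad)
    if keep.size == 0:
        raise AlignmentError("no analyzable sites remain after filtering")
    return (
        Alignment(
            aln.sequences[:, keep],
            list(aln.sample_ids),
            None if aln.coding_mask is None else aln.coding_mask[keep],
        ),
        keep,
    )


def read_segment_table(path: str | Path) -> list[SegmentMeta]:
    """Read segment metadata from a tab-delimited table with header
    gene_id, segment_id, species, distance_bp, frame."""
    metas = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "segment_id", "species", "distance_bp", "frame"}
        missing = required - set(idx)
        if missing:
            raise AlignmentError(f"segment table missing columns: {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            metas.append(
                SegmentMeta(
                    gene_id=f[idx["gene_id"]],
                    segment_id=f[idx["segment_id"]],
                    species=f[idx["species"]],
                    distance_bp=int(f[idx["distance_bp"]]),
                    frame=int(f[idx["frame"]]),
                )
            )
    return metas


def write_segment_table(path: str | Path, metas: Sequence[SegmentMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsegment_id\tspecies\tdistance_bp\tframe\n")
        for m in metas:
            fh.write(
                f"{m.gene_id}\t{m.segment_id}\t{m.species}\t{m.distance_bp}\t{m.frame}\n"
            )
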