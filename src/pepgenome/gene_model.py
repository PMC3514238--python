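"""CDS coordinate maps and the protein-to-genome coordinate lift.

The central structure is the *cdsmap*: an increasing array holding the
genomic position of every coding nucleotide of a transcript. Splice
junctions show up as jumps greater than one between adjacent entries, so a
peptide's genomic footprint falls out of a simple slice of the array
followed by a merge of consecutive runs. On the minus strand the array is
indexed from its end, which honours transcription order without reversing
the array itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .errors import FrameError, LengthMismatchError, RangeError
from .reference_io import GeneModel, ProteinRecord

# QC failure reasons
NO_PROTEIN = "NO_PROTEIN"
FRAME = "FRAME"
LENGTH_MISMATCH = "LENGTH_MISMATCH"
TRANSLATION_MISMATCH = "TRANSLATION_MISMATCH"
INTERNAL_STOP = "INTERNAL_STOP"


@dataclass
class CdsMap:
    """Ascending genomic positions of a transcript's coding nucleotides
    (stop codon removed when the protein length allows it to be inferred)."""

    gene: str
    chrom: str
    strand: str
    coords: np.ndarray

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass
class GenomicBlocks:
    """A spliced genomic footprint: sorted, non-adjacent half-open blocks."""

    chrom: str
    strand: str
    blocks: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class QCResult:
    gene: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


def build_cdsmap(gene: GeneModel, protein_length: int | None = None) -> CdsMap:
    """Collect every coding genomic position of ``gene`` in increasing order.

    When ``protein_length`` L is given, a raw length of 3L+3 means the CDS
    annotation includes the stop codon, which is trimmed (last three entries
    on '+', first three on '-'); a raw length of 3L means it does not.
    Anything else is a length mismatch, and a raw length not divisible by
    three is a frame error.
    """
    if not gene.is_coding:
        raise ValueError(f"{gene.name}: non-coding transcript has no cdsmap")
    pieces = []
    for s, e in gene.exons:
        lo, hi = max(s, gene.cds_start), min(e, gene.cds_end)
        if lo < hi:
            pieces.append(np.arange(lo, hi, dtype=np.int64))
    coords = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int64)
    raw = len(coords)
    if raw % 3 != 0:
        raise FrameError(f"{gene.name}: raw cds length {raw} not divisible by 3")
    if protein_length is not None:
        if raw == 3 * protein_length + 3:
            coords = coords[:-3] if gene.strand == "+" else coords[3:]
        elif raw != 3 * protein_length:
            raise LengthMismatchError(
                f"{gene.name}: cds length {raw} fits neither 3x{protein_length} "
                f"nor 3x{protein_length}+3"
            )
    return CdsMap(gene=gene.name, chrom=gene.chrom, strand=gene.strand, coords=coords)


def _runs_to_blocks(selected: np.ndarray) -> list[tuple[int, int]]:
    breaks = np.flatnonzero(np.diff(selected) > 1) + 1
    blocks = []
    for run in np.split(selected, breaks):
        blocks.append((int(run[0]), int(run[-1]) + 1))
    return blocks


def protein_to_genome(cdsmap: CdsMap, prot_pos: int, pep_len: int) -> GenomicBlocks:
    """Lift a peptide at protein position ``prot_pos`` (0-based) of length
    ``pep_len`` onto the genome as spliced half-open blocks."""
    n = cdsmap.n
    if prot_pos < 0 or pep_len < 1 or 3 * (prot_pos + pep_len) > n:
        raise RangeError(
            f"{cdsmap.gene}: peptide at {prot_pos} length {pep_len} exceeds "
            f"coding length {n // 3}"
        )
    if cdsmap.strand == "+":
        selected = cdsmap.coords[3 * prot_pos : 3 * (prot_pos + pep_len)]
    else:
        selected = cdsmap.coords[n - 3 * (prot_pos + pep_len) : n - 3 * prot_pos]
    return GenomicBlocks(
        chrom=cdsmap.chrom, strand=cdsmap.strand, blocks=_runs_to_blocks(selected)
    )


def extract_cds_nt(cdsmap: CdsMap, genome: dict[str, str]) -> str:
    """Spliced coding nucleotides in transcription order (reverse-complemented
    on the minus strand)."""
    if cdsmap.chrom not in genome:
        raise KeyError(f"chromosome {cdsmap.chrom!r} absent from genome")
    seq = genome[cdsmap.chrom]
    if cdsmap.n and int(cdsmap.coords[-1]) >= len(seq):
        raise RangeError(f"{cdsmap.gene}: coords exceed {cdsmap.chrom} length")
    nt = "".join(seq[p] for p in cdsmap.coords)
    if cdsmap.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return nt


def translate_cds(cdsmap: CdsMap, genome: dict[str, str]) -> str:
    """Translate the coding nucleotides with the standard nuclear codon
    table. Codons containing N become 'X'; stop codons appear as '*' (the
    caller — typically QC — decides what an internal stop means)."""
    if cdsmap.n == 0:
        raise ValueError(f"{cdsmap.gene}: empty cdsmap cannot be translated")
    nt = extract_cds_nt(cdsmap, genome)
    return str(Seq(nt).translate())


def qc_gene(
    gene: GeneModel,
    protein: ProteinRecord | None = None,
    genome: dict[str, str] | None = None,
) -> QCResult:
    """Consistency check of a gene model against its protein (and genome).

    Checks in order: a protein exists; raw CDS length is a multiple of
    three; raw length is 3L or 3L+3 for protein length L; and, when a
    genome is supplied, the in-silico translation equals the protein
    sequence (tolerating an initiator-M difference at position 0, flagging
    internal stops separately). Failures are data, not exceptions.
    """
    reasons: list[str] = []
    raw = sum(
        max(0, min(e, gene.cds_end) - max(s, gene.cds_start)) for s, e in gene.exons
    )
    if protein is None:
        reasons.append(NO_PROTEIN)
    if raw % 3 != 0:
        reasons.append(FRAME)
        return QCResult(gene=gene.name, passed=False, reasons=reasons)
    if protein is not None:
        L = len(protein.sequence)
        if raw not in (3 * L, 3 * L + 3):
            reasons.append(LENGTH_MISMATCH)
            return QCResult(gene=gene.name, passed=False, reasons=reasons)
        if genome is not None and gene.chrom in genome:
            cdsmap = build_cdsmap(gene, protein_length=L)
            translated = translate_cds(cdsmap, genome)
            mismatch = False
            internal_stop = False
            for i, (a, b) in enumerate(zip(translated, protein.sequence)):
                if a == b:
                    continue
                if i == 0 and ("M" in (a, b)):
                    continue  # initiator methionine convention difference
                if a == "*":
                    internal_stop = True
                else:
                    mismatch = True
            if mismatch:
                reasons.append(TRANSLATION_MISMATCH)
            if internal_stop:
                reasons.append(INTERNAL_STOP)
    return QCResult(gene=gene.name, passed=not reasons, reasons=reasons)
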