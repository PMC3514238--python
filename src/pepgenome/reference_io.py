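"""Readers for protein FASTA, genePred annotation, UniProt id-mapping tables
and genome FASTA.

All genomic coordinates are kept 0-based half-open on the forward strand
(genePred native); 1-based conversions happen only in the track writers.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import FormatError, RowError

logger = logging.getLogger(__name__)

_AA_RE = re.compile(r"^[A-Z]+$")
_NT_RE = re.compile(r"^[ACGTN]+$")
_GN_RE = re.compile(r"\bGN=(\S+)")


@dataclass
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not _AA_RE.match(self.sequence):
            raise ValueError(f"invalid protein sequence for {self.accession}")


@dataclass
class GeneModel:
    """One transcript's exon/CDS structure (0-based half-open, forward strand)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    name2: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.name}: empty or inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: exons unsorted or overlapping at {s}")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.name}: no exons")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.name}: cds outside tx bounds")
        if self.tx_start != self.exons[0][0] or self.tx_end != self.exons[-1][1]:
            raise ValueError(f"{self.name}: tx bounds disagree with exon span")
        if self.is_coding:
            if not any(s <= self.cds_start < e for s, e in self.exons):
                raise ValueError(f"{self.name}: cds_start not inside an exon")
            if not any(s < self.cds_end <= e for s, e in self.exons):
                raise ValueError(f"{self.name}: cds_end not inside an exon")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


class IdMappingTable:
    """Bidirectional lookups over a UniProt idmapping.dat-style 3-column table.

    Identifier comparison is case-sensitive, id-type names are not.
    """

    def __init__(self) -> None:
        self._to_ac: dict[tuple[str, str], set[str]] = {}
        self._from_ac: dict[tuple[str, str], set[str]] = {}

    def add(self, ac: str, id_type: str, identifier: str) -> None:
        t = id_type.lower()
        self._to_ac.setdefault((t, identifier), set()).add(ac)
        self._from_ac.setdefault((ac, t), set()).add(identifier)

    def to_ac(self, id_type: str, identifier: str) -> set[str]:
        """UniProtKB accessions known for an inbound identifier."""
        return set(self._to_ac.get((id_type.lower(), identifier), ()))

    def from_ac(self, ac: str, id_type: str) -> set[str]:
        """Outbound identifiers of a given type for a UniProtKB accession."""
        return set(self._from_ac.get((ac, id_type.lower()), ()))

    def knows_ac(self, ac: str) -> bool:
        return any(key[0] == ac for key in self._from_ac)


def _parse_header(description: str, dialect: str) -> tuple[str, str | None]:
    token = description.split()[0]
    symbol = None
    m = _GN_RE.search(description)
    if m:
        symbol = m.group(1)
    if dialect == "uniprot":
        parts = token.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            return parts[1], symbol
        return token, symbol
    if dialect == "refseq":
        parts = token.split("|")
        if len(parts) >= 4 and parts[0] == "gi" and parts[2] == "ref":
            return parts[3], symbol
        return token, symbol
    if dialect == "plain":
        return token, symbol
    raise ValueError(f"unknown header dialect {dialect!r}")


def read_protein_fasta(path, header_dialect: str = "plain") -> list[ProteinRecord]:
    """Read protein sequences, extracting accession (and GN= gene symbol)
    from the header per dialect; trailing ``*`` stop marks are removed."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        accession, symbol = _parse_header(rec.description, header_dialect)
        if accession in seen:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                description=rec.description,
                sequence=seq,
                gene_symbol=symbol,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _int_list(cell: str) -> list[int]:
    return [int(x) for x in cell.rstrip(",").split(",")] if cell.rstrip(",") else []


def read_genepred(path, extended: bool = False) -> list[GeneModel]:
    """Read UCSC genePred (10 columns) or genePred-extended (15, name2 kept).

    Non-coding transcripts (cdsStart == cdsEnd) are dropped with a logged
    count — there is nothing to map a peptide onto.
    """
    genes: list[GeneModel] = []
    n_noncoding = 0
    min_cols = 15 if extended else 10
    with open(path, encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise RowError(rowno, f"expected >= {min_cols} columns, got {len(cols)}")
            try:
                name = cols[0]
                chrom = cols[1]
                strand = cols[2]
                tx_start, tx_end = int(cols[3]), int(cols[4])
                cds_start, cds_end = int(cols[5]), int(cols[6])
                exon_count = int(cols[7])
                starts = _int_list(cols[8])
                ends = _int_list(cols[9])
            except ValueError as exc:
                raise RowError(rowno, f"non-numeric field ({exc})")
            if len(starts) != exon_count or len(ends) != exon_count:
                raise RowError(
                    rowno,
                    f"exonCount {exon_count} disagrees with "
                    f"{len(starts)} starts / {len(ends)} ends",
                )
            name2 = cols[11] if extended and len(cols) > 11 else None
            if cds_start == cds_end:
                n_noncoding += 1
                continue
            try:
                genes.append(
                    GeneModel(
                        name=name,
                        chrom=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        cds_start=cds_start,
                        cds_end=cds_end,
                        exons=list(zip(starts, ends)),
                        name2=name2,
                    )
                )
            except ValueError as exc:
                raise RowError(rowno, str(exc))
    if n_noncoding:
        logger.info("dropped %d non-coding transcripts from %s", n_noncoding, path)
    return genes


def _exon_frames(gene: GeneModel) -> list[int]:
    # genePredExt frames: codon phase of the first coding base of each exon,
    # in transcription order; -1 for exons without coding bases
    coding = [
        (max(s, gene.cds_start), min(e, gene.cds_end)) for s, e in gene.exons
    ]
    lens = [max(0, e - s) for s, e in coding]
    frames = []
    if gene.strand == "+":
        cum = 0
        for ln in lens:
            frames.append(cum % 3 if ln > 0 else -1)
            cum += ln
    else:
        cum_after = [sum(lens[i + 1:]) for i in range(len(lens))]
        for ln, ca in zip(lens, cum_after):
            frames.append(ca % 3 if ln > 0 else -1)
    return frames


def write_genepred(genes: list[GeneModel], path, extended: bool = False) -> None:
    """Serialize gene models back to genePred (inverse of :func:`read_genepred`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            cols = [
                g.name, g.chrom, g.strand,
                str(g.tx_start), str(g.tx_end),
                str(g.cds_start), str(g.cds_end),
                str(len(g.exons)), starts, ends,
            ]
            if extended:
                frames = ",".join(str(f) for f in _exon_frames(g)) + ","
                cols += ["0", g.name2 or g.name, "cmpl", "cmpl", frames]
            fh.write("\t".join(cols) + "\n")


def read_idmapping(path) -> IdMappingTable:
    """Read a 3-column UniProt idmapping table (AC, id_type, identifier)."""
    table = IdMappingTable()
    with open(path, encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise RowError(rowno, f"expected 3 columns, got {len(cols)}")
            table.add(cols[0], cols[1], cols[2])
    return table


def read_genome_fasta(path) -> dict[str, str]:
    """Read a nucleotide FASTA into {chrom: uppercase sequence} (ACGTN only)."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq and not _NT_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(f"{path}: non-nucleotide letters {bad} in {rec.id!r}")
        genome[rec.id] = seq
    return genome
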