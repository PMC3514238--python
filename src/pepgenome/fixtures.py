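"""Deterministic synthetic fixtures: a genome, gene models, matching
proteins, an id-mapping table and PSM files, with by-construction ground
truth for every sampled peptide.

The generator lays proteins out codon by codon while writing the genome,
so it knows the genomic positions of every residue independently of the
mapping code — the ground-truth blocks come straight from that layout.
Peptides are sampled as substrings of the translations (optionally
tryptic-like); a configurable fraction is replaced by random sequences
rejection-sampled to be absent from every translation. Whole-gene
duplication at a second locus creates peptides with known shared counts.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import FixtureError
from .psm_io import PSM, write_psm_tsv
from .reference_io import GeneModel, ProteinRecord, write_genepred

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = tuple(sorted(standard_dna_table.stop_codons))
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, ())
    _CODONS_BY_AA[aa] += (codon,)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: score thresholds the generator plants its low/mid/high tiers around
FIXTURE_TIER_THRESHOLDS = (30.0, 70.0)


@dataclass
class FixtureSpec:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 60_000
    n_genes: int = 30
    exon_count_range: tuple[int, int] = (1, 4)
    exon_len_range: tuple[int, int] = (30, 120)
    intron_len_range: tuple[int, int] = (20, 200)
    minus_strand_fraction: float = 0.5
    n_psms: int = 100
    peptide_len_range: tuple[int, int] = (7, 25)
    unmappable_fraction: float = 0.1
    shared_gene_pairs: int = 2
    score_tier_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    tryptic: bool = False
    write_mzid: bool = True

    def __post_init__(self) -> None:
        for frac in (self.minus_strand_fraction, self.unmappable_fraction):
            if not 0.0 <= frac <= 1.0:
                raise FixtureError(f"fraction {frac} outside [0, 1]")
        for lo, hi in (
            self.exon_count_range,
            self.exon_len_range,
            self.intron_len_range,
            self.peptide_len_range,
        ):
            if lo > hi or lo < 1:
                raise FixtureError(f"invalid range ({lo}, {hi})")
        if self.intron_len_range[0] < 1:
            raise FixtureError("introns must be at least 1 nt")
        if abs(sum(self.score_tier_mix) - 1.0) > 1e-9:
            raise FixtureError("score_tier_mix must sum to 1")


@dataclass
class _PlantedGene:
    index: int
    model: GeneModel
    protein: str           # translation without stop
    codon_coords: list[np.ndarray]  # genomic coords of codon i, protein order
    nt: str                # coding nucleotides in transcription order, incl. stop

    @property
    def tx_name(self) -> str:
        return self.model.name

    @property
    def uid(self) -> str:
        return f"PROT{self.index:04d}_SYN"

    @property
    def ac(self) -> str:
        return f"P{self.index + 1:05d}"


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _merge_blocks(coords: np.ndarray) -> list[tuple[int, int]]:
    # by-construction ground truth: merge ascending coords into runs
    coords = np.sort(coords)
    blocks: list[tuple[int, int]] = []
    start = prev = int(coords[0])
    for c in coords[1:]:
        c = int(c)
        if c > prev + 1:
            blocks.append((start, prev + 1))
            start = c
        prev = c
    blocks.append((start, prev + 1))
    return blocks


def truth_blocks(gene: _PlantedGene, prot_pos: int, pep_len: int) -> list[tuple[int, int]]:
    """Genomic blocks of a peptide, straight from the planted codon layout."""
    coords = np.concatenate(gene.codon_coords[prot_pos : prot_pos + pep_len])
    return _merge_blocks(coords)


def _plan_gene(rng, spec: FixtureSpec, index: int, name_index: int,
               chrom: str, cursor: int,
               template: _PlantedGene | None = None) -> tuple[_PlantedGene, int]:
    ec_lo, ec_hi = spec.exon_count_range
    el_lo, el_hi = spec.exon_len_range
    il_lo, il_hi = spec.intron_len_range
    if template is None:
        k = int(rng.integers(ec_lo, ec_hi + 1))
        lens = [int(rng.integers(el_lo, el_hi + 1)) for _ in range(k)]
        lens[-1] += (3 - sum(lens) % 3) % 3
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
    else:
        k = len(template.model.exons)
        lens = [e - s for s, e in template.model.exons]
        strand = template.model.strand
    introns = [int(rng.integers(il_lo, il_hi + 1)) for _ in range(k - 1)]
    total = sum(lens)

    exons: list[tuple[int, int]] = []
    pos = cursor
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln))
        pos += ln
        if i < k - 1:
            pos += introns[i]
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if tx_end > spec.chrom_len:
        raise FixtureError(
            f"gene {name_index} overflows {chrom} "
            f"({tx_end} > {spec.chrom_len}); enlarge chrom_len or reduce n_genes"
        )

    L = total // 3 - 1
    if L < 1:
        raise FixtureError("exon lengths too small to encode a protein")
    if template is None:
        protein = "M" + "".join(
            rng.choice(list(AA_ALPHABET), size=L - 1)
        )
        codons = [str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein]
        nt = "".join(codons) + str(rng.choice(_STOPS))
    else:
        protein, nt = template.protein, template.nt

    coords = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in exons])
    # codon i (protein order) occupies an ascending coord triplet; on the
    # minus strand transcription runs from the high end of the array
    if strand == "+":
        codon_coords = [coords[3 * i : 3 * i + 3] for i in range(L)]
    else:
        n = len(coords)
        codon_coords = [coords[n - 3 * (i + 1) : n - 3 * i] for i in range(L)]

    model = GeneModel(
        name=f"TX{name_index:04d}",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=tx_start,
        cds_end=tx_end,
        exons=exons,
        name2=f"GENE{index:04d}",
    )
    planted = _PlantedGene(
        index=name_index, model=model, protein=protein,
        codon_coords=codon_coords, nt=nt,
    )
    return planted, tx_end


def _plant_into_genome(chrom_seq: bytearray, gene: _PlantedGene) -> None:
    coords = np.concatenate(
        [np.arange(s, e, dtype=np.int64) for s, e in gene.model.exons]
    )
    written = gene.nt if gene.model.strand == "+" else _revcomp(gene.nt)
    for p, base in zip(coords, written):
        chrom_seq[p] = ord(base)


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_MZID_HEAD = """<?xml version="1.0" encoding="UTF-8"?>
<MzIdentML xmlns="http://psidev.info/psi/pi/mzIdentML/1.1" id="SYNTHETIC" version="1.1.0">
  <SequenceCollection>
"""


def _write_mzid(path: Path, psms: list[PSM]) -> None:
    # minimal synthetic mzIdentML 1.1 identification list mirroring the TSV
    peptide_ids: dict[str, str] = {}
    dbseq_ids: dict[str, str] = {}
    evidence_ids: dict[tuple[str, str], str] = {}
    lines = [_MZID_HEAD]
    for p in psms:
        for ref in p.protein_refs:
            if ref not in dbseq_ids:
                dbseq_ids[ref] = f"DBSeq_{len(dbseq_ids) + 1}"
                lines.append(
                    f'    <DBSequence id="{dbseq_ids[ref]}" accession="{ref}"'
                    ' searchDatabase_ref="SDB_1"/>\n'
                )
    for p in psms:
        if p.peptide not in peptide_ids:
            peptide_ids[p.peptide] = f"Pep_{len(peptide_ids) + 1}"
            lines.append(
                f'    <Peptide id="{peptide_ids[p.peptide]}">\n'
                f"      <PeptideSequence>{p.peptide}</PeptideSequence>\n"
                "    </Peptide>\n"
            )
    for p in psms:
        for ref in p.protein_refs:
            key = (p.peptide, ref)
            if key not in evidence_ids:
                evidence_ids[key] = f"PE_{len(evidence_ids) + 1}"
                lines.append(
                    f'    <PeptideEvidence id="{evidence_ids[key]}"'
                    f' peptide_ref="{peptide_ids[p.peptide]}"'
                    f' dBSequence_ref="{dbseq_ids[ref]}"/>\n'
                )
    lines.append("  </SequenceCollection>\n")
    lines.append("  <DataCollection>\n    <AnalysisData>\n")
    lines.append('      <SpectrumIdentificationList id="SIL_1">\n')
    for i, p in enumerate(psms, start=1):
        lines.append(
            f'        <SpectrumIdentificationResult id="SIR_{i}"'
            f' spectrumID="{p.spectrum_query}" spectraData_ref="SD_1">\n'
            f'          <SpectrumIdentificationItem id="SII_{i}" rank="1"'
            f' chargeState="{p.charge}" peptide_ref="{peptide_ids[p.peptide]}"'
            ' experimentalMassToCharge="0" calculatedMassToCharge="0"'
            ' passThreshold="true">\n'
        )
        for ref in p.protein_refs:
            lines.append(
                f'            <PeptideEvidenceRef'
                f' peptideEvidence_ref="{evidence_ids[(p.peptide, ref)]}"/>\n'
            )
        lines.append(
            '            <cvParam cvRef="PSI-MS" accession="MS:1001153"'
            f' name="synthetic:score" value="{p.score!r}"/>\n'
            "          </SpectrumIdentificationItem>\n"
            "        </SpectrumIdentificationResult>\n"
        )
    lines.append(
        "      </SpectrumIdentificationList>\n    </AnalysisData>\n"
        "  </DataCollection>\n</MzIdentML>\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)


@dataclass
class FixtureSet:
    """Paths and in-memory ground truth of one generated fixture."""

    paths: dict[str, Path]
    genes: list[_PlantedGene]
    psms: list[PSM]
    truth: list[dict]          # peptide, gene, prot_pos, chrom, strand, blocks
    unmappable: list[str]


def generate(spec: FixtureSpec, outdir) -> FixtureSet:
    """Write the full fixture file set to ``outdir`` (see module docstring).

    Same spec (including seed) twice gives byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chrom)]
    chroms = {
        name: bytearray(
            "".join(rng.choice(list("ACGT"), size=spec.chrom_len)), "ascii"
        )
        for name in chrom_names
    }

    genes: list[_PlantedGene] = []
    cursors = {name: 0 for name in chrom_names}
    n_dup = min(spec.shared_gene_pairs, spec.n_genes)
    total_genes = spec.n_genes + n_dup
    for j in range(total_genes):
        template = genes[j - spec.n_genes] if j >= spec.n_genes else None
        index = j if j < spec.n_genes else j - spec.n_genes
        chrom = chrom_names[j % spec.n_chrom]
        gap = int(rng.integers(100, 301))
        planted, end = _plan_gene(
            rng, spec, index, j, chrom, cursors[chrom] + gap, template
        )
        cursors[chrom] = end
        _plant_into_genome(chroms[chrom], planted)
        genes.append(planted)

    translations = {g.tx_name: g.protein for g in genes}

    # --- sample PSMs -------------------------------------------------------
    n_unmappable = round(spec.unmappable_fraction * spec.n_psms)
    n_mappable = spec.n_psms - n_unmappable
    lo, hi = spec.peptide_len_range
    low_max, mid_max = FIXTURE_TIER_THRESHOLDS
    tiers = ("low", "mid", "high")
    tier_bands = {"low": (1.0, low_max - 1), "mid": (low_max + 1, mid_max - 1),
                  "high": (mid_max + 1, 100.0)}

    raw_psms: list[PSM] = []
    truth_keys: set[tuple] = set()
    truth_rows: list[dict] = []
    for _ in range(n_mappable):
        g = genes[int(rng.integers(0, len(genes)))]
        L = len(g.protein)
        pl = int(rng.integers(min(lo, L), min(hi, L) + 1))
        for _attempt in range(200):
            pp = int(rng.integers(0, L - pl + 1))
            if not spec.tryptic or pp == 0 or g.protein[pp - 1] in "KR":
                break
        peptide = g.protein[pp : pp + pl]
        refs = [h.uid for h in genes if peptide in h.protein]
        tier = str(rng.choice(tiers, p=spec.score_tier_mix))
        a, b = tier_bands[tier]
        score = round(float(rng.uniform(a, b)), 2)
        raw_psms.append(
            PSM(
                spectrum_query="pending",
                peptide=peptide,
                charge=int(rng.integers(2, 5)),
                score=score,
                protein_refs=refs,
            )
        )
        for h in genes:
            start = h.protein.find(peptide)
            while start != -1:
                key = (peptide, h.tx_name, start)
                if key not in truth_keys:
                    truth_keys.add(key)
                    truth_rows.append(
                        {
                            "peptide": peptide,
                            "gene": h.tx_name,
                            "prot_pos": start,
                            "chrom": h.model.chrom,
                            "strand": h.model.strand,
                            "blocks": truth_blocks(h, start, pl),
                        }
                    )
                start = h.protein.find(peptide, start + 1)

    unmappable: list[str] = []
    for _ in range(n_unmappable):
        while True:
            pl = int(rng.integers(lo, hi + 1))
            candidate = "".join(rng.choice(list(AA_ALPHABET), size=pl))
            if not any(candidate in t for t in translations.values()):
                break
        unmappable.append(candidate)
        tier = str(rng.choice(tiers, p=spec.score_tier_mix))
        a, b = tier_bands[tier]
        raw_psms.append(
            PSM(
                spectrum_query="pending",
                peptide=candidate,
                charge=int(rng.integers(2, 5)),
                score=round(float(rng.uniform(a, b)), 2),
                protein_refs=[],
            )
        )

    order = rng.permutation(len(raw_psms))
    psms = []
    for row, idx in enumerate(order, start=1):
        p = raw_psms[int(idx)]
        p.spectrum_query = f"query_{row:05d}"
        p.source_row = row
        psms.append(p)

    # --- write files -------------------------------------------------------
    paths = {
        "genome": outdir / "genome.fa",
        "genepred": outdir / "genes.genePred",
        "proteins": outdir / "proteins.fa",
        "idmapping": outdir / "idmapping.tsv",
        "psms_tsv": outdir / "psms.tsv",
        "truth": outdir / "truth.tsv",
    }
    _write_fasta(
        paths["genome"],
        [(name, chroms[name].decode("ascii")) for name in chrom_names],
        width=80,
    )
    write_genepred([g.model for g in genes], paths["genepred"], extended=True)
    _write_fasta(
        paths["proteins"],
        [
            (
                f"sp|{g.ac}|{g.uid} synthetic protein {g.tx_name}"
                f" GN={g.model.name2}",
                g.protein,
            )
            for g in genes
        ],
        width=60,
    )
    with open(paths["idmapping"], "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.ac}\tUniProtKB-ID\t{g.uid}\n")
            fh.write(f"{g.ac}\tRefSeq\t{g.tx_name}\n")
            fh.write(f"{g.ac}\tGene_Name\t{g.model.name2}\n")
            fh.write(f"{g.ac}\tGI\t{90000 + g.index}\n")
    write_psm_tsv(psms, paths["psms_tsv"])
    if spec.write_mzid:
        paths["psms_mzid"] = outdir / "psms.mzid"
        _write_mzid(paths["psms_mzid"], psms)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("peptide\tgene\tprot_pos\tchrom\tstrand\tblocks\n")
        for row in sorted(
            truth_rows, key=lambda r: (r["peptide"], r["gene"], r["prot_pos"])
        ):
            blocks = ",".join(f"{s}-{e}" for s, e in row["blocks"])
            fh.write(
                f"{row['peptide']}\t{row['gene']}\t{row['prot_pos']}\t"
                f"{row['chrom']}\t{row['strand']}\t{blocks}\n"
            )
    return FixtureSet(
        paths=paths, genes=genes, psms=psms, truth=truth_rows, unmappable=unmappable
    )


def corrupt_gene(
    gene: GeneModel,
    mode: str,
    protein: ProteinRecord | None = None,
    genome: dict[str, str] | None = None,
) -> tuple[GeneModel, ProteinRecord | None, dict[str, str] | None]:
    """Return copies of the inputs with one planted defect.

    ``frameshift`` extends the CDS by one base (breaks mod-3);
    ``wrong_protein`` substitutes one interior residue of the FASTA record;
    ``internal_stop`` rewrites one interior codon of the genome to TAA.
    """
    if mode == "frameshift":
        exons = list(gene.exons)
        tx_end, cds_end = gene.tx_end, gene.cds_end + 1
        if cds_end > exons[-1][1]:
            s, e = exons[-1]
            exons[-1] = (s, e + 1)
            tx_end = max(tx_end, e + 1)
        out = replace(gene, cds_end=cds_end, tx_end=tx_end, exons=exons)
        return out, protein, genome
    if mode == "wrong_protein":
        if protein is None:
            raise ValueError("wrong_protein corruption needs the protein record")
        seq = list(protein.sequence)
        i = max(1, len(seq) // 2)
        seq[i] = "G" if seq[i] != "G" else "A"
        out_prot = replace(protein, sequence="".join(seq))
        return gene, out_prot, genome
    if mode == "internal_stop":
        if protein is None or genome is None:
            raise ValueError("internal_stop corruption needs protein and genome")
        pieces = [
            np.arange(max(s, gene.cds_start), min(e, gene.cds_end), dtype=np.int64)
            for s, e in gene.exons
            if min(e, gene.cds_end) > max(s, gene.cds_start)
        ]
        coords = np.concatenate(pieces)
        L = len(protein.sequence)
        j = max(1, L // 2)
        n = len(coords)
        if gene.strand == "+":
            triplet = coords[3 * j : 3 * j + 3]
            planted = "TAA"
        else:
            triplet = coords[n - 3 * (j + 1) : n - 3 * j]
            planted = _revcomp("TAA")
        seq = bytearray(genome[gene.chrom], "ascii")
        for p, base in zip(triplet, planted):
            seq[int(p)] = ord(base)
        out_genome = dict(genome)
        out_genome[gene.chrom] = seq.decode("ascii")
        return gene, protein, out_genome
    raise ValueError(f"unknown corruption mode {mode!r}")
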