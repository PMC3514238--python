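"""cdsmap construction, the protein-to-genome lift, translation and QC."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepgenome import fixtures
from pepgenome.errors import FrameError, LengthMismatchError, RangeError
from pepgenome.gene_model import (
    FRAME,
    INTERNAL_STOP,
    LENGTH_MISMATCH,
    NO_PROTEIN,
    TRANSLATION_MISMATCH,
    build_cdsmap,
    protein_to_genome,
    qc_gene,
    translate_cds,
)
from pepgenome.reference_io import GeneModel, ProteinRecord

from .conftest import make_g1, peptide_from_blocks


def oracle_blocks(cdsmap, prot_pos, pep_len):
    """Brute force: collect per-nucleotide coords codon by codon, merge."""
    n = cdsmap.n
    coords = []
    for i in range(prot_pos, prot_pos + pep_len):
        if cdsmap.strand == "+":
            coords.extend(int(c) for c in cdsmap.coords[3 * i : 3 * i + 3])
        else:
            coords.extend(int(c) for c in cdsmap.coords[n - 3 * (i + 1) : n - 3 * i])
    coords.sort()
    blocks = []
    start = prev = coords[0]
    for c in coords[1:]:
        if c > prev + 1:
            blocks.append((start, prev + 1))
            start = c
        prev = c
    blocks.append((start, prev + 1))
    return blocks


# --- build_cdsmap ----------------------------------------------------------

def test_cdsmap_enumerates_coding_positions(g1):
    cm = build_cdsmap(g1)
    assert cm.n == 18
    assert list(cm.coords) == list(range(100, 109)) + list(range(120, 129))


def test_cdsmap_trims_stop_on_plus(g1):
    cm = build_cdsmap(g1, protein_length=5)
    assert cm.n == 15
    assert cm.coords[-1] == 125  # last stop-codon positions 126..128 dropped


def test_cdsmap_trims_stop_on_minus(g1_minus):
    cm = build_cdsmap(g1_minus, protein_length=5)
    assert cm.n == 15
    assert cm.coords[0] == 103  # stop lives at the low end on the minus strand


def test_cdsmap_no_trim_when_cds_excludes_stop(g1):
    cm = build_cdsmap(g1, protein_length=6)  # 18 == 3*6 exactly
    assert cm.n == 18


def test_cdsmap_frame_error():
    g = GeneModel("g", "chr1", "+", 100, 129, 100, 128, [(100, 109), (120, 129)])
    with pytest.raises(FrameError):
        build_cdsmap(g)


def test_cdsmap_length_mismatch(g1):
    with pytest.raises(LengthMismatchError):
        build_cdsmap(g1, protein_length=4)  # 18 is neither 12 nor 15


# --- protein_to_genome -----------------------------------------------------

def test_lift_contiguous(g1):
    cm = build_cdsmap(g1)
    assert protein_to_genome(cm, 0, 2).blocks == [(100, 106)]


def test_lift_splits_at_splice_junction(g1):
    cm = build_cdsmap(g1)
    assert protein_to_genome(cm, 2, 2).blocks == [(106, 109), (120, 123)]


def test_lift_minus_strand_indexes_from_end(g1_minus):
    cm = build_cdsmap(g1_minus)
    assert protein_to_genome(cm, 0, 1).blocks == [(126, 129)]
    assert protein_to_genome(cm, 5, 1).blocks == [(100, 103)]


def test_lift_out_of_range(g1):
    cm = build_cdsmap(g1)
    with pytest.raises(RangeError):
        protein_to_genome(cm, 5, 2)  # 3*(5+2) > 18


@pytest.mark.parametrize("strand", "+-")
def test_lift_agrees_with_codon_oracle_and_conserves_length(strand, small_fixture):
    for g in small_fixture.genes:
        if g.model.strand != strand:
            continue
        cm = build_cdsmap(g.model, protein_length=len(g.protein))
        L = cm.n // 3
        for prot_pos, pep_len in [(0, 1), (0, L), (L - 1, 1), (L // 2, min(8, L - L // 2))]:
            got = protein_to_genome(cm, prot_pos, pep_len)
            assert got.blocks == oracle_blocks(cm, prot_pos, pep_len)
            assert got.total_length == 3 * pep_len


def test_lift_monotonicity(small_fixture):
    for g in small_fixture.genes[:8]:
        cm = build_cdsmap(g.model, protein_length=len(g.protein))
        L = cm.n // 3
        lifts = [protein_to_genome(cm, p, 1) for p in range(L)]
        if cm.strand == "+":
            starts = [b.blocks[0][0] for b in lifts]
            assert starts == sorted(starts)
        else:
            ends = [b.blocks[-1][1] for b in lifts]
            assert ends == sorted(ends, reverse=True)


# --- translate_cds ---------------------------------------------------------

def plus_gene_over(seq_len):
    return GeneModel("t", "chrT", "+", 0, seq_len, 0, seq_len, [(0, seq_len)])


def test_translate_plus():
    cm = build_cdsmap(plus_gene_over(6))
    assert translate_cds(cm, {"chrT": "ATGGAA"}) == "ME"


def test_translate_minus_uses_reverse_complement():
    g = GeneModel("t", "chrT", "-", 0, 6, 0, 6, [(0, 6)])
    cm = build_cdsmap(g)
    # forward genome ATGGAA; minus strand reads TTCCAT -> F, H
    assert translate_cds(cm, {"chrT": "ATGGAA"}) == "FH"


def test_translate_n_codon_is_x():
    cm = build_cdsmap(plus_gene_over(6))
    assert translate_cds(cm, {"chrT": "ATGGNA"}) == "MX"


def test_translate_reports_stop_as_star():
    cm = build_cdsmap(plus_gene_over(9))
    assert translate_cds(cm, {"chrT": "ATGTAAGAA"}) == "M*E"


# --- round trip over fixture genes ----------------------------------------

@given(st.data())
def test_peptide_round_trip_through_genome(small_fixture, small_genome, data):
    """Any substring of a translation lifts to blocks whose spliced,
    strand-adjusted nucleotides translate back to that substring — including
    peptides spanning splice junctions, on both strands."""
    g = data.draw(st.sampled_from(small_fixture.genes))
    L = len(g.protein)
    pep_len = data.draw(st.integers(1, min(30, L)))
    prot_pos = data.draw(st.integers(0, L - pep_len))
    cm = build_cdsmap(g.model, protein_length=L)
    blocks = protein_to_genome(cm, prot_pos, pep_len)
    back = peptide_from_blocks(
        small_genome, blocks.chrom, blocks.strand, blocks.blocks
    )
    assert back == g.protein[prot_pos : prot_pos + pep_len]


def test_junction_spanning_round_trip_both_strands(small_fixture, small_genome):
    checked = 0
    for g in small_fixture.genes:
        if len(g.model.exons) < 2:
            continue
        cm = build_cdsmap(g.model, protein_length=len(g.protein))
        # peptide straddling the first splice junction
        first_exon_aa = (g.model.exons[0][1] - g.model.exons[0][0]) // 3
        pos = max(0, first_exon_aa - 2)
        pep_len = min(6, len(g.protein) - pos)
        blocks = protein_to_genome(cm, pos, pep_len)
        if len(blocks.blocks) > 1:
            back = peptide_from_blocks(small_genome, cm.chrom, cm.strand, blocks.blocks)
            assert back == g.protein[pos : pos + pep_len]
            checked += 1
    assert checked > 0


# --- qc_gene ---------------------------------------------------------------

def protein_for(seq):
    return ProteinRecord(accession="P", description="P", sequence=seq)


def test_qc_passes_consistent_gene(g1):
    # plant codons for MAAVQ plus a stop across the two exons of g1
    from pepgenome.fixtures import _CODONS_BY_AA

    prot = "MAAVQ"
    coding = "".join(_CODONS_BY_AA[aa][0] for aa in prot) + "TAA"
    s = bytearray(b"N" * 200)
    cm = build_cdsmap(g1)
    for p, base in zip(cm.coords, coding):
        s[p] = ord(base)
    res = qc_gene(g1, protein_for(prot), {"chr1": s.decode()})
    assert res.passed and res.reasons == []


def test_qc_no_protein(g1):
    res = qc_gene(g1, None)
    assert not res.passed and res.reasons == [NO_PROTEIN]


def test_qc_frame():
    g = GeneModel("g", "chr1", "+", 100, 129, 100, 128, [(100, 109), (120, 129)])
    res = qc_gene(g, protein_for("MAAVQ"))
    assert res.reasons == [FRAME]  # 17 nt is not a codon multiple


def test_qc_length_mismatch(g1):
    res = qc_gene(g1, protein_for("MAAV"))  # 18 vs 12/15
    assert res.reasons == [LENGTH_MISMATCH]


def test_qc_leading_methionine_difference_tolerated(small_fixture, small_genome):
    g = small_fixture.genes[0]
    prot = protein_for("L" + g.protein[1:])  # non-M at position 0
    res = qc_gene(g.model, prot, small_genome)
    assert res.passed


def test_qc_translation_mismatch_and_internal_stop(small_fixture, small_genome):
    g = small_fixture.genes[0]
    _, bad_prot, _ = fixtures.corrupt_gene(
        g.model, "wrong_protein",
        protein=protein_for(g.protein), genome=small_genome,
    )
    res = qc_gene(g.model, bad_prot, small_genome)
    assert res.reasons == [TRANSLATION_MISMATCH]

    _, _, bad_genome = fixtures.corrupt_gene(
        g.model, "internal_stop",
        protein=protein_for(g.protein), genome=small_genome,
    )
    res = qc_gene(g.model, protein_for(g.protein), bad_genome)
    assert res.reasons == [INTERNAL_STOP]
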