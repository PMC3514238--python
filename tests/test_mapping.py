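"""Gene linking, the two mapping passes and mapping classification."""
import pytest

from pepgenome.errors import ConfigError
from pepgenome.mapping_engine import (
    AnnotationIndex,
    classify,
    map_pass1,
    map_pass2,
    resolve_gene_links,
)
from pepgenome.psm_io import PSM
from pepgenome.reference_io import GeneModel, IdMappingTable, ProteinRecord

from .conftest import make_g1

THRESHOLDS = (3.0, 7.0)


def psm(peptide, refs=(), score=5.0, query="q", charge=2):
    return PSM(query, peptide, charge, score, list(refs))


# --- resolve_gene_links ----------------------------------------------------

@pytest.fixture
def annotation():
    genes = [
        GeneModel("NP_1.2", "chr1", "+", 0, 9, 0, 9, [(0, 9)], name2="SYMB"),
        GeneModel("ENST0001", "chr2", "+", 0, 9, 0, 9, [(0, 9)], name2="OTHER"),
    ]
    return AnnotationIndex(genes)


def test_direct_transcript_hit(annotation):
    assert resolve_gene_links(psm("PEP", ["NP_1"]), None, None, annotation) == {"NP_1.2"}


def test_version_suffix_ignored(annotation):
    assert resolve_gene_links(psm("PEP", ["NP_1.9"]), None, None, annotation) == {"NP_1.2"}


def test_two_hop_idmap_chain(annotation):
    idmap = IdMappingTable()
    idmap.add("P1", "UniProtKB-ID", "NAME_HUMAN")
    idmap.add("P1", "RefSeq", "NP_1")
    got = resolve_gene_links(psm("PEP", ["NAME_HUMAN"]), idmap, None, annotation)
    assert got == {"NP_1.2"}


def test_gi_and_gene_name_routes(annotation):
    idmap = IdMappingTable()
    idmap.add("P2", "GI", "999")
    idmap.add("P2", "Gene_Name", "OTHER")
    got = resolve_gene_links(psm("PEP", ["GI:999"]), idmap, None, annotation)
    assert got == {"ENST0001"}


def test_fasta_symbol_route(annotation):
    fasta = {
        "ACCX": ProteinRecord("ACCX", "h", "MKL", gene_symbol="SYMB"),
    }
    assert resolve_gene_links(psm("PEP", ["ACCX"]), None, fasta, annotation) == {"NP_1.2"}


def test_unresolvable_reference_is_empty(annotation):
    assert resolve_gene_links(psm("PEP", ["GI:12345"]), None, None, annotation) == set()


def test_empty_protein_refs_resolve_to_nothing(annotation):
    assert resolve_gene_links(psm("PEP"), None, None, annotation) == set()


# --- mapping passes --------------------------------------------------------

@pytest.fixture
def g1_world():
    """g1 with translation MAWKR (5 aa; CDS 18 nt = 3*5+3)."""
    g = make_g1()
    return [g], {"g1": "MAWKR"}


def test_pass1_lifts_linked_peptide(g1_world):
    genes, translations = g1_world
    p = psm("WK", ["g1"])
    mappings, unresolved = map_pass1([p], genes, translations, [{"g1"}])
    assert unresolved == []
    (mp,) = mappings
    assert mp.blocks.blocks == [(106, 109), (120, 123)]
    assert mp.prot_pos == 2
    assert mp.mapping_pass == "annotation"
    assert mp.psms == [p]


def test_pass1_peptide_absent_from_linked_gene_is_unresolved(g1_world):
    genes, translations = g1_world
    mappings, unresolved = map_pass1(
        [psm("QQQ", ["g1"])], genes, translations, [{"g1"}]
    )
    assert mappings == [] and unresolved == ["QQQ"]


def test_pass1_groups_psms_sharing_a_peptide(g1_world):
    genes, translations = g1_world
    p1, p2 = psm("AWK", ["g1"], query="a"), psm("AWK", ["g1"], query="b")
    mappings, _ = map_pass1([p1, p2], genes, translations, [{"g1"}, {"g1"}])
    (mp,) = mappings
    assert mp.psms == [p1, p2]


def test_pass1_missing_linked_gene_logs_and_drops(g1_world, caplog):
    genes, translations = g1_world
    with caplog.at_level("WARNING"):
        mappings, unresolved = map_pass1(
            [psm("AWK", ["ghost"])], genes, translations, [{"ghost"}]
        )
    assert mappings == [] and unresolved == ["AWK"]
    assert "ghost" in caplog.text


def test_pass2_finds_all_loci_of_duplicated_translation():
    g_b = GeneModel("g2", "chr2", "+", 100, 129, 100, 129, [(100, 109), (120, 129)])
    genes = [make_g1(), g_b]
    translations = {"g1": "MAWKR", "g2": "MAWKR"}
    mappings = map_pass2(["AWK"], genes, translations)
    assert len(mappings) == 2
    assert all(mp.mapping_pass == "sequence" for mp in mappings)
    out = classify(mappings, THRESHOLDS)
    assert [mp.shared_count for mp in out] == [2, 2]
    assert all(not mp.unique for mp in out)


def test_pass2_absent_peptide_yields_nothing(g1_world):
    genes, translations = g1_world
    assert map_pass2(["QQQQ"], genes, translations) == []


def test_pass2_locus_superset_of_pass1(g1_world):
    genes, translations = g1_world
    p = psm("AWK", ["g1"])
    pass1, _ = map_pass1([p], genes, translations, [{"g1"}])
    pass2 = map_pass2(["AWK"], genes, translations)
    loci1 = {mp.locus for mp in pass1}
    loci2 = {mp.locus for mp in pass2}
    assert loci1 <= loci2


def test_il_equivalence_flag(g1_world):
    genes, translations = g1_world  # translation MAWKR
    strict = map_pass2(["MAWKR".replace("W", "W")], genes, translations)
    assert len(strict) == 1
    # no hit without folding when I replaces L-like residue; here test folding
    translations_il = {"g1": "MALKR"}
    assert map_pass2(["MAIKR"], genes, translations_il) == []
    folded = map_pass2(["MAIKR"], genes, translations_il, il_equivalence=True)
    assert len(folded) == 1 and folded[0].peptide == "MAIKR"


# --- classify --------------------------------------------------------------

def test_classify_single_locus_is_unique(g1_world):
    genes, translations = g1_world
    p = psm("AWK", ["g1"])
    mappings, _ = map_pass1([p], genes, translations, [{"g1"}])
    (mp,) = classify(mappings, THRESHOLDS)
    assert mp.unique and mp.shared_count == 1


def test_classify_reports_each_locus_separately():
    genes = [
        GeneModel(f"g{i}", f"chr{i}", "+", 100, 129, 100, 129, [(100, 109), (120, 129)])
        for i in range(1, 4)
    ]
    translations = {g.name: "MAWKR" for g in genes}
    out = classify(map_pass2(["AWK"], genes, translations), THRESHOLDS)
    assert len(out) == 3
    assert all(mp.shared_count == 3 for mp in out)


def test_classify_merges_isoforms_with_identical_blocks(g1_world):
    genes, _ = g1_world
    iso = GeneModel("iso", "chr1", "+", 100, 129, 100, 129, [(100, 109), (120, 129)])
    genes = genes + [iso]
    translations = {"g1": "MAWKR", "iso": "MAWKR"}
    out = classify(map_pass2(["AWK"], genes, translations), THRESHOLDS)
    (mp,) = out  # same locus via two transcripts -> one unique item
    assert mp.unique and mp.gene == "g1,iso"


@pytest.mark.parametrize(
    "score,tier", [(1.0, "low"), (5.0, "mid"), (9.0, "high"), (3.0, "low"), (7.0, "mid")]
)
def test_classify_tier_thresholds(g1_world, score, tier):
    genes, translations = g1_world
    mappings, _ = map_pass1(
        [psm("AWK", ["g1"], score=score)], genes, translations, [{"g1"}]
    )
    (mp,) = classify(mappings, THRESHOLDS)
    assert mp.tier == tier


def test_classify_uses_best_psm_score(g1_world):
    genes, translations = g1_world
    psms = [psm("AWK", ["g1"], score=s, query=f"q{s}") for s in (1.0, 9.0)]
    mappings, _ = map_pass1(psms, genes, translations, [{"g1"}, {"g1"}])
    (mp,) = classify(mappings, THRESHOLDS)
    assert mp.tier == "high"


def test_classify_rejects_non_increasing_thresholds(g1_world):
    with pytest.raises(ConfigError):
        classify([], (7.0, 3.0))


def test_classify_is_idempotent(small_fixture):
    from pepgenome.mapping_engine import map_pass2 as mp2

    genes = [g.model for g in small_fixture.genes]
    translations = {g.tx_name: g.protein for g in small_fixture.genes}
    peptides = sorted({p.peptide for p in small_fixture.psms})
    psms_by_pep = {}
    for p in small_fixture.psms:
        psms_by_pep.setdefault(p.peptide, []).append(p)
    once = classify(mp2(peptides, genes, translations, psms_by_pep), THRESHOLDS)
    twice = classify(once, THRESHOLDS)
    assert twice == once
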