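import pytest
from Bio.Seq import Seq
from hypothesis import HealthCheck, settings

from pepgenome import fixtures
from pepgenome.reference_io import GeneModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_g1(strand: str = "+") -> GeneModel:
    """Worked two-exon gene: exons [(100,109),(120,129)], CDS spans both
    (18 coding nt, i.e. 5 aa + stop)."""
    return GeneModel(
        name="g1",
        chrom="chr1",
        strand=strand,
        tx_start=100,
        tx_end=129,
        cds_start=100,
        cds_end=129,
        exons=[(100, 109), (120, 129)],
    )


@pytest.fixture
def g1():
    return make_g1("+")


@pytest.fixture
def g1_minus():
    return make_g1("-")


def peptide_from_blocks(genome, chrom, strand, blocks) -> str:
    """Independent back-translation: splice the genomic blocks ascending,
    reverse-complement on the minus strand, translate."""
    nt = "".join(genome[chrom][s:e] for s, e in blocks)
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return str(Seq(nt).translate())


def naive_search(patterns, text):
    """Brute-force multi-pattern oracle (str.find per pattern)."""
    hits = []
    for pat in set(patterns):
        if not pat:
            continue
        start = text.find(pat)
        while start != -1:
            hits.append((start, pat))
            start = text.find(pat, start + 1)
    hits.sort()
    return [(pat, pos) for pos, pat in hits]


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Default-sized synthetic study: 30 genes + 2 duplicates, 100 PSMs."""
    outdir = tmp_path_factory.mktemp("fixture_small")
    return fixtures.generate(fixtures.FixtureSpec(seed=7), outdir)


@pytest.fixture(scope="session")
def small_genome(small_fixture):
    from pepgenome.reference_io import read_genome_fasta

    return read_genome_fasta(small_fixture.paths["genome"])
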