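"""Two-pass peptide-to-gene mapping built on Wu–Manber multi-pattern search.

Pass 1 (annotation-filtered) searches each peptide only against the
translations of the genes its PSMs reference; pass 2 (sequence-only)
searches every peptide left unresolved against *all* gene translations with
one shared pattern index. Hits are lifted to spliced genomic blocks via the
cdsmap, then merged and classified by uniqueness, score tier and shared
count.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .errors import ConfigError
from .gene_model import CdsMap, GenomicBlocks, build_cdsmap, protein_to_genome
from .psm_io import PSM
from .reference_io import GeneModel, IdMappingTable, ProteinRecord

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")

PASS_ANNOTATION = "annotation"
PASS_SEQUENCE = "sequence"

TIER_LOW = "low"
TIER_MID = "mid"
TIER_HIGH = "high"


def strip_version(identifier: str) -> str:
    """Drop a trailing '.<digits>' version suffix (NP_000001.1 -> NP_000001)."""
    return _VERSION_RE.sub("", identifier)


# ---------------------------------------------------------------------------
# Wu–Manber multi-pattern exact search
# ---------------------------------------------------------------------------

@dataclass
class WuManberIndex:
    """Preprocessed shift/hash tables for a pattern set.

    ``m`` is the shortest indexed pattern length and ``B`` the block size;
    only the length-``m`` prefix of each pattern enters the tables, the
    remainder is verified on candidate hits. Patterns shorter than ``B``
    are kept aside and matched naively.
    """

    patterns: tuple[str, ...]
    m: int
    B: int
    shift: dict[str, int]
    bucket: dict[str, tuple[int, ...]]
    prefix: tuple[str, ...]
    short_patterns: tuple[str, ...]

    @property
    def default_shift(self) -> int:
        return self.m - self.B


def build_index(patterns, B: int | None = None) -> WuManberIndex:
    """Build Wu–Manber shift and bucket tables over a pattern set.

    ``B`` defaults to 3 when every pattern allows it, else 2; patterns
    shorter than ``B`` are routed to a naive fallback list. Results are
    independent of pattern insertion order (patterns are sorted
    internally).
    """
    pats = sorted(set(patterns))
    if not pats:
        return WuManberIndex((), 0, 2, {}, {}, (), ())
    min_len = min(len(p) for p in pats)
    if B is None:
        B = 3 if min_len >= 3 else 2
    if B not in (2, 3):
        raise ValueError(f"block size B must be 2 or 3, got {B}")
    main = [p for p in pats if len(p) >= B]
    short = tuple(p for p in pats if len(p) < B)
    if not main:
        return WuManberIndex((), 0, B, {}, {}, (), short)
    m = min(len(p) for p in main)
    shift: dict[str, int] = {}
    bucket: dict[str, list[int]] = {}
    for idx, pat in enumerate(main):
        prefix = pat[:m]
        for i in range(m - B + 1):
            gram = prefix[i : i + B]
            s = m - B - i
            if s < shift.get(gram, m):
                shift[gram] = s
            if s == 0:
                bucket.setdefault(gram, []).append(idx)
    return WuManberIndex(
        patterns=tuple(main),
        m=m,
        B=B,
        shift=shift,
        bucket={g: tuple(v) for g, v in bucket.items()},
        prefix=tuple(p[:2] for p in main),
        short_patterns=short,
    )


def search(index: WuManberIndex, text: str, text_id: str = "") -> list[tuple[str, int]]:
    """Report every occurrence of every pattern in ``text`` exactly once,
    sorted by position then pattern (overlaps and nestings included)."""
    hits: list[tuple[int, str]] = []
    for pat in index.short_patterns:
        start = text.find(pat)
        while start != -1:
            hits.append((start, pat))
            start = text.find(pat, start + 1)
    if index.patterns and len(text) >= index.m:
        m, B = index.m, index.B
        default = index.default_shift
        n = len(text)
        pos = m - 1
        while pos < n:
            gram = text[pos - B + 1 : pos + 1]
            s = index.shift.get(gram, default)
            if s > 0:
                pos += s
                continue
            start = pos - m + 1
            for idx in index.bucket.get(gram, ()):
                if text.startswith(index.prefix[idx], start) and text.startswith(
                    index.patterns[idx], start
                ):
                    hits.append((start, index.patterns[idx]))
            pos += 1
    hits.sort()
    return [(pat, pos) for pos, pat in hits]


# ---------------------------------------------------------------------------
# Gene linking
# ---------------------------------------------------------------------------

class AnnotationIndex:
    """Lookup of transcript names (version-insensitive) and gene symbols."""

    def __init__(self, genes: list[GeneModel]):
        self._by_name: dict[str, set[str]] = {}
        self._by_symbol: dict[str, set[str]] = {}
        for g in genes:
            self._by_name.setdefault(strip_version(g.name), set()).add(g.name)
            if g.name2:
                self._by_symbol.setdefault(g.name2, set()).add(g.name)

    def lookup_name(self, identifier: str) -> set[str]:
        return set(self._by_name.get(strip_version(identifier), ()))

    def lookup_symbol(self, symbol: str) -> set[str]:
        return set(self._by_symbol.get(symbol, ()))


#: inbound id-mapping types recognised on PSM protein references
INBOUND_ID_TYPES = ("UniProtKB-ID", "IPI", "GI")
#: outbound id-mapping types matched against annotation transcript names
OUTBOUND_NAME_TYPES = ("RefSeq", "Ensembl_TRS")


def resolve_gene_links(
    psm: PSM,
    idmap: IdMappingTable | None,
    fasta: dict[str, ProteinRecord] | None,
    annotation: AnnotationIndex,
) -> set[str]:
    """Resolve a PSM's protein references to annotation transcript names.

    Three routes are unioned: (a) the reference used directly as a
    transcript name; (b) the id-mapping chain UniProtKB-ID/IPI/GI ->
    UniProtKB-AC -> RefSeq/Ensembl_TRS/Gene_Name; (c) the gene symbol from
    the matching protein FASTA header against genePred name2. Version
    suffixes are ignored throughout; unresolvable references yield nothing.
    """
    genes: set[str] = set()
    for ref in psm.protein_refs:
        candidates = {ref, strip_version(ref)}
        if ref.upper().startswith("GI:"):
            candidates.add(ref[3:])
        for cand in candidates:
            genes |= annotation.lookup_name(cand)
        if idmap is not None:
            acs: set[str] = set()
            for cand in candidates:
                for id_type in INBOUND_ID_TYPES:
                    acs |= idmap.to_ac(id_type, cand)
                if idmap.knows_ac(cand):
                    acs.add(cand)
            for ac in acs:
                for id_type in OUTBOUND_NAME_TYPES:
                    for name in idmap.from_ac(ac, id_type):
                        genes |= annotation.lookup_name(name)
                for symbol in idmap.from_ac(ac, "Gene_Name"):
                    genes |= annotation.lookup_symbol(symbol)
        if fasta:
            for cand in candidates:
                rec = fasta.get(cand)
                if rec is not None and rec.gene_symbol:
                    genes |= annotation.lookup_symbol(rec.gene_symbol)
    return genes


# ---------------------------------------------------------------------------
# Mapping passes
# ---------------------------------------------------------------------------

@dataclass
class PeptideMapping:
    """One placement of a peptide on the genome, with quality metadata."""

    peptide: str
    gene: str
    chrom: str
    strand: str
    blocks: GenomicBlocks
    prot_pos: int
    psms: list[PSM] = field(default_factory=list)
    mapping_pass: str = PASS_ANNOTATION
    tier: str | None = None
    unique: bool | None = None
    shared_count: int | None = None

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.strand, tuple(self.blocks.blocks))

    def best_score(self) -> float:
        scores = [p.score for p in self.psms if not math.isnan(p.score)]
        return max(scores) if scores else float("-inf")


def _fold_il(s: str) -> str:
    return s.replace("L", "I")


def _cdsmap_cache(
    genes: dict[str, GeneModel], translations: dict[str, str]
) -> dict[str, CdsMap]:
    cache: dict[str, CdsMap] = {}
    for name, g in genes.items():
        if name in translations:
            cache[name] = build_cdsmap(g, protein_length=len(translations[name]))
    return cache


def map_pass1(
    psms: list[PSM],
    genes: list[GeneModel],
    translations: dict[str, str],
    links: list[set[str]],
    il_equivalence: bool = False,
) -> tuple[list[PeptideMapping], list[str]]:
    """Annotation-filtered mapping pass.

    ``links`` gives, for each PSM (parallel to ``psms``), the annotation
    transcript names its protein references resolved to. Peptides are
    grouped per linked gene and searched with one pattern index per gene
    translation. Returns the mappings plus the peptides left unresolved
    (no links, or absent from every linked translation).
    """
    gene_by_name = {g.name: g for g in genes}
    cdsmaps = _cdsmap_cache(gene_by_name, translations)
    fold = _fold_il if il_equivalence else (lambda s: s)

    by_gene: dict[str, dict[str, list[PSM]]] = {}
    psms_by_peptide: dict[str, list[PSM]] = {}
    for psm, linked in zip(psms, links):
        psms_by_peptide.setdefault(psm.peptide, []).append(psm)
        for gene_name in linked:
            if gene_name not in translations:
                logger.warning(
                    "linked gene %s has no translation/annotation; link dropped",
                    gene_name,
                )
                continue
            by_gene.setdefault(gene_name, {}).setdefault(psm.peptide, []).append(psm)

    mappings: list[PeptideMapping] = []
    resolved: set[str] = set()
    for gene_name, peptide_group in sorted(by_gene.items()):
        folded_to_orig: dict[str, list[str]] = {}
        for pep in peptide_group:
            folded_to_orig.setdefault(fold(pep), []).append(pep)
        index = build_index(folded_to_orig.keys())
        text = fold(translations[gene_name])
        for folded_pat, pos in search(index, text, gene_name):
            for pep in folded_to_orig[folded_pat]:
                blocks = protein_to_genome(cdsmaps[gene_name], pos, len(pep))
                mappings.append(
                    PeptideMapping(
                        peptide=pep,
                        gene=gene_name,
                        chrom=blocks.chrom,
                        strand=blocks.strand,
                        blocks=blocks,
                        prot_pos=pos,
                        psms=list(peptide_group[pep]),
                        mapping_pass=PASS_ANNOTATION,
                    )
                )
                resolved.add(pep)
    unresolved = sorted(set(psms_by_peptide) - resolved)
    return mappings, unresolved


def map_pass2(
    peptides,
    genes: list[GeneModel],
    translations: dict[str, str],
    psms_by_peptide: dict[str, list[PSM]] | None = None,
    il_equivalence: bool = False,
) -> list[PeptideMapping]:
    """Sequence-only mapping pass: one shared pattern index over all
    remaining peptides, scanned across every gene translation."""
    fold = _fold_il if il_equivalence else (lambda s: s)
    gene_by_name = {g.name: g for g in genes}
    cdsmaps = _cdsmap_cache(gene_by_name, translations)

    folded_to_orig: dict[str, list[str]] = {}
    for pep in sorted(set(peptides)):
        folded_to_orig.setdefault(fold(pep), []).append(pep)
    index = build_index(folded_to_orig.keys())

    mappings: list[PeptideMapping] = []
    for gene_name in sorted(translations):
        if gene_name not in cdsmaps:
            continue
        text = fold(translations[gene_name])
        for folded_pat, pos in search(index, text, gene_name):
            for pep in folded_to_orig[folded_pat]:
                blocks = protein_to_genome(cdsmaps[gene_name], pos, len(pep))
                mappings.append(
                    PeptideMapping(
                        peptide=pep,
                        gene=gene_name,
                        chrom=blocks.chrom,
                        strand=blocks.strand,
                        blocks=blocks,
                        prot_pos=pos,
                        psms=list(psms_by_peptide.get(pep, []))
                        if psms_by_peptide
                        else [],
                        mapping_pass=PASS_SEQUENCE,
                    )
                )
    return mappings


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    mappings: list[PeptideMapping], thresholds: tuple[float, float]
) -> list[PeptideMapping]:
    """Merge identical loci, then set shared count, uniqueness and tier.

    Mappings sharing (peptide, chrom, strand, blocks) — e.g. isoforms with
    a common exon — collapse into one item whose gene field joins all
    source transcripts. ``shared_count`` counts distinct loci per peptide
    sequence; tier comes from the best supporting PSM score against
    ``thresholds = (low_max, mid_max)``. Output order is (chrom, start,
    peptide, gene), so repeated runs are byte-stable downstream.
    """
    low_max, mid_max = thresholds
    if not low_max < mid_max:
        raise ConfigError(f"tier thresholds must increase, got {thresholds}")
    merged: dict[tuple, PeptideMapping] = {}
    for mp in mappings:
        key = (mp.peptide,) + mp.locus
        if key not in merged:
            merged[key] = PeptideMapping(
                peptide=mp.peptide,
                gene=mp.gene,
                chrom=mp.chrom,
                strand=mp.strand,
                blocks=mp.blocks,
                prot_pos=mp.prot_pos,
                psms=list(mp.psms),
                mapping_pass=mp.mapping_pass,
            )
        else:
            tgt = merged[key]
            gene_names = set(tgt.gene.split(",")) | set(mp.gene.split(","))
            tgt.gene = ",".join(sorted(gene_names))
            seen = {(id(p)) for p in tgt.psms}
            tgt.psms.extend(p for p in mp.psms if id(p) not in seen)
            if mp.mapping_pass == PASS_ANNOTATION:
                tgt.mapping_pass = PASS_ANNOTATION
            tgt.prot_pos = min(tgt.prot_pos, mp.prot_pos)

    per_peptide: dict[str, int] = {}
    for mp in merged.values():
        per_peptide[mp.peptide] = per_peptide.get(mp.peptide, 0) + 1
    out = list(merged.values())
    for mp in out:
        mp.shared_count = per_peptide[mp.peptide]
        mp.unique = mp.shared_count == 1
        best = mp.best_score()
        if best > mid_max:
            mp.tier = TIER_HIGH
        elif best > low_max:
            mp.tier = TIER_MID
        else:
            mp.tier = TIER_LOW
    out.sort(key=lambda mp: (mp.chrom, mp.blocks.start, mp.peptide, mp.gene))
    return out
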