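# Methods

## The mapping model

A peptide identified by tandem mass spectrometry is a substring of some
protein; the protein is the translation of a transcript's coding sequence
(CDS); the CDS is a set of genomic intervals on one strand. `pepgenome`
composes these three relations exactly — no alignment, no tolerance for
mismatches or frame shifts. A peptide is *mapped* when its sequence occurs
verbatim in a gene's translation; its genomic footprint is then fully
determined by the gene's exon/CDS structure.

The central data structure is the **cdsmap**: for one transcript, the
strictly increasing array of genomic positions (0-based) of every coding
nucleotide. Splice junctions appear as jumps greater than one between
adjacent entries. With protein length L the array length is 3L after stop
trimming, and:

* forward strand: residue *i* occupies `coords[3i : 3i+3]`;
* reverse strand: residue *i* occupies `coords[n-3(i+1) : n-3i]` — the
  array stays ascending and is indexed from its end, which is equivalent to
  walking the transcript in transcription order.

A peptide at protein position *p*, length *ℓ*, therefore selects a
contiguous slice of 3ℓ coordinates; maximal runs of consecutive integers
become half-open blocks. Two invariants follow by construction and are
asserted throughout the test suite: total block length equals 3ℓ, and
extracting the blocks' nucleotides, reverse-complementing on the minus
strand and translating reproduces the peptide exactly.

**Stop-codon trimming** is inferred, not assumed: genePred files differ in
whether `cdsEnd` includes the stop codon. A raw CDS length of 3L+3 for a
protein of length L means the stop is annotated and is trimmed (last
triplet on `+`, first triplet on `-`); a length of 3L means it is not.
Anything else is a length mismatch and fails QC.

## Gene quality control

Reverse-strand placement is computed from the high end of the coordinate
array, so any disagreement between annotated CDS length and actual protein
length shifts every residue. QC therefore checks, in order: a protein
record exists for the transcript (`NO_PROTEIN`); CDS length ≡ 0 mod 3
(`FRAME`); CDS length ∈ {3L, 3L+3} (`LENGTH_MISMATCH`); and, when a genome
FASTA is available, residue-exact agreement of the in-silico translation
with the protein (`TRANSLATION_MISMATCH`), with internal stop codons
flagged separately (`INTERNAL_STOP`) and a difference at position 0
involving methionine tolerated (initiator-Met conventions differ between
databases). Later checks are skipped when an earlier one already
invalidates their premise, so each planted defect yields exactly one
reason. QC failures are data (a per-gene report), not exceptions; failing
genes are excluded from mapping when QC is enabled.

## Search

Both mapping passes use the Wu–Manber multi-pattern exact search: patterns
are the peptides, the text is one gene translation. With m the shortest
pattern length and block size B, a table maps each B-gram to how far the
window may shift (0 for B-grams that terminate some pattern's length-m
prefix, in which case a hash bucket lists the candidate patterns to verify).
B is 3 when every pattern allows it, else 2; one- and two-residue peptides
are matched by plain scanning. The default shift for unseen B-grams is
m − B, a deliberately conservative variant (the textbook construction
allows m − B + 1); correctness is unaffected and is verified exhaustively
against a naive per-pattern scan — on randomised instances (hypothesis and
seeded), and on 1000 instances with up to 50 patterns of length 2–30 in
texts up to 2000 characters in the acceptance checks. All occurrences are
reported, including overlapping and nested ones, in (position, pattern)
order, independent of pattern insertion order.

The translations searched are the protein FASTA sequences assigned to
genes (accession = transcript name, id-mapping, or `GN=` symbol vs
genePred `name2`, in that order); when a genome is supplied, genes without
an assigned protein fall back to their own in-silico translation. An
optional flag folds I and L in both patterns and text, since the two are
isobaric and indistinguishable by mass alone; it is off by default, exact
matching being the conservative choice.

## Two passes and classification

Pass 1 restricts each peptide's search space to the genes its PSM's
protein references resolve to (one Wu–Manber index per gene). Peptides with
no links or no hits go to pass 2: a single index over all of them scanned
across every translation, which may produce several loci per peptide. By
construction pass 2's locus set for a peptide is a superset of pass 1's;
the acceptance suite asserts this, with equality for peptides from
non-duplicated genes.

After both passes, mappings with identical (peptide, chrom, strand,
blocks) are merged — isoforms sharing an exon do not make a peptide
"shared"; the merged item lists all source transcripts. The shared count is
the number of distinct loci per peptide sequence (unique ⇔ 1), and each
locus is reported as a separate output item. The score tier is computed
from the best (maximum) PSM score supporting a mapping: high above
`mid_max`, mid above `low_max`, else low. The thresholds are required
configuration with defaults (30, 70) on the synthetic score scale; real
search-engine scores need thresholds chosen for that engine and the
upstream FDR procedure, which is outside this package's scope. Scores are
stored higher-is-better internally; lower-is-better inputs are negated at
read time. Output order is fixed to (chrom, start, peptide, gene), making
all output files byte-identical across runs.

## File formats and numerical conventions

All internal coordinates are 0-based half-open on the forward strand
(genePred native). BED12 is written in the same convention; GFF3 conversion
(start + 1, same end) happens only in the writer, and the test suite checks
the two files interval-by-interval. Tier colours default to grey
(128,128,128), orange (255,140,0) and green (0,170,0); the BED score column
carries 333/666/1000 per tier so browsers without itemRgb support still
show three levels. BED name fields are `|`-separated `key=value` tokens
(peptide, gene, spectrum query, charge, shared count, pass) with whitespace
replaced by `_`; GFF3 attribute values percent-encode the reserved
characters `;=%&,` and control characters. Non-coding transcripts
(cdsStart == cdsEnd) are dropped at parse time with a logged count.

## The synthetic-data generator

The generator emulates the structure the mapper depends on, with defaults
chosen as a desk-scale caricature of a eukaryotic annotation: 2
chromosomes of 60 kb, 30 genes of 1–4 exons (30–120 nt exons, 20–200 nt
introns, half on each strand), 100 PSMs of 7–25 residues, 10% unmappable
decoys, two genes duplicated at a second locus, and equal thirds of
low/mid/high scores planted around the default thresholds. Proteins are
generated residue by residue and back-translated through randomly chosen
codons written directly into the genome, so gene, protein and genome are
consistent by construction and the generator records every residue's
genomic coordinates as it writes them — that layout, not the mapping code,
is the source of the ground-truth blocks used in tests. PSM protein
references list every protein containing the peptide, as a search engine
would. The acceptance runs scale the same generator up to 200 genes with
1–6 exons and 2200 PSMs (5% decoys, four duplicated genes), sizes chosen so
the full suite completes in seconds on one CPU while exercising every code
path (both strands, junction-spanning peptides, multi-locus peptides,
missing scores aside).

What the generator does **not** emulate: realistic spectra or masses,
missed cleavages and full enzymatic digestion (peptides are substrings,
optionally required to follow K/R), sequence polymorphism between protein
database and genome, chromosome aliasing, and overlapping genes. Passing
tests therefore demonstrate the correctness of the coordinate arithmetic,
search, linking and serialisation — not robustness to annotation/database
version skew, which on real data is precisely what the QC step is for.

## Known limitations

* Exact matching only: a peptide absent from every translation (sequence
  variant, unannotated ORF) lands in the unmapped report; six-frame genome
  search is out of scope.
* mzIdentML support is a 1.1 identification-list subset (Peptide,
  PeptideEvidence, DBSequence, SpectrumIdentificationResult/Item); protocol
  and software metadata are ignored, and files are read whole via lxml, so
  very large mzid files cost memory proportional to their size.
* The genePred dialect (plain or extended) must be stated by the caller;
  GTF/GFF input is not parsed.
* Score tiers use one global threshold pair; per-engine calibration is the
  user's responsibility.
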