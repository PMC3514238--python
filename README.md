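# pepgenome

Map peptide-spectrum matches (PSMs) from shotgun proteomics experiments onto
genome coordinates, and write genome-browser track files (BED12 and GFF3)
that encode identification quality, uniqueness and sharedness.

Proteogenomic analysis routinely needs mass-spectrometry evidence displayed
next to genomic annotation — to validate transcripts, compare protein and
transcript expression, or spot unannotated coding regions. Search engines
report peptides against *protein* databases, so the genomic position of a
peptide has to be reconstructed from gene annotation. `pepgenome` does that
reconstruction and emits tracks any common genome browser (UCSC, Ensembl,
IGV, ...) can load directly.

## Method

Inputs are up to five files: PSMs (mzIdentML 1.1 subset or tab-separated
text), protein sequences (FASTA), gene annotation (UCSC genePred, optionally
"extended" with gene symbols), an optional UniProt id-mapping table, and an
optional genome FASTA (needed only for gene quality control and in-silico
translation fallback).

1. **Gene quality control** (optional). Each transcript's CDS annotation is
   checked against its protein: reading frame (CDS length ≡ 0 mod 3), length
   consistency (3L or 3L+3 for protein length L, i.e. with or without the
   stop codon), and — when a genome is supplied — exact agreement of the
   in-silico translation with the protein sequence, flagging internal stop
   codons separately. Inconsistent genes are excluded: placement on the
   reverse strand depends entirely on the CDS annotation agreeing with the
   translated length.
2. **Annotation-filtered pass.** Each PSM's protein references are resolved
   to transcripts — directly, through the id-mapping chain
   UniProtKB-ID/IPI/GI → UniProtKB-AC → RefSeq/Ensembl-TRS/gene symbol, or
   through `GN=` symbols in FASTA headers. All peptides linked to one gene
   are searched simultaneously in that gene's translation with the
   Wu–Manber multi-pattern algorithm (block-based bad-character shifts plus
   hash buckets; exact, all occurrences).
3. **Coordinate lift.** For each gene a *cdsmap* is built: the increasing
   array of genomic positions of every coding nucleotide, stop codon
   trimmed. A hit at protein position *p* of length *ℓ* selects
   `coords[3p : 3(p+ℓ)]` on the forward strand, or the mirror-image slice
   from the array's end on the reverse strand; runs of consecutive
   coordinates become exon blocks, so spliced peptides fall out naturally
   (total block length is always 3ℓ).
4. **Sequence-only pass.** Peptides that could not be linked or found are
   pooled into one Wu–Manber index and searched against *all* translations;
   this can yield several candidate loci per peptide.
5. **Classification and output.** Mappings with identical loci are merged
   across isoforms; each peptide gets a shared count (number of distinct
   loci; unique ⇔ 1) and a score tier (low/mid/high against two
   configurable thresholds). BED12 separates uniqueness (and mapping pass)
   into track sections and colours tiers grey/orange/green; GFF3 encodes
   both in the feature type (`unique_high_peptide`, ...) with one
   `peptide_part` child per exon block. Unmapped peptides are reported in a
   separate TSV.

## Worked example

The package ships a deterministic synthetic-data generator, so a complete
run needs no downloads:

```bash
pepgenome fixtures --seed 1 --outdir demo
pepgenome map --psms demo/psms.tsv --proteins demo/proteins.fa \
    --genepred demo/genes.genePred --idmapping demo/idmapping.tsv \
    --genome demo/genome.fa --outdir demo/out
```

which logs

```
INFO pepgenome: fixture written to demo (32 genes, 100 PSMs)
INFO pepgenome: PSMs read: 100; genes passing QC: 32; pass-1 mappings: 103;
pass-2 mappings: 0; items written: 103; unmapped peptides: 10
```

All 90 genuinely mappable peptides were placed by the annotation-filtered
pass (103 items: peptides from duplicated genes are reported once per
locus); the 10 planted decoy peptides end up in
`demo/out/peptides_unmapped.tsv`. The BED output starts

```
track name="peptides_unique_annotation" description="peptide mappings (unique, annotation)" itemRgb=On
chr1  1078  1245  VVEFITSPQPYKVFLAEGKMHMC|gene=TX0002|q=query_00030|z=2|shared=1|pass=annotation  333  -  1078  1245  128,128,128  2  30,39  0,128
```

— a 23-residue peptide on the minus strand of chr1 spanning a splice
junction (two blocks of 30 and 39 nt, 69 = 3 × 23), low score tier (grey,
BED score 333), unique locus. The matching GFF3 line places the same
interval at start 1079 (1-based) with type encoding uniqueness and tier:

```
chr1  peptides  shared_high_peptide  146  181  71.95  -  .  ID=pep000001;Name=VQVDVHEMHSMD;...;shared_count=2;mapping_pass=annotation
```

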