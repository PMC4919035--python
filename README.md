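# genebuild

A desk-scale, evidence-driven gene-annotation pipeline: from pre-computed
evidence alignments on a toy genome assembly to a final, filtered,
multi-biotype gene set.

Vertebrate genome annotation systems do not predict genes ab initio — they
align biological sequence evidence (same-species proteins, cDNAs, ESTs,
RNA-seq reads) to the assembly and then make a long series of filtering and
selection decisions to turn raw alignments into a coherent gene set.  This
package reimplements that decision-making layer as an importable library
and a composable command-line tool, for people who want to study, test or
teach the logic of evidence-based annotation without a compute farm: the
external aligners (BLAST, Exonerate, GeneWise, BWA, ...) are out of scope,
and their outputs are this package's inputs.

The stages, in pipeline order:

* **targeted** — protein hits are grouped into candidate loci (single
  linkage, 200 kb gap), each locus extended ±200 kb; candidate coding
  models are built from the hit blocks with splice-aware edge refinement;
  models with more than one internal stop codon are rejected, a single
  internal stop is replaced by a small frameshift intron; introns of 1, 2,
  4 or 5 bp are labelled with a frameshift attribute; per locus, the
  candidate whose genomic translation best matches the protein under an
  affine-gap local alignment (Smith–Waterman–Gotoh family, BLOSUM62) is
  selected.  cDNAs with an annotated CDS range contribute competing
  models with UTRs; selenocysteine positions turn TGA stops into U.
* **rnaseq** — read blocks collapse into putative exons; spliced reads
  give intron features (depth, canonical GT..AG / CT..AC flag, strand
  inferred from splice dinucleotides); exons that retain an intron are
  split; read pairing groups blocks into proto-transcripts; per
  proto-transcript the single chain with the most read support (junction
  depths + exon coverage) is kept; models are called protein-coding when
  a protein aligns at ≥ 80 % identity and ≥ 80 % coverage.
* **utr** — a donor transcript matching both boundaries of a coding
  model's first (last) intron donates the 5' (3') UTR; donors rank by
  CAGE/ditag support; a missing initial Met is recovered from the 5' UTR
  and a missing stop from ≤ 150 bases downstream.
* **filter** — consensus scoring of each model against transcribed
  evidence (good / bad / small, with "small" below an evidence depth of
  six) and layer filtering: lower-priority models survive only where no
  preferred-layer model overlaps their exons on the same strand.
* **genebuild** — transcripts cluster into genes by coding-exon overlap;
  transcripts with no unique splices relative to a longer model are
  removed.
* **pseudo** — processed pseudogenes (one protein supporting both
  multi-exon and single-exon genes), repeat-filled-intron pseudogenes,
  and all-introns-shorter-than-9-bp pseudogenes.
* **lincRNA / merge / ids** — intergenic cDNA models become lincRNAs
  unless they have both a ≥ 35 % ORF and a protein-domain hit; an
  automatic set can be merged under a manually curated one (exact
  CDS-structure matches take the manual coordinates, everything manual is
  retained); stable identifiers are assigned and propagated between runs
  by exon-overlap Jaccard, with versions bumped on structural change.

A seeded fixture generator (`genebuild fixtures`) plants a toy genome with
known genes, retrotransposed copies and repeats, and derives every
evidence class from that truth — so the entire pipeline is testable
offline.  See `docs/methods.md` for the full model description and the
design choices.

## Worked example

Generate a fixture bundle (20 planted genes, 2 retro-copies, 2 lincRNAs)
and run the full pipeline:

```bash
genebuild fixtures --seed 1 --out demo
genebuild run --genome demo/genome.fa --agp demo/assembly.agp \
    --evidence demo/evidence --repeats demo/repeats.gff3 \
    --out demo/final.gff3
```

which prints

```
wrote fixture bundle (24 truth genes) to demo
final gene set: lincRNA=2, processed_pseudogene=2, protein_coding=20
```

All 20 planted protein-coding genes are recovered as protein-coding, both
retrotransposed copies are recognised as processed pseudogenes (the same
protein supports a multi-exon gene elsewhere), and the two planted
noncoding transcripts survive the lincRNA filter.  `demo/final.gff3`
carries the models with their biotypes, layers, supporting-evidence
identifiers and stable ids:

```
chr1  genebuild  gene  2947  4567  .  -  .  ID=ENSTOYG00000001;biotype=protein_coding;version=1
chr1  genebuild  mRNA  2947  4567  .  -  .  ID=c2g_cdna_fam000;Parent=ENSTOYG00000001;...;evidence_ids=cdna_fam000,prot_fam000
```

Stages also run individually (`genebuild targeted`, `rnaseq`, `utr`,
`filter`, `genebuild`, `pseudo`, `merge`, `ids`), reading and writing
GFF3 so they compose on disk.

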