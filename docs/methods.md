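# Methods

`genebuild` reimplements, at desk scale, the bespoke decision-making stages
of an evidence-driven vertebrate gene-annotation system: it consumes
pre-computed evidence alignments (protein hits, cDNA alignments, RNA-seq
read blocks) on a genome assembly and emits a filtered, multi-biotype gene
set.  External alignment programs are deliberately out of scope — their
*outputs* are the inputs here.  What the package owns is the decision
logic: locus grouping and candidate selection, internal-stop resolution,
transcript assembly from read blocks, retained-intron removal, UTR
extension, consensus and layer filtering, gene construction, pseudogene
and lincRNA classification, set merging and stable-identifier bookkeeping.

## Coordinates and data model

All coordinates are 1-based and inclusive (the GTF/GFF3 convention); BED
input/output converts at the boundary.  Intron spans run from the first to
the last intronic base.  The CDS of a transcript includes its terminal
stop codon — a single convention applied on both GFF3 and GTF output.
Exon lists are stored in ascending genomic order regardless of strand;
5'→3' logic (first intron, UTR sides, splicing) derives from the strand.

Assembly structure follows the AGP component model.  A region is
*toplevel* when it appears as a component of no other region; annotation
runs on toplevel sequences.  A scaffold that appears as a component of any
chromosome — even partially — is not toplevel; partial placement is an
interpretation the format leaves open, and disqualifying any component
appearance is the simplest consistent reading.  Coordinate projection
follows mappings up or down (chaining through intermediate systems) and
returns a gap marker, not an error, for positions in assembly gaps.

## Targeted stage

Exact-match protein hits are grouped per protein and region/strand by
single-linkage with a 200 kb gap limit, and each locus is extended by
200 kb on both sides (clamped to the region).  Full protein-to-genome
alignment is not re-derived: candidate exon chains come from the hit
blocks themselves, with intron edges allowed to slide up to 15 bp to the
nearest consensus splice pair (GT..AG, or CT..AC on the reverse strand).
Models with more than one internal stop codon are rejected; a single
internal stop is excised by a 3-bp intron replacing exactly the stop codon
(the smallest excision that restores the frame; the length of such
"frameshift introns" is otherwise unconstrained in principle, and 1, 2, 4
and 5 bp introns are the lengths labelled with the frameshift attribute).
Stops flagged as selenocysteine positions translate as U and are never
counted as internal stops.

Competing candidates for one protein at one locus (including models built
from cDNAs with an annotated CDS range) are ranked by the local alignment
of their genomic translation against the input protein — affine-gap local
alignment (Smith–Waterman–Gotoh family), BLOSUM62, gap open 12, extend 2,
a gap of length L costing open + (L−1)·extend.  Absolute scores are
placeholders; only the ranking is contractual, and it is verified against
a brute-force alignment-enumeration oracle in the test suite.  Ties break
to fewest frameshift introns, then longest CDS, then smallest identifier,
so selection is independent of input order.  Selection is per candidate
locus, not per protein globally: a protein whose hits fall at two
well-separated loci (a parent gene and a retrotransposed copy) yields one
selected model at each, which the pseudogene stage later depends on.

## RNA-seq stage

Aligned read blocks are collapsed into putative exons by interval union
(adjacent intervals merge); per-block mean depth is aligned bases over
block length.  Spliced (multi-block) reads define intron features keyed by
exact coordinates, with read-count depth; strand is inferred from the
splice dinucleotides, so unstranded reads still produce stranded introns.
A putative exon that fully contains a sufficiently spliced intron
(default: one spliced read) is a retained-intron artefact and is split
into its flanking sub-blocks.  Read pairing then groups blocks into
proto-transcripts: every pair links all blocks either mate touches, and
links seen in at least two distinct pairs join blocks into one component.

Within a proto-transcript exactly one isoform is kept — the conservative
one-model-per-gene contract.  The chain score is the sum of junction
depths plus per-exon mean depths (the paper-level notion of "most read
support" made concrete; ties prefer fewer exons, then the leftmost start).
The optimum is found by dynamic programming over intron edges, with the
constraint that consecutive introns through one block leave a non-empty
exon — guaranteeing every output intron coincides exactly with an observed
intron feature.  The DP is checked against exhaustive chain enumeration.
When no intron connects anything, each block becomes a single-exon model
(the fragmented-model regime of low-coverage data).

A model is called protein-coding when a protein aligns to it at ≥ 80 %
identity and ≥ 80 % coverage (both thresholds required); its CDS is the
longest ATG-initiated ORF of the spliced sequence.  Where several ORFs
would satisfy the aligned span the longest wins — a deliberate
simplification over frame-matching against the alignment.

## UTR extension

Coding models built from protein alignment carry no UTR.  A donor model
(cDNA, RNA-seq or EST) whose intron set contains the coding model's first
intron with both boundaries exact donates the 5' UTR; the last intron
plays the same role for the 3' UTR; single-exon models must lie within a
single donor exon to receive both.  Donors are tried in source precedence
cDNA > RNA-seq > EST (EST data being of more variable quality), and within
a source ranked by the number of CAGE/ditag positions within ±50 bp of
their transcript ends.  UTR addition never moves a CDS coordinate and is
idempotent.

CDS-end completion then runs: a translation not starting with methionine
is extended to the first in-frame ATG scanning 5'→3' from the UTR start
(maximal extension — the alternative nearest-ATG reading is configurable),
skipping candidates separated from the CDS by an in-frame stop; a
translation without a terminal stop adopts the first in-frame stop within
150 bases downstream, and stops beyond that window are ignored.

## Consensus classification and layering

Each candidate model is scored against overlapping same-species
transcribed evidence: score = (matched introns + ½·matched exon
boundaries) / (introns + ½·exon boundaries), in [0,1], so a fully
supported model scores exactly 1.  The ½ boundary weight and the good/bad
cutoff (a model is *good* iff its score reaches 0.75 of its overlap
cluster's maximum) are this package's calibration — the ranking, not the
absolute score, is the tested contract.  A cluster overlapped by fewer
than six distinct same-species evidence models cannot be scored reliably
and all its models are labelled *small*; depth counts distinct evidence
models, not sources.

Layering assigns priorities: same-species models (targeted, cdna2genome,
RNA-seq) in layer 1; *good* similarity models next (near-taxon before the
rest), *small* last; *bad* models never enter.  All layer-1 models are
kept; a lower-layer model survives only if none of its exons overlaps, on
the same strand, an exon of a kept model from any preferred layer.  Exon
overlap (not genomic-span overlap) is the criterion, so a model nested in
another's intron survives.  The result is independent of within-layer
input order.

## Gene construction and pseudogenes

Transcripts cluster into genes by transitive closure of same-strand
coding-exon overlap (plain exon overlap for non-coding models) — UTR-only
overlap never fuses genes.  Within a gene, a transcript whose intron set
is a subset of a longer transcript's is redundant and removed; "longer"
means more genomic exon length, then more introns, then identifier.  A
single-exon transcript contained in a longer transcript's exon is the
intronless limit of the same rule.  Evidence identifiers of removed
transcripts transfer to the subsuming transcript, so genes keep the full
record of their support — the pseudogene stage depends on this.

Pseudogene labelling applies three signatures in order, first match wins,
and never moves a coordinate: (1) *processed pseudogene* — a protein
supporting both multi-exon and single-exon genes marks the single-exon
ones as retrotransposed copies (granularity is the gene: a gene is
multi-exon if any transcript is); proteins supporting only multi-exon or
only single-exon genes mark functional families and cause no relabelling;
(2) *repeat pseudogene* — repeat cover of the gene's intronic sequence
above 0.5 (the "high proportion" made concrete; configurable);
(3) *frameshift pseudogene* — every transcript has introns and all are
strictly shorter than 9 bp.

## lincRNAs, merging, stable identifiers

lincRNA candidates are cDNA-derived models with no exon overlap with
protein-coding genes (either strand).  A candidate is rejected only when
it has BOTH an ORF covering at least 35 % of its length AND a protein
domain hit; either alone is insufficient.  Chromatin-methylation regions
(H3K4me3/H3K36me3) are an optional input; when supplied, candidates must
overlap one.

Merging folds an automatic set under a manually curated one.  Genes
sharing exon overlap group into a merged gene; an automatic transcript
whose intron–exon boundaries, UTRs excluded, exactly equal a manual
transcript's merges into it on the manual coordinates.  "Excluding UTRs"
is implemented as equality of the CDS-clipped exon chain, which also
pins the reading frame.  Manual annotation is never altered; automatic
genes without manual overlap carry over unchanged.

Stable identifiers are propagated by best exon-overlap Jaccard (threshold
0.5) within a biotype class (coding / pseudogene / non-coding), greedily
by descending Jaccard, then larger overlap, then older identifier, so the
assignment is order-independent and no two live genes share an id.  A
matched gene keeps its id and bumps its version iff its structure changed;
retired ids are never reused.

## Synthetic data

The fixture generator plants multi-exon protein-coding genes (ATG-initiated
CDS with a single terminal stop, GT..AG introns, UTRs on both ends, both
strands) on one chromosome assembled from abutting contigs via AGP, plus
one unplaced scaffold.  From that truth it derives every evidence class:
proteins with point substitutions at a set rate (default 1 %) and
exact-coordinate hit blocks; cDNAs with annotated CDS ranges; paired
75-base read blocks tiling each transcript at a target depth (default 30),
junction-spanning reads arising naturally from transcript-space sampling
and intron-retaining reads generated explicitly (default 10 % of depth) so
the retained-intron filter is exercised; CAGE/ditag positions jittered
±10 bp around transcript ends; and intergenic repeat stretches.
Retrotransposed copies of chosen parents are inserted as intronless CDS
copies beyond a 210 kb spacer, so one protein's hits fall in two distinct
candidate loci rather than one.

Default study conditions — 20 genes, 2 retro-copies, 2 lincRNAs, depth 30,
1 % mutation — are what the end-to-end acceptance suite runs; the genome
is then about 0.7 Mb and the full pipeline takes well under a minute.

What the generator does not emulate: sequencing errors and quality
scores, expression-level variation between genes, alternative splicing,
overlapping or nested genes, soft-clipped or multi-mapping reads, and
non-canonical splice sites in truth genes.  Passing tests therefore show
that the decision rules behave as specified on clean, well-separated
loci — not that the pipeline is robust to the full messiness of real
vertebrate data.

## Numerical and degenerate-input choices

Interval operations are exact integer arithmetic; there are no tolerances.
Empty inputs yield empty outputs rather than errors everywhere except
fatal assembly inconsistencies (unknown regions, overlapping AGP target
intervals) and malformed sequences (a CDS not divisible into codons
rejects its model; non-amino-acid symbols are fatal to alignment scoring).
A selenocysteine U is scored as X under BLOSUM62, which lacks a U column.
All tie-breaks (selection, isoform choice, redundancy, id propagation) are
total orders ending in identifiers, making every stage deterministic and
input-order independent.  All randomness lives in the fixture generator
and is driven by a single integer seed.

## Known limitations

Similarity-pipeline models from other species are supported structurally
(source tags, consensus labels, layers 2–4) but the default fixture plants
none, so layers 2–4 are exercised only by unit tests.  The per-run boolean
admitting non-consensus splice sites marks introns in attributes but no
second alignment pass exists to rescue them.  Expected insert-size
validation of read pairs is exposed as an optional maximum-span filter and
is off by default.  UTR donors can never repair internal structure — UTR
extension only.
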