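"""Seeded toy-genome generator with planted truth and derived evidence.

The generator builds a single-chromosome assembly (plus one unplaced
scaffold) carrying non-overlapping multi-exon protein-coding genes with
UTRs, then derives every evidence class the pipeline consumes from that
truth: mutated same-species proteins with exact-match hit blocks, cDNAs
with annotated CDS ranges, paired RNA-seq read blocks (including
junction-spanning and intron-retaining reads), CAGE/ditag positions, and
intergenic repeat stretches.  Retrotransposed intronless copies of chosen
parent genes are inserted far from their parents so the processed-
pseudogene signature (one protein supporting both a multi-exon and a
single-exon gene) is present in the evidence.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    EvidenceAlignment,
    Exon,
    RepeatFeature,
    SeqRegion,
    TagFeature,
    TranscriptModel,
    revcomp,
    translate_cds,
)
from . import io_formats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# sense codons only (no stops), indexed for mutation-free CDS generation
SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if translate_cds(a + b + c) != "*"
]


@dataclass
class FixtureParams:
    """Study conditions for the toy genome; defaults are the conditions the
    acceptance suite runs under (20 genes, 2 retro-copies, read depth 30,
    1% evidence mutation rate)."""

    n_genes: int = 20
    n_retro_copies: int = 2
    n_lincrnas: int = 2
    mutation_rate: float = 0.01
    read_depth: int = 30
    read_length: int = 75
    insert_size: int = 250
    retained_intron_fraction: float = 0.1
    exon_range: tuple[int, int] = (2, 5)
    codons_range: tuple[int, int] = (60, 180)
    utr_range: tuple[int, int] = (60, 150)
    intron_range: tuple[int, int] = (150, 600)
    intergenic_range: tuple[int, int] = (2000, 4000)
    retro_spacer_bp: int = 210_000  # keeps copies > one locus-grouping gap away
    contig_size: int = 50_000
    tag_jitter: int = 10
    chrom_length: int | None = None  # fixed length; fatal if genes do not fit

    def validate(self):
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate outside [0, 1]")
        if not (0 <= self.retained_intron_fraction <= 1):
            raise ValueError("retained_intron_fraction outside [0, 1]")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.read_length < 20:
            raise ValueError("read_length too short")


@dataclass
class PlantedGene:
    """One truth gene: the planted transcript plus its generative recipe."""

    family_id: str
    transcript: TranscriptModel
    mrna: str           # spliced transcript sequence, 5'->3'
    utr5_len: int
    cds_len: int        # nt, includes the terminal stop codon
    is_processed_copy: bool = False
    is_lincrna: bool = False

    @property
    def protein(self) -> str:
        s = self.mrna[self.utr5_len : self.utr5_len + self.cds_len]
        return translate_cds(s).rstrip("*")


@dataclass
class GenomeFixture:
    genome: dict[str, str]
    regions: list[SeqRegion]
    mappings: list
    genes: list[PlantedGene]
    repeats: list[RepeatFeature]
    params: FixtureParams
    seed: int

    def truth_introns(self) -> set[tuple[str, int, int]]:
        out = set()
        for g in self.genes:
            if g.is_lincrna:
                continue
            for s, e in g.transcript.introns():
                out.add((g.transcript.region, s, e))
        return out


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _make_cds(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    body = "".join(SENSE_CODONS[i] for i in idx)
    return "ATG" + body + "TAA"


def _split_lengths(rng, total: int, n_parts: int, min_part: int = 40) -> list[int]:
    """Random composition of *total* into n_parts, each >= min_part."""
    if total < n_parts * min_part:
        n_parts = max(1, total // min_part)
    cuts = sorted(int(c) for c in rng.choice(total - n_parts * min_part + 1,
                                             size=n_parts - 1, replace=True))
    parts, prev = [], 0
    for c in cuts + [total - n_parts * min_part]:
        parts.append(c - prev + min_part)
        prev = c
    return parts


def _build_locus(rng, params: FixtureParams, coding: bool = True):
    """Return (locus_seq, exon_spans_sense, mrna, utr5_len, cds_len).

    exon_spans_sense are 1-based inclusive intervals within the locus, in
    sense (5'->3') orientation.
    """
    lo, hi = params.codons_range
    if coding:
        cds = _make_cds(rng, int(rng.integers(lo, hi + 1)))
    else:
        cds = ""
    u5 = int(rng.integers(*params.utr_range))
    u3 = int(rng.integers(*params.utr_range))
    mrna = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    n_exons = int(rng.integers(params.exon_range[0], params.exon_range[1] + 1))
    exon_lens = _split_lengths(rng, len(mrna), n_exons)
    pieces, spans, pos, t = [], [], 0, 0
    for i, L in enumerate(exon_lens):
        pieces.append(mrna[t : t + L])
        spans.append((pos + 1, pos + L))
        pos += L
        t += L
        if i < len(exon_lens) - 1:
            ilen = int(rng.integers(*params.intron_range))
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            pieces.append(intron)
            pos += ilen
    return "".join(pieces), spans, mrna, u5, len(cds)


def _reflect(span: tuple[int, int], locus_len: int) -> tuple[int, int]:
    s, e = span
    return (locus_len - e + 1, locus_len - s + 1)


def _plant(chrom_parts, offset, locus, spans, strand):
    """Append locus (revcomp'd on -) and return genomic exon intervals."""
    L = len(locus)
    if strand == "-":
        chrom_parts.append(revcomp(locus))
        spans = [_reflect(s, L) for s in spans]
    else:
        chrom_parts.append(locus)
    genomic = sorted((offset + s, offset + e) for s, e in spans)
    return genomic, offset + L


def make_genome(n_genes: int, seed: int, params: FixtureParams | None = None) -> GenomeFixture:
    """Build the toy assembly with planted genes, copies and repeats."""
    params = params or FixtureParams(n_genes=n_genes)
    params.n_genes = n_genes
    params.validate()
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    parts: list[str] = []
    genes: list[PlantedGene] = []
    repeats: list[RepeatFeature] = []
    offset = 0

    def intergenic():
        nonlocal offset
        n = int(rng.integers(*params.intergenic_range))
        seq = _random_seq(rng, n)
        # drop a repeat stretch into roughly every other intergenic gap
        if rng.random() < 0.5 and n > 600:
            rs = int(rng.integers(100, n - 500))
            rlen = int(rng.integers(200, 400))
            repeats.append(RepeatFeature(chrom, offset + rs + 1, offset + rs + rlen, "toyLINE"))
        parts.append(seq)
        offset += n

    intergenic()
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        locus, spans, mrna, u5, cds_len = _build_locus(rng, params)
        genomic, offset = _plant(parts, offset, locus, spans, strand)
        exons = [Exon(chrom, s, e, strand) for s, e in genomic]
        t = TranscriptModel(
            id=f"truth_g{i:03d}.t1",
            exons=exons,
            biotype="protein_coding",
            source="manual",
        )
        cs = t.transcript_to_genomic(u5 + 1)
        ce = t.transcript_to_genomic(u5 + cds_len)
        t.cds_start, t.cds_end = min(cs, ce), max(cs, ce)
        genes.append(PlantedGene(f"fam{i:03d}", t, mrna, u5, cds_len))
        intergenic()

    for i in range(params.n_lincrnas):
        strand = "+" if rng.random() < 0.5 else "-"
        locus, spans, mrna, u5, cds_len = _build_locus(rng, params, coding=False)
        genomic, offset = _plant(parts, offset, locus, spans, strand)
        t = TranscriptModel(
            id=f"truth_linc{i:02d}.t1",
            exons=[Exon(chrom, s, e, strand) for s, e in genomic],
            biotype="lincRNA",
            source="manual",
        )
        genes.append(PlantedGene(f"linc{i:02d}", t, mrna, u5, 0, is_lincrna=True))
        intergenic()

    # retro-copies go beyond a long spacer so one protein's hits fall in two
    # distinct candidate loci rather than being grouped into one
    if params.n_retro_copies:
        parts.append(_random_seq(rng, params.retro_spacer_bp))
        offset += params.retro_spacer_bp
        parents = [g for g in genes if not g.is_lincrna and len(g.transcript.exons) > 1]
        chosen = rng.choice(len(parents), size=min(params.n_retro_copies, len(parents)), replace=False)
        for j, pi in enumerate(sorted(int(x) for x in chosen)):
            parent = parents[pi]
            cds_seq = parent.mrna[parent.utr5_len : parent.utr5_len + parent.cds_len]
            strand = "+" if rng.random() < 0.5 else "-"
            genomic, offset = _plant(parts, offset, cds_seq, [(1, len(cds_seq))], strand)
            t = TranscriptModel(
                id=f"truth_retro{j:02d}.t1",
                exons=[Exon(chrom, genomic[0][0], genomic[0][1], strand)],
                cds_start=genomic[0][0],
                cds_end=genomic[0][1],
                biotype="protein_coding",
                source="manual",
                attributes={"processed_copy": "true", "parent_family": parent.family_id},
            )
            genes.append(
                PlantedGene(parent.family_id, t, cds_seq, 0, parent.cds_len,
                            is_processed_copy=True)
            )
            intergenic()

    seq = "".join(parts)
    if params.chrom_length is not None:
        if len(seq) > params.chrom_length:
            raise ValueError(
                f"cannot pack {n_genes} genes into {params.chrom_length} bp "
                f"(need {len(seq)})"
            )
        seq += _random_seq(rng, params.chrom_length - len(seq))

    scaffold_seq = _random_seq(rng, 5000)
    genome = {chrom: seq, "scaffold_un": scaffold_seq}
    regions = [
        SeqRegion(chrom, len(seq), "chromosome"),
        SeqRegion("scaffold_un", len(scaffold_seq), "scaffold"),
    ]
    mappings = []
    from .core import AssemblyMapping

    n_contigs = math.ceil(len(seq) / params.contig_size)
    for i in range(n_contigs):
        s = i * params.contig_size + 1
        e = min((i + 1) * params.contig_size, len(seq))
        regions.append(SeqRegion(f"ctg{i:03d}", e - s + 1, "contig"))
        mappings.append(AssemblyMapping(f"ctg{i:03d}", 1, e - s + 1, chrom, s, e, "+"))
    return GenomeFixture(genome, regions, mappings, genes, repeats, params, seed)


# ---------------------------------------------------------------------------
# Evidence derivation
# ---------------------------------------------------------------------------

@dataclass
class EvidenceBundle:
    proteins: dict[str, str] = field(default_factory=dict)
    protein_hits: list[EvidenceAlignment] = field(default_factory=list)
    cdnas: dict[str, str] = field(default_factory=dict)
    cdna_alignments: list[EvidenceAlignment] = field(default_factory=list)
    reads: list[EvidenceAlignment] = field(default_factory=list)
    tags: list[TagFeature] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(self.proteins, outdir / "proteins.fa")
        io_formats.write_evidence_gff3(self.protein_hits, outdir / "protein_hits.gff3")
        io_formats.write_fasta(self.cdnas, outdir / "cdnas.fa")
        io_formats.write_evidence_gff3(self.cdna_alignments, outdir / "cdna_alignments.gff3")
        io_formats.write_bed12(self.reads, outdir / "reads.bed")
        io_formats.write_tags(self.tags, outdir / "tags.bed")


def _transcript_interval_blocks(t: TranscriptModel, a: int, b: int) -> list[tuple[int, int]]:
    """Genomic intervals covered by transcript-coordinate range [a, b]."""
    order = t.exons if t.strand == "+" else list(reversed(t.exons))
    out, c = [], 0
    for e in order:
        lo, hi = c + 1, c + e.length
        s, x = max(a, lo), min(b, hi)
        if s <= x:
            if t.strand == "+":
                out.append((e.start + (s - lo), e.start + (x - lo)))
            else:
                out.append((e.end - (x - lo), e.end - (s - lo)))
        c += e.length
    return sorted(out)


def _mutate_protein(rng, protein: str, rate: float) -> tuple[str, int]:
    out, n_mut = [], 0
    for aa in protein:
        if rng.random() < rate:
            choices = AA_ALPHABET.replace(aa, "")
            out.append(choices[int(rng.integers(0, len(choices)))])
            n_mut += 1
        else:
            out.append(aa)
    return "".join(out), n_mut


def make_evidence(fixture: GenomeFixture, seed: int,
                  params: FixtureParams | None = None) -> EvidenceBundle:
    """Derive protein, cDNA, RNA-seq and tag evidence from the planted truth."""
    params = params or fixture.params
    rng = np.random.default_rng(seed)
    ev = EvidenceBundle()
    by_family: dict[str, list[PlantedGene]] = {}
    for g in fixture.genes:
        by_family.setdefault(g.family_id, []).append(g)

    for fam, members in sorted(by_family.items()):
        primary = next((g for g in members if not g.is_processed_copy), members[0])
        if primary.is_lincrna:
            _lincrna_evidence(ev, primary)
            continue
        pid = f"prot_{fam}"
        mutated, n_mut = _mutate_protein(rng, primary.protein, params.mutation_rate)
        ev.proteins[pid] = mutated
        identity = 100.0 * (1 - n_mut / max(1, len(primary.protein)))
        for g in members:
            t = g.transcript
            blocks = []
            for gs, ge in t.coding_exons():
                ta = t.genomic_to_transcript(gs) - g.utr5_len
                tb = t.genomic_to_transcript(ge) - g.utr5_len
                blocks.append((gs, ge, min(ta, tb), max(ta, tb)))
            ev.protein_hits.append(
                EvidenceAlignment(
                    query_id=pid, query_type="protein", region=t.region,
                    strand=t.strand, blocks=blocks,
                    percent_identity=identity, query_coverage=100.0,
                )
            )
        _cdna_evidence(ev, primary, fam)
        _read_evidence(ev, rng, primary, params)
        _tag_evidence(ev, rng, primary, params)
    return ev


def _cdna_evidence(ev: EvidenceBundle, g: PlantedGene, fam: str) -> None:
    cid = f"cdna_{fam}"
    ev.cdnas[cid] = g.mrna
    t = g.transcript
    blocks = []
    for e in t.exons:
        ta = t.genomic_to_transcript(e.start)
        tb = t.genomic_to_transcript(e.end)
        blocks.append((e.start, e.end, min(ta, tb), max(ta, tb)))
    ev.cdna_alignments.append(
        EvidenceAlignment(
            query_id=cid, query_type="cdna", region=t.region, strand=t.strand,
            blocks=blocks,
            annotated_cds_on_query=(
                (g.utr5_len + 1, g.utr5_len + g.cds_len) if g.cds_len else None
            ),
        )
    )


def _lincrna_evidence(ev: EvidenceBundle, g: PlantedGene) -> None:
    _cdna_evidence(ev, g, g.family_id)


def _read_evidence(ev: EvidenceBundle, rng, g: PlantedGene, params: FixtureParams) -> None:
    t = g.transcript
    L = len(g.mrna)
    rl, ins = params.read_length, params.insert_size
    ins = min(ins, L)
    # evenly spaced, jittered mate-1 starts keep coverage uniform at the
    # target depth; mate-2 sits one insert downstream, wrapping into range
    span = max(1, L - rl + 1)
    n_pairs = math.ceil(params.read_depth * span / (2 * rl))
    stem = f"read_{g.family_id}"
    k = 0
    for j in range(n_pairs):
        t1 = 1 + int(j * span / n_pairs)
        t1 = min(span, max(1, t1 + int(rng.integers(-3, 4))))
        t2 = (t1 + ins - rl - 1) % span + 1
        for tag, (a, b) in (("1", (t1, min(L, t1 + rl - 1))),
                            ("2", (t2, min(L, t2 + rl - 1)))):
            blocks = _transcript_interval_blocks(t, a, b)
            if not blocks:
                continue
            ev.reads.append(
                EvidenceAlignment(
                    query_id=f"{stem}_{k:05d}/{tag}", query_type="read",
                    region=t.region, strand="+",
                    blocks=[(gs, ge, 1, ge - gs + 1) for gs, ge in blocks],
                    mate_id=f"{stem}_{k:05d}/{'2' if tag == '1' else '1'}",
                )
            )
        k += 1
    # intron-retaining reads: contiguous genomic tiles across each intron
    if params.retained_intron_fraction > 0:
        depth = params.read_depth * params.retained_intron_fraction
        for s, e in t.introns():
            span_s, span_e = s - rl + 10, e + rl - 10
            n = math.ceil(depth * (span_e - span_s + 1) / rl)
            for j in range(n):
                gs = int(rng.integers(span_s, max(span_s + 1, span_e - rl + 2)))
                ev.reads.append(
                    EvidenceAlignment(
                        query_id=f"{stem}_ri{s}_{j:04d}", query_type="read",
                        region=t.region, strand="+",
                        blocks=[(gs, gs + rl - 1, 1, rl)],
                    )
                )


def _tag_evidence(ev: EvidenceBundle, rng, g: PlantedGene, params: FixtureParams) -> None:
    t = g.transcript
    tss = t.start if t.strand == "+" else t.end
    tes = t.end if t.strand == "+" else t.start
    for pos, kind in ((tss, "cage"), (tss, "ditag_start"), (tes, "ditag_end")):
        jitter = int(rng.integers(-params.tag_jitter, params.tag_jitter + 1))
        ev.tags.append(
            TagFeature(t.region, max(1, pos + jitter), t.strand, kind,
                       count=int(rng.integers(1, 6)))
        )


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(outdir, seed: int, params: FixtureParams | None = None) -> GenomeFixture:
    """Write the complete input bundle (genome, AGP, truth, evidence) to a dir."""
    params = params or FixtureParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = make_genome(params.n_genes, seed, params)
    io_formats.write_fasta(fixture.genome, outdir / "genome.fa")
    io_formats.write_agp(fixture.mappings, [], outdir / "assembly.agp")
    io_formats.write_repeats(fixture.repeats, outdir / "repeats.gff3")
    from .core import GeneModel

    truth_genes = [
        GeneModel(id=g.transcript.id.rsplit(".", 1)[0], transcripts=[g.transcript],
                  biotype=g.transcript.biotype)
        for g in fixture.genes
    ]
    io_formats.write_models(truth_genes, outdir / "truth.gff3")
    ev = make_evidence(fixture, seed + 1)
    ev.write(outdir / "evidence")
    return fixture
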