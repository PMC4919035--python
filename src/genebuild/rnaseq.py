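"""RNA-seq model building: exon blocks, introns, isoform selection, coding call.

Aligned read blocks are collapsed into putative exons; spliced reads yield
intron features with read depth and a canonical-splice flag; exons that are
really retained introns are split using the spliced evidence; read pairing
groups blocks into proto-transcripts; within each proto-transcript the
single best-supported exon–intron chain is kept (the conservative
one-model-per-gene contract); finally protein alignments at 80% identity
and 80% coverage decide which models are protein-coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import EvidenceAlignment, Exon, IntronFeature, TranscriptModel

log = logging.getLogger("genebuild")

CODING_IDENTITY = 80.0
CODING_COVERAGE = 80.0
MIN_PAIRS = 2
MIN_SPLICED = 1


@dataclass(frozen=True)
class Block:
    """A collapsed putative exon with its mean read depth."""

    region: str
    start: int
    end: int
    mean_depth: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProtoTranscript:
    """Blocks grouped by read pairing; strand resolved later from splices."""

    region: str
    blocks: list[Block]
    strand: str = "."
    linked_by: dict[tuple[int, int], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Block collapse
# ---------------------------------------------------------------------------

def collapse_blocks(reads: list[EvidenceAlignment]) -> list[Block]:
    """Union of overlapping/adjacent aligned intervals, with mean depth."""
    per_region: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        for gs, ge, _, _ in r.blocks:
            per_region.setdefault(r.region, []).append((gs, ge))
    out = []
    for region, ivals in sorted(per_region.items()):
        ivals.sort()
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # mean depth = aligned bases falling in the block / block length
        covered = [0.0] * len(merged)
        idx = 0
        for s, e in ivals:
            while merged[idx][1] < s:
                idx += 1
            covered[idx] += e - s + 1
        out.extend(
            Block(region, s, e, covered[i] / (e - s + 1))
            for i, (s, e) in enumerate(merged)
        )
    return out


# ---------------------------------------------------------------------------
# Intron features from spliced alignments
# ---------------------------------------------------------------------------

def build_intron_features(
    reads: list[EvidenceAlignment], genome: dict[str, str]
) -> list[IntronFeature]:
    """One feature per distinct junction; strand from splice dinucleotides.

    GT..AG on the top strand is a canonical forward intron, CT..AC a
    canonical reverse one; anything else keeps the read's strand and is
    flagged non-canonical.
    """
    counts: dict[tuple[str, int, int], int] = {}
    read_strand: dict[tuple[str, int, int], str] = {}
    for r in reads:
        for s, e in r.implied_introns():
            if e < s:
                continue
            key = (r.region, s, e)
            counts[key] = counts.get(key, 0) + 1
            read_strand.setdefault(key, r.strand)
    out = []
    for (region, s, e), depth in sorted(counts.items()):
        chrom = genome[region]
        left, right = chrom[s - 1 : s + 1].upper(), chrom[e - 2 : e].upper()
        if left == "GT" and right == "AG":
            strand, canonical = "+", True
        elif left == "CT" and right == "AC":
            strand, canonical = "-", True
        else:
            strand, canonical = read_strand[(region, s, e)], False
        out.append(IntronFeature(region, s, e, strand, depth, canonical))
    return out


# ---------------------------------------------------------------------------
# Retained-intron false exons
# ---------------------------------------------------------------------------

def remove_retained_intron_exons(
    blocks: list[Block],
    introns: list[IntronFeature],
    min_spliced: int = MIN_SPLICED,
) -> list[Block]:
    """Split any block that fully contains a sufficiently spliced intron.

    A block containing an intron with depth >= *min_spliced* strictly inside
    it is replaced by the two flanking sub-blocks; multiple contained introns
    split the block repeatedly.  Introns merely overlapping a block edge do
    not trigger a split.
    """
    by_region: dict[str, list[IntronFeature]] = {}
    for i in introns:
        if i.depth >= min_spliced:
            by_region.setdefault(i.region, []).append(i)
    out = []
    for b in blocks:
        inside = sorted(
            (i.start, i.end)
            for i in by_region.get(b.region, [])
            if b.start < i.start and i.end < b.end
        )
        if not inside:
            out.append(b)
            continue
        # keep non-nested, non-overlapping introns left to right
        pieces, cursor = [], b.start
        for s, e in inside:
            if s <= cursor:
                continue
            pieces.append((cursor, s - 1))
            cursor = e + 1
        pieces.append((cursor, b.end))
        out.extend(Block(b.region, s, e, b.mean_depth) for s, e in pieces if s <= e)
    return sorted(out, key=lambda b: (b.region, b.start))


# ---------------------------------------------------------------------------
# Proto-transcripts via read pairing
# ---------------------------------------------------------------------------

def link_by_pairing(
    blocks: list[Block],
    reads: list[EvidenceAlignment],
    min_pairs: int = MIN_PAIRS,
    max_pair_span: int | None = None,
) -> list[ProtoTranscript]:
    """Connected components of blocks under mate-pair links.

    Each read pair links every pair of blocks touched by either mate; block
    pairs linked by at least *min_pairs* distinct read pairs join one
    proto-transcript.  Unpaired blocks stay singletons.  *max_pair_span*
    optionally discards pairs whose genomic extent exceeds a plausible
    insert (off by default).
    """
    trees: dict[str, IntervalTree] = {}
    order: dict[tuple[str, int, int], int] = {}
    for idx, b in enumerate(blocks):
        trees.setdefault(b.region, IntervalTree()).addi(b.start, b.end + 1, idx)
        order[(b.region, b.start, b.end)] = idx

    def touched(read: EvidenceAlignment) -> set[int]:
        tree = trees.get(read.region)
        if tree is None:
            return set()
        hit = set()
        for gs, ge, _, _ in read.blocks:
            hit.update(iv.data for iv in tree.overlap(gs, ge + 1))
        return hit

    by_id = {r.query_id: r for r in reads}
    edge_count: dict[tuple[int, int], int] = {}
    seen_pairs = set()
    for r in reads:
        if not r.mate_id or r.mate_id not in by_id:
            continue
        pair_key = tuple(sorted((r.query_id, r.mate_id)))
        if pair_key in seen_pairs:
            continue
        seen_pairs.add(pair_key)
        mate = by_id[r.mate_id]
        if max_pair_span is not None:
            span = max(r.end, mate.end) - min(r.start, mate.start) + 1
            if span > max_pair_span:
                continue
        union = touched(r) | touched(mate)
        for a in union:
            for b in union:
                if a < b:
                    edge_count[(a, b)] = edge_count.get((a, b), 0) + 1

    parent = list(range(len(blocks)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    strong_edges = {e: c for e, c in edge_count.items() if c >= min_pairs}
    for (a, b) in strong_edges:
        parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in range(len(blocks)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        members.sort(key=lambda i: blocks[i].start)
        linked = {
            (a, b): c
            for (a, b), c in strong_edges.items()
            if a in members and b in members
        }
        out.append(
            ProtoTranscript(
                region=blocks[members[0]].region,
                blocks=[blocks[i] for i in members],
                linked_by=linked,
            )
        )
    out.sort(key=lambda p: (p.region, p.blocks[0].start))
    return out


# ---------------------------------------------------------------------------
# Isoform selection
# ---------------------------------------------------------------------------

def chain_score(exons: list[Block], introns: list[IntronFeature]) -> float:
    """Support for a chain: junction depths plus per-exon mean depths."""
    return sum(i.depth for i in introns) + sum(b.mean_depth for b in exons)


def _compatible_edges(blocks: list[Block], introns: list[IntronFeature]):
    """(intron, a, b) for introns whose flanking bases land in blocks a < b."""
    edges = []
    for intron in introns:
        a = b = None
        for idx, blk in enumerate(blocks):
            if blk.start <= intron.start - 1 <= blk.end and intron.start - 1 >= blk.start:
                a = idx
            if blk.start <= intron.end + 1 <= blk.end and intron.end + 1 <= blk.end:
                b = idx
        if a is not None and b is not None and a < b:
            edges.append((intron, a, b))
    return edges


def select_isoform(
    proto: ProtoTranscript,
    introns: list[IntronFeature],
    id_prefix: str = "rnaseq",
) -> list[TranscriptModel]:
    """Keep the exon–intron chain with the most read support.

    Among all chains consistent with the proto-transcript's blocks and the
    observed introns, the chain maximizing junction depth plus exon coverage
    wins; ties prefer fewer exons, then the leftmost start.  When no intron
    connects anything and several blocks remain, one single-exon model per
    block is emitted (fragmented models at low coverage).
    """
    blocks = sorted(proto.blocks, key=lambda b: b.start)
    region_introns = [
        i for i in introns
        if i.region == proto.region
        and any(b.start <= i.start - 1 <= b.end for b in blocks)
    ]
    edges = _compatible_edges(blocks, region_introns)
    if not edges and len(blocks) > 1:
        log.warning(
            "proto-transcript at %s:%d has no consistent chain; emitting "
            "%d single-exon models", proto.region, blocks[0].start, len(blocks),
        )
        return [
            _chain_to_model([b], [], f"{id_prefix}_{proto.region}_{b.start}")
            for b in blocks
        ]
    # DP over intron edges in coordinate order (score, then fewer exons,
    # then leftmost start); consecutive introns through one block must
    # leave a non-empty exon between them, so every output intron is an
    # observed intron feature
    edges.sort(key=lambda x: (x[0].start, x[0].end))
    best_edge: list[tuple] = []
    back_edge: list[int | None] = []
    for k, (intron, a, b) in enumerate(edges):
        key = (
            blocks[a].mean_depth + intron.depth + blocks[b].mean_depth,
            -2,
            -blocks[a].start,
        )
        back = None
        for f, (fi, fa, fb) in enumerate(edges[:k]):
            if fb != a or fi.end + 1 > intron.start - 1:
                continue
            prev = best_edge[f]
            cand = (prev[0] + intron.depth + blocks[b].mean_depth,
                    prev[1] - 1, prev[2])
            if cand > key:
                key, back = cand, f
        best_edge.append(key)
        back_edge.append(back)
    best_single = max(
        ((blk.mean_depth, -1, -blk.start), i) for i, blk in enumerate(blocks)
    )
    best_k = max(range(len(edges)), key=lambda k: best_edge[k], default=None)
    if best_k is None or best_edge[best_k] < best_single[0]:
        chain_blocks, chain_introns = [blocks[best_single[1]]], []
    else:
        rev_edges = []
        cur = best_k
        while cur is not None:
            rev_edges.append(edges[cur])
            cur = back_edge[cur]
        rev_edges.reverse()
        chain_blocks = [blocks[rev_edges[0][1]]] + [blocks[e[2]] for e in rev_edges]
        chain_introns = [e[0] for e in rev_edges]
    model = _chain_to_model(
        chain_blocks, chain_introns,
        f"{id_prefix}_{proto.region}_{chain_blocks[0].start}",
    )
    return [model]


def _chain_to_model(chain_blocks, chain_introns, model_id) -> TranscriptModel:
    region = chain_blocks[0].region
    strands = [i.strand for i in chain_introns if i.canonical]
    strand = max(set(strands), key=strands.count) if strands else "+"
    bounds = []
    cursor = chain_blocks[0].start
    for intron, blk_next in zip(chain_introns, chain_blocks[1:]):
        bounds.append((cursor, intron.start - 1))
        cursor = intron.end + 1
    bounds.append((cursor, chain_blocks[-1].end))
    exons = [Exon(region, s, e, strand) for s, e in bounds if s <= e]
    return TranscriptModel(
        id=model_id, exons=exons, biotype="misc_noncoding", source="rnaseq",
    )


# ---------------------------------------------------------------------------
# Coding assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinModelAlignment:
    """A protein-vs-transcript alignment summarised as identity/coverage."""

    model_id: str
    protein_id: str
    identity: float
    coverage: float


def find_orfs(seq: str) -> list[tuple[int, int]]:
    """ATG-initiated ORFs as (start, end) 1-based spans in the sequence,
    each running to the first in-frame stop (included) or sequence end."""
    seq = seq.upper()
    orfs = []
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            if open_start is not None and codon in stops:
                orfs.append((open_start + 1, i + 3))
                open_start = None
            i += 3
        if open_start is not None:
            orfs.append((open_start + 1, len(seq) - (len(seq) - frame) % 3))
    return orfs


def assign_coding(
    models: list[TranscriptModel],
    alignments: list[ProteinModelAlignment],
    genome: dict[str, str],
    min_identity: float = CODING_IDENTITY,
    min_coverage: float = CODING_COVERAGE,
) -> list[TranscriptModel]:
    """Protein-coding iff some protein aligns at >= 80% identity AND coverage.

    The CDS is the longest ORF of the spliced sequence; models without a
    qualifying alignment (or without any ORF) stay non-coding.
    """
    support: dict[str, list[ProteinModelAlignment]] = {}
    for a in alignments:
        if a.identity >= min_identity and a.coverage >= min_coverage:
            support.setdefault(a.model_id, []).append(a)
    out = []
    for m in models:
        hits = support.get(m.id)
        if not hits:
            out.append(m.copy(biotype="misc_noncoding"))
            continue
        orfs = find_orfs(m.spliced_seq(genome))
        if not orfs:
            out.append(m.copy(biotype="misc_noncoding"))
            continue
        a, b = max(orfs, key=lambda o: o[1] - o[0])
        g1, g2 = m.transcript_to_genomic(a), m.transcript_to_genomic(b)
        new = m.copy(
            cds_start=min(g1, g2), cds_end=max(g1, g2), biotype="protein_coding",
        )
        new.evidence_ids = sorted({h.protein_id for h in hits})
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def run_rnaseq(
    reads: list[EvidenceAlignment],
    genome: dict[str, str],
    coding_alignments: list[ProteinModelAlignment] | None = None,
    min_pairs: int = MIN_PAIRS,
    min_spliced: int = MIN_SPLICED,
) -> tuple[list[TranscriptModel], list[IntronFeature]]:
    blocks = collapse_blocks(reads)
    introns = build_intron_features(reads, genome)
    blocks = remove_retained_intron_exons(blocks, introns, min_spliced)
    protos = link_by_pairing(blocks, reads, min_pairs)
    models = []
    for proto in protos:
        models.extend(select_isoform(proto, introns))
    # de-duplicate identical structures from adjacent proto-transcripts
    seen, unique = set(), []
    for m in models:
        key = (m.region, m.strand, tuple((e.start, e.end) for e in m.exons))
        if key not in seen:
            seen.add(key)
            unique.append(m)
    if coding_alignments is not None:
        unique = assign_coding(unique, coding_alignments, genome)
    log.info(
        "rnaseq: %d reads -> %d blocks, %d introns, %d proto-transcripts, %d models",
        len(reads), len(blocks), len(introns), len(protos), len(unique),
    )
    return unique, introns
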