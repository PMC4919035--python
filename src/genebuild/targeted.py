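"""Same-species protein to coding-model stage.

Exact-match protein hits are grouped into candidate loci, each locus is
extended to give a generous genomic context, candidate coding models are
built from the hit blocks (with splice-aware refinement of block edges),
internal stop codons are resolved or the model rejected, tiny frameshift
introns are labelled, and for each protein the candidate whose translation
best matches the input protein — under an affine-gap local alignment — is
selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .core import (
    EvidenceAlignment,
    Exon,
    TranscriptModel,
)

log = logging.getLogger("genebuild")

FRAMESHIFT_LENGTHS = frozenset({1, 2, 4, 5})
DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_EXTENSION_KB = 200
SPLICE_SLIDE_BP = 15

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*U")


@dataclass
class CandidateLocus:
    """All hits of one protein in one genomic neighbourhood."""

    protein_id: str
    region: str
    strand: str
    start: int
    end: int
    hits: list[EvidenceAlignment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Locus grouping and extension
# ---------------------------------------------------------------------------

def group_hits(
    hits: list[EvidenceAlignment], max_gap_bp: int = DEFAULT_MAX_GAP_BP
) -> list[CandidateLocus]:
    """Single-linkage grouping of each protein's hits along the genome.

    Hits of one protein on one region and strand whose gaps do not exceed
    *max_gap_bp* form one maximal locus.
    """
    by_key: dict[tuple, list[EvidenceAlignment]] = {}
    for h in hits:
        by_key.setdefault((h.query_id, h.region, h.strand), []).append(h)
    loci = []
    for (pid, region, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.start)
        current: list[EvidenceAlignment] = []
        for h in group:
            if current and h.start - max(x.end for x in current) - 1 > max_gap_bp:
                loci.append(_locus(pid, region, strand, current))
                current = []
            current.append(h)
        if current:
            loci.append(_locus(pid, region, strand, current))
    return loci


def _locus(pid, region, strand, hits) -> CandidateLocus:
    return CandidateLocus(
        protein_id=pid, region=region, strand=strand,
        start=min(h.start for h in hits), end=max(h.end for h in hits),
        hits=list(hits),
    )


def extend_locus(
    locus: CandidateLocus, region_length: int, extension_kb: float = DEFAULT_EXTENSION_KB
) -> CandidateLocus:
    """Extend the locus span symmetrically, clamped to the region."""
    ext = int(extension_kb * 1000)
    return CandidateLocus(
        protein_id=locus.protein_id, region=locus.region, strand=locus.strand,
        start=max(1, locus.start - ext),
        end=min(region_length, locus.end + ext),
        hits=locus.hits,
    )


# ---------------------------------------------------------------------------
# Candidate model construction
# ---------------------------------------------------------------------------

def canonical_intron(genome: dict[str, str], region: str, s: int, e: int, strand: str) -> bool:
    chrom = genome[region]
    left, right = chrom[s - 1 : s + 1].upper(), chrom[e - 2 : e].upper()
    if strand == "+":
        return left == "GT" and right == "AG"
    return left == "CT" and right == "AC"


def _slide_to_splice(genome, region, s, e, strand, max_slide=SPLICE_SLIDE_BP):
    """Slide intron ends independently (<= max_slide bp) to GT..AG edges."""
    chrom = genome[region]
    donor_di, acceptor_di = ("GT", "AG") if strand == "+" else ("CT", "AC")
    def best_shift(pos, dinuc, at_start):
        for d in sorted(range(-max_slide, max_slide + 1), key=abs):
            p = pos + d
            if at_start:
                if chrom[p - 1 : p + 1].upper() == dinuc:
                    return p
            else:
                if chrom[p - 2 : p].upper() == dinuc:
                    return p
        return pos
    return best_shift(s, donor_di, True), best_shift(e, acceptor_di, False)


def models_from_locus(
    locus: CandidateLocus,
    genome: dict[str, str],
    allow_noncanonical: bool = False,
    id_prefix: str = "targeted",
) -> list[TranscriptModel]:
    """One candidate coding model per hit alignment in the locus.

    Hit blocks become the exon chain; intron edges slide up to 15 bp to the
    nearest consensus splice pair.  The CDS spans the whole chain.
    """
    models = []
    for i, hit in enumerate(sorted(locus.hits, key=lambda h: (h.start, h.query_id))):
        exons = [[gs, ge] for gs, ge, _, _ in hit.blocks]
        for j in range(len(exons) - 1):
            s, e = exons[j][1] + 1, exons[j + 1][0] - 1
            if e < s:
                continue
            if not canonical_intron(genome, locus.region, s, e, locus.strand):
                ns, ne = _slide_to_splice(genome, locus.region, s, e, locus.strand)
                if canonical_intron(genome, locus.region, ns, ne, locus.strand):
                    s, e = ns, ne
                elif not allow_noncanonical:
                    pass  # keep original edges; consensus scoring will punish
            exons[j][1], exons[j + 1][0] = s - 1, e + 1
        try:
            model = TranscriptModel(
                id=f"{id_prefix}_{locus.protein_id}_L{locus.start}_{i}",
                exons=[Exon(locus.region, s, e, locus.strand) for s, e in exons],
                cds_start=min(s for s, _ in exons),
                cds_end=max(e for _, e in exons),
                biotype="protein_coding",
                source="targeted",
                evidence_ids=[locus.protein_id],
            )
        except ValueError as err:
            log.warning("skipping malformed candidate at %s: %s", locus.start, err)
            continue
        if allow_noncanonical:
            noncanon = [
                f"{s}-{e}"
                for s, e in model.introns()
                if not canonical_intron(genome, locus.region, s, e, locus.strand)
            ]
            if noncanon:
                model.attributes["noncanonical_introns"] = ",".join(noncanon)
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Internal stop handling
# ---------------------------------------------------------------------------

def handle_internal_stops(model: TranscriptModel, genome: dict[str, str]):
    """Resolve internal stop codons.

    Returns (status, model) where status is "unchanged", "modified" or
    "rejected".  Exactly one internal stop is excised by a 3-bp frameshift
    intron replacing the stop codon; two or more reject the model.
    Selenocysteine-flagged stops translate as U and are never counted.
    """
    cds = model.cds_seq(genome)
    if len(cds) % 3 != 0:
        log.warning("model %s: CDS length %d not divisible by 3; rejected",
                    model.id, len(cds))
        return "rejected", None
    aa = model.translation(genome)
    internal = [i for i, x in enumerate(aa[:-1]) if x == "*"]
    if not internal:
        return "unchanged", model
    if len(internal) > 1:
        return "rejected", None
    codon_idx = internal[0]
    span = model.cds_transcript_span()
    tpositions = [span[0] + 3 * codon_idx + k for k in range(3)]
    gpositions = {model.transcript_to_genomic(tp) for tp in tpositions}
    new_exons = []
    for e in model.exons:
        pieces, cur = [], None
        for p in range(e.start, e.end + 1):
            if p in gpositions:
                if cur:
                    pieces.append(cur)
                cur = None
            else:
                if cur is None:
                    cur = [p, p]
                else:
                    cur[1] = p
        if cur:
            pieces.append(cur)
        new_exons.extend(Exon(e.region, s, t, e.strand) for s, t in pieces)
    out = model.copy(exons=new_exons)
    out.attributes["internal_stop_replaced"] = str(min(gpositions))
    return "modified", out


def classify_frameshift_introns(model: TranscriptModel) -> TranscriptModel:
    """Label every 1/2/4/5-bp intron with a frameshift attribute.

    The attribute value lists the flagged intron lengths in genomic order;
    recomputation is idempotent.
    """
    flagged = [
        e - s + 1 for s, e in model.introns() if (e - s + 1) in FRAMESHIFT_LENGTHS
    ]
    out = model.copy()
    if flagged:
        out.attributes["frameshift_introns"] = ",".join(str(x) for x in flagged)
    else:
        out.attributes.pop("frameshift_introns", None)
    return out


def count_frameshift_introns(model: TranscriptModel) -> int:
    return sum(1 for s, e in model.introns() if (e - s + 1) in FRAMESHIFT_LENGTHS)


# ---------------------------------------------------------------------------
# Translation-vs-protein scoring and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap local alignment parameters.

    A gap of length L costs open + (L-1)*extend.  When *use_blosum* is set
    the BLOSUM62 matrix replaces the match/mismatch scores.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 2
    use_blosum: bool = True


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.use_blosum:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def score_translation_match(
    model_translation: str, protein: str, scoring: AlignmentScoring | None = None
) -> float:
    """Optimal local-alignment score of a model translation vs its protein."""
    scoring = scoring or AlignmentScoring()
    if not model_translation or not protein:
        raise ValueError("empty sequence")
    for seq in (model_translation, protein):
        bad = set(seq.upper()) - VALID_AA
        if bad:
            raise ValueError(f"non-amino-acid symbols {sorted(bad)!r}")
    a = model_translation.upper().rstrip("*").replace("U", "X").replace("*", "X")
    b = protein.upper().rstrip("*").replace("U", "X").replace("*", "X")
    if not a or not b:
        return 0.0
    return max(0.0, _make_aligner(scoring).score(a, b))


def best_targeted_select(
    candidates: list[TranscriptModel],
    protein: str,
    genome: dict[str, str],
    scoring: AlignmentScoring | None = None,
) -> TranscriptModel | None:
    """Pick the candidate whose translation scores highest against the protein.

    Ties break to fewest frameshift introns, then longest CDS, then
    lexicographically smallest id; the choice is independent of input order.
    """
    best, best_key = None, None
    for m in candidates:
        try:
            score = score_translation_match(m.translation(genome), protein, scoring)
        except ValueError as err:
            log.warning("cannot score %s: %s", m.id, err)
            continue
        span = m.cds_transcript_span()
        cds_len = span[1] - span[0] + 1 if span else 0
        key = (-score, count_frameshift_introns(m), -cds_len, m.id)
        if best_key is None or key < best_key:
            best, best_key = m, key
    return best


# ---------------------------------------------------------------------------
# Selenoproteins
# ---------------------------------------------------------------------------

def apply_selenocysteine(
    model: TranscriptModel, sec_positions: list[int], genome: dict[str, str]
) -> TranscriptModel:
    """Mark flagged stop codons as selenocysteine.

    *sec_positions* are 1-based residue positions on the query protein.  A
    flagged position whose codon is not TGA is a warning and is skipped;
    unflagged stops elsewhere still count as internal stops.
    """
    cds = model.cds_seq(genome)
    flagged = []
    for pos in sec_positions:
        codon = cds[3 * (pos - 1) : 3 * pos].upper()
        if codon == "TGA":
            flagged.append(pos - 1)
        else:
            log.warning(
                "model %s: selenocysteine position %d is %s, not TGA; ignored",
                model.id, pos, codon or "beyond CDS",
            )
    if not flagged:
        return model
    out = model.copy()
    out.attributes["selenocysteine_codons"] = ",".join(str(i) for i in sorted(flagged))
    return out


# ---------------------------------------------------------------------------
# cdna2genome: cDNAs with an annotated CDS range
# ---------------------------------------------------------------------------

def _query_to_genomic(aln: EvidenceAlignment, q: int) -> int | None:
    for gs, ge, qs, qe in aln.blocks:
        if qs <= q <= qe:
            if aln.strand == "-":
                return ge - (q - qs)
            return gs + (q - qs)
    return None


def cdna2genome_models(
    alignments: list[EvidenceAlignment],
    genome: dict[str, str],
    id_prefix: str = "c2g",
) -> list[TranscriptModel]:
    """Coding models from cDNA alignments carrying an annotated CDS range.

    The query CDS range maps through the alignment blocks onto the genome;
    flanking aligned query becomes UTR.  Internal-stop handling then applies
    (at most one internal stop survives, as a 3-bp frameshift intron).
    """
    out = []
    for aln in alignments:
        if not aln.annotated_cds_on_query:
            continue
        qs, qe = aln.annotated_cds_on_query
        g1, g2 = _query_to_genomic(aln, qs), _query_to_genomic(aln, qe)
        if g1 is None or g2 is None:
            log.warning("cdna %s: annotated CDS not covered by alignment; rejected",
                        aln.query_id)
            continue
        model = TranscriptModel(
            id=f"{id_prefix}_{aln.query_id}",
            exons=[Exon(aln.region, gs, ge, aln.strand) for gs, ge, _, _ in aln.blocks],
            cds_start=min(g1, g2),
            cds_end=max(g1, g2),
            biotype="protein_coding",
            source="cdna2genome",
            evidence_ids=[aln.query_id],
        )
        status, fixed = handle_internal_stops(model, genome)
        if status == "rejected":
            log.warning("cdna2genome model %s rejected (internal stops)", model.id)
            continue
        out.append(fixed)
    return out


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def run_targeted(
    protein_hits: list[EvidenceAlignment],
    proteins: dict[str, str],
    genome: dict[str, str],
    region_lengths: dict[str, int],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    extension_kb: float = DEFAULT_EXTENSION_KB,
    extra_candidates: list[TranscriptModel] | None = None,
    scoring: AlignmentScoring | None = None,
) -> list[TranscriptModel]:
    """Full targeted stage: per candidate locus, build and select one model.

    One protein hitting several well-separated loci (e.g. a parent gene and
    a retrotransposed copy) yields one selected model at each locus.
    """
    loci = group_hits(protein_hits, max_gap_bp)
    extra = extra_candidates or []
    selected = []
    for locus in loci:
        hit_span = (locus.start, locus.end)  # before extension
        locus = extend_locus(locus, region_lengths[locus.region], extension_kb)
        candidates = []
        for m in models_from_locus(locus, genome):
            status, fixed = handle_internal_stops(m, genome)
            if status != "rejected":
                candidates.append(classify_frameshift_introns(fixed))
        # competing models at this locus from other methods (e.g. cdna2genome)
        for m in extra:
            if (
                m.region == locus.region
                and m.strand == locus.strand
                and m.start <= hit_span[1]
                and hit_span[0] <= m.end
            ):
                candidates.append(classify_frameshift_introns(m))
        protein = proteins.get(locus.protein_id)
        if protein is None or not candidates:
            continue
        best = best_targeted_select(candidates, protein, genome, scoring)
        if best is not None:
            if locus.protein_id not in best.evidence_ids:
                best = best.copy()
                best.evidence_ids.append(locus.protein_id)
            selected.append(best)
    log.info("targeted: %d loci -> %d selected models", len(loci), len(selected))
    return selected
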