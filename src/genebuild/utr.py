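"""UTR extension of coding models from transcribed evidence.

A coding model built from protein alignment carries no UTR.  When an
RNA-seq, cDNA or EST model matches both boundaries of the coding model's
first intron, its structure donates the 5' UTR; the last intron plays the
same role for the 3' UTR; single-exon models must lie within the donor.
After extension the CDS ends are completed: a missing initial Met is
searched for in the 5' UTR, a missing stop within 150 bases downstream.
Donors are ranked by CAGE/ditag support near their transcript ends.
"""

from __future__ import annotations

import logging

from .core import Exon, TagFeature, TranscriptModel

log = logging.getLogger("genebuild")

STOP_SEARCH_BP = 150
TAG_WINDOW_BP = 50
SOURCE_PRECEDENCE = {"cdna": 0, "rnaseq": 1, "est": 2}
STOPS = {"TAA", "TAG", "TGA"}


def _first_intron(model: TranscriptModel) -> tuple[int, int] | None:
    """The 5'-most intron (genomically last on the minus strand)."""
    intr = model.introns()
    if not intr:
        return None
    return intr[0] if model.strand == "+" else intr[-1]


def _last_intron(model: TranscriptModel) -> tuple[int, int] | None:
    intr = model.introns()
    if not intr:
        return None
    return intr[-1] if model.strand == "+" else intr[0]


def _extend_left(model: TranscriptModel, donor: TranscriptModel, intron) -> TranscriptModel | None:
    """Copy donor structure genomically left of *intron* onto the model."""
    d_exons = [e for e in donor.exons if e.end < intron[0]]
    if not d_exons:
        return None
    flank = d_exons[-1]
    first = model.exons[0]
    if flank.start >= first.start:
        return None  # donor adds nothing on this side
    new_first = Exon(first.region, flank.start, first.end, first.strand)
    utr_exons = [
        Exon(first.region, e.start, e.end, first.strand) for e in d_exons[:-1]
    ]
    return model.copy(exons=utr_exons + [new_first] + model.exons[1:])


def _extend_right(model: TranscriptModel, donor: TranscriptModel, intron) -> TranscriptModel | None:
    d_exons = [e for e in donor.exons if e.start > intron[1]]
    if not d_exons:
        return None
    flank = d_exons[0]
    last = model.exons[-1]
    if flank.end <= last.end:
        return None
    new_last = Exon(last.region, last.start, flank.end, last.strand)
    utr_exons = [
        Exon(last.region, e.start, e.end, last.strand) for e in d_exons[1:]
    ]
    return model.copy(exons=model.exons[:-1] + [new_last] + utr_exons)


def add_utrs(
    coding_model: TranscriptModel, donor_models: list[TranscriptModel]
) -> TranscriptModel:
    """Add UTRs from the first donor whose structure licenses each end.

    Multi-exon models: a donor must match both boundaries of the model's
    first (resp. last) intron exactly to donate the 5' (resp. 3') UTR.
    Single-exon models: the exon must lie within one donor exon.  The CDS
    is never altered; with no matching donor the model returns unchanged.
    """
    model = coding_model
    donors = [
        d for d in donor_models
        if d.region == model.region and d.strand == model.strand
    ]
    if len(model.exons) == 1:
        for d in donors:
            container = next(
                (e for e in d.exons
                 if e.start <= model.start and model.end <= e.end),
                None,
            )
            if container is None:
                continue
            exons = [
                Exon(model.region, e.start, e.end, model.strand) for e in d.exons
            ]
            out = model.copy(exons=exons)
            out.attributes["utr_donor"] = d.id
            return out
        return model
    fi, li = _first_intron(model), _last_intron(model)
    five_side = _extend_left if model.strand == "+" else _extend_right
    three_side = _extend_right if model.strand == "+" else _extend_left
    out = model
    for d in donors:
        if fi in d.introns():
            ext = five_side(out, d, fi)
            if ext is not None:
                ext.attributes["utr_donor_5p"] = d.id
                out = ext
                break
    for d in donors:
        if li in d.introns():
            ext = three_side(out, d, li)
            if ext is not None:
                ext.attributes["utr_donor_3p"] = d.id
                out = ext
                break
    return out


def complete_cds_ends(
    model: TranscriptModel,
    genome: dict[str, str],
    stop_search_bp: int = STOP_SEARCH_BP,
) -> TranscriptModel:
    """Complete a CDS missing its initial Met or terminal stop.

    The 5' UTR is scanned 5'->3' from its start for the first in-frame ATG
    with no intervening in-frame stop (maximal extension); downstream, the
    first in-frame stop within *stop_search_bp* bases of the CDS end is
    adopted (stops beyond the window are ignored).
    """
    if not model.is_coding:
        return model
    seq = model.spliced_seq(genome)
    a, b = model.cds_transcript_span()
    new_a, new_b = a, b
    aa = model.translation(genome)
    if not aa.startswith("M"):
        for p in range(a % 3 or 3, a, 3):
            if p + 2 >= a:
                break
            codon = seq[p - 1 : p + 2].upper()
            # first in-frame ATG not separated from the CDS by an in-frame stop
            if codon == "ATG" and not _stop_between(seq, p + 3, a):
                new_a = p
                break
    if not aa.rstrip().endswith("*"):
        q = b + 1
        while q + 2 <= len(seq) and q + 2 - b <= stop_search_bp:
            if seq[q - 1 : q + 2].upper() in STOPS:
                new_b = q + 2
                break
            q += 3
    if (new_a, new_b) == (a, b):
        return model
    g1 = model.transcript_to_genomic(new_a)
    g2 = model.transcript_to_genomic(new_b)
    return model.copy(cds_start=min(g1, g2), cds_end=max(g1, g2))


def _stop_between(seq: str, start: int, cds_start: int) -> bool:
    for p in range(start, cds_start, 3):
        if p + 2 < cds_start and seq[p - 1 : p + 2].upper() in STOPS:
            return True
    return False


def tag_support(
    donor: TranscriptModel, tags: list[TagFeature], window: int = TAG_WINDOW_BP
) -> int:
    """Number of CAGE/ditag positions within +-window of the donor TSS/TES."""
    tss = donor.start if donor.strand == "+" else donor.end
    tes = donor.end if donor.strand == "+" else donor.start
    n = 0
    for t in tags:
        if t.region != donor.region:
            continue
        if abs(t.position - tss) <= window or abs(t.position - tes) <= window:
            n += 1
    return n


def rank_utr_donors(
    donors: list[TranscriptModel],
    tags: list[TagFeature],
    window: int = TAG_WINDOW_BP,
) -> list[TranscriptModel]:
    """Sort donors by tag support, descending; stable otherwise."""
    return sorted(donors, key=lambda d: -tag_support(d, tags, window))


def run_utr(
    coding_models: list[TranscriptModel],
    donor_models: list[TranscriptModel],
    tags: list[TagFeature],
    genome: dict[str, str],
    stop_search_bp: int = STOP_SEARCH_BP,
) -> list[TranscriptModel]:
    """UTR stage: rank donors (source precedence, then tag support), extend
    every coding model, then complete CDS ends."""
    ranked = sorted(
        rank_utr_donors(donor_models, tags),
        key=lambda d: SOURCE_PRECEDENCE.get(d.source, 3),
    )
    # sorted is stable: tag ranking is preserved within each source class
    out = []
    n_ext = 0
    for m in coding_models:
        if not m.is_coding:
            out.append(m)
            continue
        ext = add_utrs(m, ranked)
        if ext is not m:
            n_ext += 1
        out.append(complete_cds_ends(ext, genome, stop_search_bp))
    log.info("utr: extended %d of %d coding models", n_ext, len(coding_models))
    return out
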