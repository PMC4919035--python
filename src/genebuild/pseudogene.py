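"""Pseudogene labelling of protein-coding gene models.

Three signatures, applied in order with first match winning:

* processed pseudogene — one protein supports both multi-exon and
  single-exon genes; the single-exon ones are retrotransposed copies;
* repeat pseudogene — a high proportion of intronic sequence is repeats,
  suggesting repeat insertion into a once-intronless locus;
* frameshift pseudogene — every intron is under nine bases, i.e. the
  splice structure exists only to paper over a degenerate reading frame.

Labelling never moves a coordinate; only the biotype changes.
"""

from __future__ import annotations

import logging

from .core import GeneModel, RepeatFeature

log = logging.getLogger("genebuild")

REPEAT_INTRON_FRACTION = 0.5
MAX_FRAMESHIFT_INTRON = 9  # strict: an intron of exactly 9 bp does not count


def _relabel(gene: GeneModel, biotype: str) -> GeneModel:
    return GeneModel(
        id=gene.id,
        transcripts=[t.copy(biotype=biotype) for t in gene.transcripts],
        biotype=biotype,
    )


def label_processed(genes: list[GeneModel]) -> list[GeneModel]:
    """Relabel single-exon genes whose supporting protein also supports a
    multi-exon gene.

    Proteins supporting only multi-exon or only single-exon genes are taken
    to mark a functional gene family and cause no relabelling.
    """
    by_evidence: dict[str, list[int]] = {}
    for idx, g in enumerate(genes):
        if g.biotype != "protein_coding":
            continue
        for ev in g.evidence_ids():
            by_evidence.setdefault(ev, []).append(idx)
    to_label: set[int] = set()
    for ev, idxs in by_evidence.items():
        multi = [i for i in idxs if genes[i].is_multi_exon()]
        single = [i for i in idxs if not genes[i].is_multi_exon()]
        if multi and single:
            to_label.update(single)
    out = []
    for idx, g in enumerate(genes):
        out.append(_relabel(g, "processed_pseudogene") if idx in to_label else g)
    if to_label:
        log.info("pseudogene: %d processed pseudogene(s)", len(to_label))
    return out


def repeat_intron_fraction(gene: GeneModel, repeats: list[RepeatFeature]) -> float:
    """Repeat-covered intronic bp over total intronic bp (union per gene)."""
    introns: set[tuple[int, int]] = set()
    for t in gene.transcripts:
        introns.update(t.introns())
    merged: list[list[int]] = []
    for s, e in sorted(introns):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = sum(e - s + 1 for s, e in merged)
    if total == 0:
        return 0.0
    covered = 0
    for s, e in merged:
        for r in repeats:
            if r.region != gene.region:
                continue
            lo, hi = max(s, r.start), min(e, r.end)
            if lo <= hi:
                covered += hi - lo + 1
    return covered / total


def label_repeat_pseudo(
    gene: GeneModel,
    repeats: list[RepeatFeature],
    fraction_threshold: float = REPEAT_INTRON_FRACTION,
) -> GeneModel:
    """Pseudogene iff repeat cover of intronic sequence exceeds the threshold.

    Vacuous for intronless genes.
    """
    if gene.biotype != "protein_coding":
        return gene
    if repeat_intron_fraction(gene, repeats) > fraction_threshold:
        return _relabel(gene, "pseudogene")
    return gene


def label_frameshift_pseudo(gene: GeneModel) -> GeneModel:
    """Pseudogene iff every transcript has introns and all are < 9 bp."""
    if gene.biotype != "protein_coding":
        return gene
    ok = True
    for t in gene.transcripts:
        lengths = [e - s + 1 for s, e in t.introns()]
        if not lengths or any(x >= MAX_FRAMESHIFT_INTRON for x in lengths):
            ok = False
            break
    return _relabel(gene, "pseudogene") if ok else gene


def run_pseudogene(
    genes: list[GeneModel],
    repeats: list[RepeatFeature] | None = None,
    fraction_threshold: float = REPEAT_INTRON_FRACTION,
) -> list[GeneModel]:
    """Apply the three signatures in order; the first match wins per gene."""
    out = []
    for g in label_processed(genes):
        if g.biotype != "protein_coding":
            out.append(g)
            continue
        g2 = label_repeat_pseudo(g, repeats or [], fraction_threshold)
        if g2.biotype != "protein_coding":
            out.append(g2)
            continue
        out.append(label_frameshift_pseudo(g2))
    return out
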