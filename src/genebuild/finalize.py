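"""Gene-set finalization: lincRNAs, manual/automatic merge, stable IDs.

lincRNA candidates are cDNA-derived models away from protein-coding genes;
a candidate with both a substantial open reading frame (>= 35% of its
length) and a protein-domain hit is rejected as likely coding.  The merge
step folds an automatically built gene set under a manually curated one:
where an automatic transcript's intron–exon boundaries, UTRs excluded,
exactly match a manual transcript the two become one merged transcript on
the manual coordinates; everything manual is always retained and automatic
models fill the gaps.  Stable identifiers are then assigned, propagating
ids from a previous annotation by best exon overlap and bumping versions
where coordinates changed.
"""

from __future__ import annotations

import logging
import re

from .core import GeneModel, TranscriptModel
from .rnaseq import find_orfs

log = logging.getLogger("genebuild")

ORF_FRACTION = 0.35
ID_JACCARD_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# lincRNA filtering
# ---------------------------------------------------------------------------

def max_orf_fraction(candidate: TranscriptModel, genome: dict[str, str]) -> float:
    seq = candidate.spliced_seq(genome)
    if not seq:
        return 0.0
    orfs = find_orfs(seq)
    if not orfs:
        return 0.0
    return max(b - a + 1 for a, b in orfs) / len(seq)


def _overlaps_any_exon(model: TranscriptModel, genes: list[GeneModel]) -> bool:
    for g in genes:
        if g.region != model.region or g.start > model.end or model.start > g.end:
            continue
        for t in g.transcripts:
            for e in t.exons:
                for x in model.exons:
                    if x.start <= e.end and e.start <= x.end:
                        return True
    return False


def lincrna_filter(
    candidates: list[TranscriptModel],
    coding_genes: list[GeneModel],
    domain_hits: set[str],
    genome: dict[str, str],
    orf_fraction: float = ORF_FRACTION,
    chromatin_regions: list[tuple[str, int, int]] | None = None,
) -> list[TranscriptModel]:
    """Keep candidates as lincRNA transcripts.

    Drops any candidate exon-overlapping a protein-coding gene (either
    strand); then rejects those with BOTH an ORF covering at least
    *orf_fraction* of their length AND a protein-domain hit; optionally
    requires overlap with a chromatin-methylation region.
    """
    coding = [g for g in coding_genes if g.biotype == "protein_coding"]
    out = []
    for c in candidates:
        if _overlaps_any_exon(c, coding):
            continue
        if chromatin_regions is not None:
            hit = any(
                region == c.region and s <= c.end and c.start <= e
                for region, s, e in chromatin_regions
            )
            if not hit:
                continue
        frac = max_orf_fraction(c, genome)
        has_domain = c.id in domain_hits or bool(set(c.evidence_ids) & domain_hits)
        if frac >= orf_fraction and has_domain:
            continue
        out.append(c.copy(biotype="lincRNA"))
    return out


# ---------------------------------------------------------------------------
# Manual / automatic merge
# ---------------------------------------------------------------------------

def _reduced_chain(t: TranscriptModel) -> tuple:
    """Exon chain for merge comparison, UTR boundaries excluded.

    For coding transcripts the exons are clipped to the CDS span so only the
    coding structure (and hence the reading frame) is compared; non-coding
    transcripts compare their full exon chain.
    """
    if t.is_coding:
        return tuple(t.coding_exons())
    return tuple((e.start, e.end) for e in t.exons)


def _genes_overlap(a: GeneModel, b: GeneModel) -> bool:
    if a.region != b.region or a.strand != b.strand:
        return False
    for t in a.transcripts:
        for u in b.transcripts:
            for x in t.exons:
                for y in u.exons:
                    if x.start <= y.end and y.start <= x.end:
                        return True
    return False


def merge_sets(
    manual_genes: list[GeneModel], automatic_genes: list[GeneModel]
) -> list[GeneModel]:
    """Fold the automatic annotation under the manual one.

    Genes from both sets sharing exon overlap group into one merged gene.
    An automatic transcript whose reduced chain exactly equals a manual
    transcript's merges into it — the manual coordinates are kept and the
    merge is recorded in the manual transcript's attributes.  Non-matching
    automatic transcripts join the merged gene as additional isoforms.
    Manual annotation is never altered; automatic genes with no manual
    overlap carry over unchanged.
    """
    consumed_auto: set[int] = set()
    merged: list[GeneModel] = []
    for mg in manual_genes:
        group = [
            (i, ag)
            for i, ag in enumerate(automatic_genes)
            if i not in consumed_auto and _genes_overlap(mg, ag)
        ]
        transcripts = [t.copy() for t in mg.transcripts]
        manual_chains = {_reduced_chain(t): t for t in transcripts}
        for i, ag in group:
            consumed_auto.add(i)
            for at in ag.transcripts:
                match = manual_chains.get(_reduced_chain(at))
                if match is not None:
                    prev = match.attributes.get("merged_with", "")
                    match.attributes["merged_with"] = (
                        f"{prev},{at.id}" if prev else at.id
                    )
                else:
                    transcripts.append(at)
        merged.append(GeneModel(id=mg.id, transcripts=transcripts,
                                biotype=mg.biotype, version=mg.version))
    for i, ag in enumerate(automatic_genes):
        if i not in consumed_auto:
            merged.append(ag)
    merged.sort(key=lambda g: (g.region, g.start, g.id))
    return merged


# ---------------------------------------------------------------------------
# Stable identifiers
# ---------------------------------------------------------------------------

def _biotype_class(biotype: str) -> str:
    if biotype == "protein_coding":
        return "coding"
    if "pseudogene" in biotype:
        return "pseudo"
    return "noncoding"


def _exon_intervals(g: GeneModel) -> list[tuple[int, int]]:
    ivals = sorted(
        (e.start, e.end) for t in g.transcripts for e in t.exons
    )
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _jaccard(a: GeneModel, b: GeneModel) -> tuple[float, int]:
    if a.region != b.region or a.strand != b.strand:
        return 0.0, 0
    ia, ib = _exon_intervals(a), _exon_intervals(b)
    inter = 0
    for s1, e1 in ia:
        for s2, e2 in ib:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                inter += hi - lo + 1
    la = sum(e - s + 1 for s, e in ia)
    lb = sum(e - s + 1 for s, e in ib)
    union = la + lb - inter
    return (inter / union if union else 0.0), inter


def _structure_key(g: GeneModel) -> tuple:
    return tuple(
        sorted(
            (tuple((e.start, e.end) for e in t.exons), t.cds_start, t.cds_end)
            for t in g.transcripts
        )
    )


def _id_number(stable_id: str) -> int:
    m = re.search(r"(\d+)$", stable_id)
    return int(m.group(1)) if m else 0


def assign_stable_ids(
    new_set: list[GeneModel],
    previous_set: list[GeneModel] | None = None,
    prefix: str = "ENSTOY",
) -> list[GeneModel]:
    """Assign or propagate stable gene identifiers.

    First run: fresh ids, version 1.  Later runs: each new gene takes the id
    of the best-overlapping previous gene of the same biotype class
    (exon-overlap Jaccard >= 0.5, greedy by descending Jaccard, then larger
    overlap, then older id); the version bumps iff the structure changed.
    Unmatched genes get fresh ids; retired ids are never reused.
    """
    previous_set = previous_set or []
    order = {id(g): i for i, g in enumerate(new_set)}
    pairs = []
    for g in new_set:
        for p in previous_set:
            if _biotype_class(g.biotype) != _biotype_class(p.biotype):
                continue
            jac, inter = _jaccard(g, p)
            if jac >= ID_JACCARD_THRESHOLD:
                pairs.append((jac, inter, p, g))
    # greedy: best Jaccard first, then larger overlap, then older previous id
    pairs.sort(key=lambda x: (-x[0], -x[1], _id_number(x[2].id), x[2].id,
                              x[3].region, x[3].start, x[3].id))
    assigned_prev: set[str] = set()
    assigned_new: set[int] = set()
    mapping: dict[int, GeneModel] = {}
    for jac, inter, p, g in pairs:
        if p.id in assigned_prev or id(g) in assigned_new:
            continue
        assigned_prev.add(p.id)
        assigned_new.add(id(g))
        mapping[id(g)] = p
    counter = max((_id_number(p.id) for p in previous_set), default=0)
    out = []
    for g in sorted(new_set, key=lambda g: (g.region, g.start, order[id(g)])):
        prev = mapping.get(id(g))
        if prev is not None:
            version = prev.version + (
                1 if _structure_key(g) != _structure_key(prev) else 0
            )
            out.append(GeneModel(id=prev.id, transcripts=g.transcripts,
                                 biotype=g.biotype, version=version))
        else:
            counter += 1
            out.append(GeneModel(id=f"{prefix}G{counter:08d}",
                                 transcripts=g.transcripts,
                                 biotype=g.biotype, version=1))
    return out
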