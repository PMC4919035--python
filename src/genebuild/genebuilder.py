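"""Gene construction: cluster filtered transcripts, drop redundant isoforms.

Protein-coding transcripts whose coding exons overlap on one strand belong
to one gene (transitive closure); non-coding transcripts cluster by plain
exon overlap.  Within a gene, a transcript whose splice pattern adds
nothing over a longer transcript — its introns a subset of the longer
model's, no unique splices — is removed.
"""

from __future__ import annotations

import logging

from .core import GeneModel, TranscriptModel

log = logging.getLogger("genebuild")


def _intervals_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    for s1, e1 in a:
        for s2, e2 in b:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def _cluster(models: list[TranscriptModel], key_intervals) -> list[list[TranscriptModel]]:
    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.region, m.strand), []).append(m)
    out = []
    for group in groups.values():
        group.sort(key=lambda m: (m.start, m.id))
        parent = list(range(len(group)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ivals = [key_intervals(m) for m in group]
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].start > group[i].end:
                    break
                if _intervals_overlap(ivals[i], ivals[j]):
                    parent[find(i)] = find(j)
        comp: dict[int, list[TranscriptModel]] = {}
        for i, m in enumerate(group):
            comp.setdefault(find(i), []).append(m)
        out.extend(comp.values())
    return out


def cluster_genes(
    models: list[TranscriptModel], id_prefix: str = "gene"
) -> list[GeneModel]:
    """Group transcripts into genes.

    Coding models join a gene when their coding exons overlap; non-coding
    models when any exons overlap.  Coding and non-coding models never share
    a gene.
    """
    coding = [m for m in models if m.is_coding]
    noncoding = [m for m in models if not m.is_coding]
    clusters = _cluster(coding, lambda m: m.coding_exons())
    clusters += _cluster(noncoding, lambda m: [(e.start, e.end) for e in m.exons])
    clusters.sort(key=lambda c: (c[0].region, min(t.start for t in c), c[0].id))
    genes = []
    for i, cluster in enumerate(clusters):
        cluster.sort(key=lambda t: (t.start, t.id))
        biotype = (
            "protein_coding" if cluster[0].is_coding else cluster[0].biotype
        )
        genes.append(
            GeneModel(id=f"{id_prefix}_{i + 1:05d}", transcripts=cluster, biotype=biotype)
        )
    return genes


def _is_redundant(t: TranscriptModel, other: TranscriptModel) -> bool:
    """True if *t* adds no splicing over the longer model *other*."""
    if other is t:
        return False
    longer = (
        other.exon_length(),
        len(other.introns()),
        # deterministic final tie-break so exact duplicates drop one side only
        t.id,
    ) > (t.exon_length(), len(t.introns()), other.id)
    if not longer:
        return False
    if len(t.exons) == 1:
        return any(e.start <= t.start and t.end <= e.end for e in other.exons)
    return t.intron_set() <= other.intron_set()


def remove_redundant(gene: GeneModel) -> GeneModel:
    """Drop transcripts with completely redundant splicing patterns.

    Supporting-evidence identifiers of a dropped transcript move to the
    longer transcript that subsumed it, so a gene keeps the full record of
    which sequences support it.
    """
    keep, dropped = [], []
    for t in gene.transcripts:
        subsumer = next(
            (u for u in gene.transcripts if _is_redundant(t, u)), None
        )
        if subsumer is None:
            keep.append(t)
        else:
            dropped.append((t, subsumer))
    if not keep:
        return gene
    kept_by_id = {t.id: t.copy() for t in keep}
    for t, subsumer in dropped:
        target = kept_by_id.get(subsumer.id)
        while target is None:
            # subsumer itself was dropped; follow the chain
            subsumer = next(u for u in gene.transcripts if _is_redundant(subsumer, u))
            target = kept_by_id.get(subsumer.id)
        for ev in t.evidence_ids:
            if ev not in target.evidence_ids:
                target.evidence_ids.append(ev)
    if dropped:
        log.info("gene %s: removed %d redundant transcript(s)", gene.id, len(dropped))
    return GeneModel(
        id=gene.id,
        transcripts=[kept_by_id[t.id] for t in keep],
        biotype=gene.biotype,
    )


def run_genebuilder(
    models: list[TranscriptModel], id_prefix: str = "gene"
) -> list[GeneModel]:
    return [remove_redundant(g) for g in cluster_genes(models, id_prefix)]
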