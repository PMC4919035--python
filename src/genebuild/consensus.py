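"""Transcript-consensus classification and layer-hierarchy filtering.

Each candidate coding model is scored by how well its introns and exon
boundaries are matched by same-species transcribed evidence (cDNA, EST and
RNA-seq models, plus RNA-seq introns).  Within a cluster of overlapping
models the high scorers are "good", low scorers "bad"; clusters with fewer
than six same-species evidence models cannot be scored reliably and every
model in them is "small".  Layer filtering then keeps a lower-priority
model only where nothing in a preferred layer overlaps it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import IntronFeature, TranscriptModel

log = logging.getLogger("genebuild")

MIN_DEPTH = 6
BAD_FRACTION = 0.75


@dataclass(frozen=True)
class ConsensusVerdict:
    model_id: str
    score: float
    label: str  # good | bad | small
    depth: int


def consensus_score(
    model: TranscriptModel,
    evidence_models: list[TranscriptModel],
    rnaseq_introns: list[IntronFeature] | None = None,
) -> float:
    """Fraction of the model's splice structure matched by evidence, in [0,1].

    Matched introns count fully, matched exon boundaries half:
    (mI + mB/2) / (nI + nB/2).
    """
    relevant = [
        e for e in evidence_models
        if e.region == model.region and e.strand == model.strand
        and e.start <= model.end and model.start <= e.end
    ]
    ev_introns = set()
    ev_bounds = set()
    for e in relevant:
        ev_introns.update(e.introns())
        for x in e.exons:
            ev_bounds.update((x.start, x.end))
    for i in rnaseq_introns or []:
        if i.region == model.region and i.strand == model.strand:
            ev_introns.add((i.start, i.end))
            ev_bounds.update((i.start - 1, i.end + 1))
    introns = model.introns()
    bounds = [c for e in model.exons for c in (e.start, e.end)]
    denom = len(introns) + 0.5 * len(bounds)
    if denom == 0:
        return 0.0
    m_i = sum(1 for i in introns if i in ev_introns)
    m_b = sum(1 for c in bounds if c in ev_bounds)
    return (m_i + 0.5 * m_b) / denom


def cluster_by_overlap(
    models: list[TranscriptModel], use_exons: bool = True
) -> list[list[TranscriptModel]]:
    """Transitive closure of same-strand overlap (exon-level by default)."""
    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.region, m.strand), []).append(m)
    clusters = []
    for group in groups.values():
        group.sort(key=lambda m: (m.start, m.id))
        parent = list(range(len(group)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].start > group[i].end:
                    break
                if not use_exons or _exons_overlap(group[i], group[j]):
                    parent[find(i)] = find(j)
        comp: dict[int, list[TranscriptModel]] = {}
        for i, m in enumerate(group):
            comp.setdefault(find(i), []).append(m)
        clusters.extend(comp.values())
    clusters.sort(key=lambda c: (c[0].region, c[0].start, c[0].id))
    return clusters


def _exons_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for x in a.exons:
        for y in b.exons:
            if x.start <= y.end and y.start <= x.end:
                return True
    return False


def consensus_classify(
    cluster: list[TranscriptModel],
    evidence_models: list[TranscriptModel],
    rnaseq_introns: list[IntronFeature] | None = None,
    min_depth: int = MIN_DEPTH,
    bad_fraction: float = BAD_FRACTION,
) -> list[ConsensusVerdict]:
    """Label one overlap-cluster of models good/bad/small.

    Depth is the number of distinct same-species evidence models overlapping
    the cluster; below *min_depth* nothing can be scored and every model is
    "small".  Otherwise a model is "good" iff its score reaches
    *bad_fraction* of the cluster's best score.
    """
    if not cluster:
        return []
    region = cluster[0].region
    lo = min(m.start for m in cluster)
    hi = max(m.end for m in cluster)
    depth = len(
        {
            e.id
            for e in evidence_models
            if e.region == region and e.start <= hi and lo <= e.end
        }
    )
    scores = {
        m.id: consensus_score(m, evidence_models, rnaseq_introns) for m in cluster
    }
    if depth < min_depth:
        return [ConsensusVerdict(m.id, scores[m.id], "small", depth) for m in cluster]
    top = max(scores.values())
    return [
        ConsensusVerdict(
            m.id,
            scores[m.id],
            "good" if scores[m.id] >= bad_fraction * top else "bad",
            depth,
        )
        for m in cluster
    ]


def classify_all(
    models: list[TranscriptModel],
    evidence_models: list[TranscriptModel],
    rnaseq_introns: list[IntronFeature] | None = None,
    min_depth: int = MIN_DEPTH,
    bad_fraction: float = BAD_FRACTION,
) -> dict[str, ConsensusVerdict]:
    verdicts: dict[str, ConsensusVerdict] = {}
    for cluster in cluster_by_overlap(models):
        for v in consensus_classify(
            cluster, evidence_models, rnaseq_introns, min_depth, bad_fraction
        ):
            verdicts[v.model_id] = v
    return verdicts


# ---------------------------------------------------------------------------
# Layer annotation
# ---------------------------------------------------------------------------

SAME_SPECIES_SOURCES = {"targeted", "cdna2genome", "rnaseq"}


def assign_layers(
    models: list[TranscriptModel],
    verdicts: dict[str, ConsensusVerdict] | None = None,
) -> list[TranscriptModel]:
    """Default hierarchy: same-species models in layer 1; "good" similarity
    models next (near taxa before the rest), "small" last; "bad" models
    never enter layering."""
    verdicts = verdicts or {}
    out = []
    for m in models:
        if m.source in SAME_SPECIES_SOURCES:
            layer = 1
        else:
            v = verdicts.get(m.id)
            label = v.label if v else "small"
            if label == "bad":
                continue
            if label == "small":
                layer = 4
            else:
                layer = 2 if m.attributes.get("taxon_distance") == "near" else 3
        out.append(m.copy(layer=layer))
    return out


def layer_filter(models: list[TranscriptModel]) -> list[TranscriptModel]:
    """Keep lower-layer models only where no kept preferred model overlaps.

    All layer-1 models are kept; a layer-k model survives iff none of its
    exons overlaps, on the same strand, an exon of a kept model from any
    layer < k.  The result is independent of within-layer input order.
    """
    for m in models:
        if m.layer is None:
            raise ValueError(f"model {m.id} has no layer assigned")
    kept: list[TranscriptModel] = []
    for layer in sorted({m.layer for m in models}):
        tier = sorted((m for m in models if m.layer == layer), key=lambda m: m.id)
        lower = [k for k in kept if k.layer < layer]
        for m in tier:
            clash = any(
                k.region == m.region and k.strand == m.strand and _exons_overlap(m, k)
                for k in lower
            )
            if not clash:
                kept.append(m)
    kept.sort(key=lambda m: (m.region, m.start, m.id))
    return kept
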