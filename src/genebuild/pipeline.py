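"""End-to-end genebuild: evidence in, filtered multi-biotype gene set out.

Stage order follows the annotation system's protein-coding model building:
targeted (and cdna2genome) coding models, RNA-seq models and introns, UTR
extension, consensus classification, layer filtering, gene construction,
pseudogene labelling, lincRNA annotation and stable-identifier assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from . import consensus as consensus_mod
from . import finalize as finalize_mod
from . import genebuilder, pseudogene, rnaseq, targeted, utr
from .core import (
    EvidenceAlignment,
    GeneModel,
    RepeatFeature,
    SeqRegion,
    TagFeature,
    TranscriptModel,
    build_toplevel,
)
from .io_formats import PipelineConfig

log = logging.getLogger("genebuild")


@dataclass
class EvidenceSet:
    """All pre-computed evidence a run consumes."""

    protein_hits: list[EvidenceAlignment] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    cdna_alignments: list[EvidenceAlignment] = field(default_factory=list)
    reads: list[EvidenceAlignment] = field(default_factory=list)
    tags: list[TagFeature] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)
    domain_hits: set[str] = field(default_factory=set)


def cdna_models(alignments: list[EvidenceAlignment]) -> list[TranscriptModel]:
    """Plain transcript models from cDNA/EST alignments (UTR donors,
    consensus evidence and lincRNA candidates)."""
    from .core import Exon

    out = []
    for a in alignments:
        out.append(
            TranscriptModel(
                id=f"cdnamodel_{a.query_id}",
                exons=[Exon(a.region, gs, ge, a.strand) for gs, ge, _, _ in a.blocks],
                biotype="misc_noncoding",
                source="cdna" if a.query_type == "cdna" else a.query_type,
                evidence_ids=[a.query_id],
            )
        )
    return out


def _identity_coverage(model_aa: str, protein: str) -> tuple[float, float]:
    """Percent identity and protein coverage of a global protein alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    a = model_aa.rstrip("*").replace("U", "X").replace("*", "X")
    if not a or not protein:
        return 0.0, 0.0
    aln = aligner.align(a, protein)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    coverage = 100.0 * aligned_cols / len(protein)
    return identity, coverage


def score_proteins_vs_models(
    models: list[TranscriptModel],
    proteins: dict[str, str],
    protein_hits: list[EvidenceAlignment],
    genome: dict[str, str],
) -> list[rnaseq.ProteinModelAlignment]:
    """Identity/coverage of each protein against models overlapping its hits.

    The model side of the alignment is the translation of its longest ORF.
    """
    spans: dict[str, list[tuple[str, int, int]]] = {}
    for h in protein_hits:
        spans.setdefault(h.query_id, []).append((h.region, h.start, h.end))
    out = []
    for m in models:
        orfs = rnaseq.find_orfs(m.spliced_seq(genome))
        if not orfs:
            continue
        a, b = max(orfs, key=lambda o: o[1] - o[0])
        from .core import translate_cds

        model_aa = translate_cds(m.spliced_seq(genome)[a - 1 : b])
        for pid, regions in spans.items():
            if not any(
                r == m.region and s <= m.end and m.start <= e for r, s, e in regions
            ):
                continue
            identity, coverage = _identity_coverage(model_aa, proteins[pid])
            out.append(rnaseq.ProteinModelAlignment(m.id, pid, identity, coverage))
    return out


@dataclass
class GenebuildResult:
    genes: list[GeneModel]
    rnaseq_introns: list
    verdicts: dict

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    def by_biotype(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[g.biotype] = out.get(g.biotype, 0) + 1
        return out

    def intron_set(self) -> set[tuple[str, int, int]]:
        out = set()
        for g in self.genes:
            for t in g.transcripts:
                for s, e in t.introns():
                    out.add((t.region, s, e))
        return out


def run_genebuild(
    genome: dict[str, str],
    regions: list[SeqRegion],
    mappings: list,
    evidence: EvidenceSet,
    config: PipelineConfig | None = None,
    previous_set: list[GeneModel] | None = None,
    id_prefix: str = "ENSTOY",
) -> GenebuildResult:
    config = config or PipelineConfig()
    thr = config.thresholds
    toplevel = build_toplevel(mappings, regions)
    log.info("toplevel regions: %s", ", ".join(r.name for r in toplevel))
    region_lengths = {name: len(seq) for name, seq in genome.items()}

    # coding models from same-species proteins, with cdna2genome competitors
    c2g = targeted.cdna2genome_models(evidence.cdna_alignments, genome)
    targeted_models = targeted.run_targeted(
        evidence.protein_hits,
        evidence.proteins,
        genome,
        region_lengths,
        extension_kb=thr["extension_kb"],
        extra_candidates=c2g,
    )

    # RNA-seq models and intron features; coding status from protein hits
    rnaseq_models, introns = rnaseq.run_rnaseq(evidence.reads, genome)
    coding_alignments = score_proteins_vs_models(
        rnaseq_models, evidence.proteins, evidence.protein_hits, genome
    )
    rnaseq_models = rnaseq.assign_coding(
        rnaseq_models,
        coding_alignments,
        genome,
        min_identity=thr["coding_identity"],
        min_coverage=thr["coding_coverage"],
    )

    donors = cdna_models(evidence.cdna_alignments) + [
        m for m in rnaseq_models if not m.is_coding
    ] + [m.copy(cds_start=None, cds_end=None) for m in rnaseq_models if m.is_coding]

    candidates = targeted_models + [m for m in rnaseq_models if m.is_coding]
    candidates = utr.run_utr(
        candidates, donors, evidence.tags, genome,
        stop_search_bp=int(thr["stop_search_bp"]),
    )

    verdicts = consensus_mod.classify_all(
        candidates,
        cdna_models(evidence.cdna_alignments) + rnaseq_models,
        introns,
        min_depth=int(thr["consensus_min_depth"]),
        bad_fraction=thr["consensus_bad_fraction"],
    )
    layered = consensus_mod.assign_layers(candidates, verdicts)
    kept = consensus_mod.layer_filter(layered)

    genes = genebuilder.run_genebuilder(kept)
    genes = pseudogene.run_pseudogene(
        genes, evidence.repeats, thr["repeat_intron_fraction"]
    )

    linc_candidates = [
        m for m in cdna_models(evidence.cdna_alignments)
    ]
    linc_transcripts = finalize_mod.lincrna_filter(
        linc_candidates,
        [g for g in genes if g.biotype == "protein_coding"],
        evidence.domain_hits,
        genome,
        orf_fraction=thr["orf_fraction"],
    )
    linc_genes = genebuilder.cluster_genes(linc_transcripts, id_prefix="linc")

    all_genes = genes + linc_genes
    all_genes = finalize_mod.assign_stable_ids(all_genes, previous_set, id_prefix)
    result = GenebuildResult(all_genes, introns, verdicts)
    log.info("genebuild: %s", result.by_biotype())
    return result
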