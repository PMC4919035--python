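"""Readers and writers for the formats the pipeline composes on disk.

FASTA goes through Bio.SeqIO, GFF3/GTF parsing through gffutils (in-memory
database); AGP v2.0 and BED12 have small dedicated parsers.  All other
modules do their file I/O through this one.
"""

from __future__ import annotations

import logging
import sys

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AssemblyError,
    AssemblyMapping,
    EvidenceAlignment,
    Exon,
    GeneModel,
    IntronFeature,
    RepeatFeature,
    SeqRegion,
    TagFeature,
    TranscriptModel,
)

log = logging.getLogger("genebuild")

BIOTYPES = {
    "protein_coding",
    "processed_pseudogene",
    "pseudogene",
    "lincRNA",
    "misc_noncoding",
}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# AGP v2.0
# ---------------------------------------------------------------------------

def read_agp(path) -> list[AssemblyMapping]:
    """Parse AGP component lines (W/F); gap lines (N/U) carry no mapping."""
    mappings = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise AssemblyError(f"{path}:{lineno}: short AGP line")
            comp_type = f[4]
            if comp_type in ("N", "U"):
                continue
            if comp_type not in ("W", "F", "A", "D", "G", "O", "P"):
                raise AssemblyError(f"{path}:{lineno}: bad component type {comp_type}")
            mappings.append(
                AssemblyMapping(
                    component=f[5],
                    component_start=int(f[6]),
                    component_end=int(f[7]),
                    target=f[0],
                    target_start=int(f[1]),
                    target_end=int(f[2]),
                    orientation="-" if len(f) > 8 and f[8] == "-" else "+",
                )
            )
    return mappings


def write_agp(mappings: list[AssemblyMapping], gaps, path) -> None:
    """Write component lines plus N-gap lines; *gaps* is [(target, start, end)]."""
    lines = []
    for m in mappings:
        lines.append(
            (m.target, m.target_start, m.target_end, "W",
             m.component, m.component_start, m.component_end, m.orientation)
        )
    for target, start, end in gaps:
        lines.append((target, start, end, "N", end - start + 1, "scaffold", "yes", "paired-ends"))
    lines.sort(key=lambda l: (l[0], l[1]))
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        part = {}
        for l in lines:
            part[l[0]] = part.get(l[0], 0) + 1
            fh.write("\t".join(str(x) for x in (l[0], l[1], l[2], part[l[0]], *l[3:])) + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF gene models
# ---------------------------------------------------------------------------

def _fmt_attrs_gff3(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_models(genes: list[GeneModel], path, dialect: str = "gff3") -> None:
    genes = sorted(genes, key=lambda g: (g.region, g.start, g.id))
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                _write_gene_gff3(g, fh)
        elif dialect == "gtf":
            for g in genes:
                _write_gene_gtf(g, fh)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def _transcript_extra_attrs(t: TranscriptModel) -> dict[str, str]:
    extra = {"source_set": t.source}
    if t.layer is not None:
        extra["layer"] = str(t.layer)
    if t.evidence_ids:
        extra["evidence_ids"] = ",".join(t.evidence_ids)
    for k, v in sorted(t.attributes.items()):
        extra[k] = str(v)
    return extra


def _write_gene_gff3(g: GeneModel, fh) -> None:
    src = "genebuild"
    fh.write(
        f"{g.region}\t{src}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
        + _fmt_attrs_gff3({"ID": g.id, "biotype": g.biotype, "version": str(g.version)})
        + "\n"
    )
    for t in sorted(g.transcripts, key=lambda t: (t.start, t.id)):
        attrs = {"ID": t.id, "Parent": g.id, "biotype": t.biotype}
        attrs.update(_transcript_extra_attrs(t))
        fh.write(
            f"{g.region}\t{src}\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
            + _fmt_attrs_gff3(attrs)
            + "\n"
        )
        for i, e in enumerate(t.exons, 1):
            fh.write(
                f"{g.region}\t{src}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t"
                + _fmt_attrs_gff3({"ID": f"{t.id}.exon{i}", "Parent": t.id})
                + "\n"
            )
        if t.is_coding:
            _write_cds_and_utrs_gff3(t, fh, src)


def _cds_pieces(t: TranscriptModel) -> list[tuple[int, int, int]]:
    """CDS intervals with GFF phase column values, in 5'->3' order."""
    pieces = t.coding_exons()
    if t.strand == "-":
        pieces = pieces[::-1]
    out, done = [], 0
    for s, e in pieces:
        frame = (3 - done % 3) % 3
        out.append((s, e, frame))
        done += e - s + 1
    return out


def _write_cds_and_utrs_gff3(t: TranscriptModel, fh, src: str) -> None:
    for s, e, frame in sorted(_cds_pieces(t)):
        fh.write(
            f"{t.region}\t{src}\tCDS\t{s}\t{e}\t.\t{t.strand}\t{frame}\t"
            + _fmt_attrs_gff3({"ID": f"{t.id}.cds", "Parent": t.id})
            + "\n"
        )
    for s, e, kind in _utr_pieces(t):
        fh.write(
            f"{t.region}\t{src}\t{kind}\t{s}\t{e}\t.\t{t.strand}\t.\t"
            + _fmt_attrs_gff3({"Parent": t.id})
            + "\n"
        )


def _utr_pieces(t: TranscriptModel) -> list[tuple[int, int, str]]:
    out = []
    for e in t.exons:
        if e.end < t.cds_start:
            left = (e.start, e.end)
        elif e.start < t.cds_start:
            left = (e.start, t.cds_start - 1)
        else:
            left = None
        if left:
            kind = "five_prime_UTR" if t.strand == "+" else "three_prime_UTR"
            out.append((left[0], left[1], kind))
        if e.start > t.cds_end:
            right = (e.start, e.end)
        elif e.end > t.cds_end:
            right = (t.cds_end + 1, e.end)
        else:
            right = None
        if right:
            kind = "three_prime_UTR" if t.strand == "+" else "five_prime_UTR"
            out.append((right[0], right[1], kind))
    return sorted(out)


def _write_gene_gtf(g: GeneModel, fh) -> None:
    src = "genebuild"
    for t in sorted(g.transcripts, key=lambda t: (t.start, t.id)):
        base = f'gene_id "{g.id}"; transcript_id "{t.id}"; biotype "{t.biotype}";'
        fh.write(f"{g.region}\t{src}\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{base}\n")
        for e in t.exons:
            fh.write(f"{g.region}\t{src}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t{base}\n")
        if t.is_coding:
            # stop codon included in the CDS on output (single convention)
            for s, e, frame in sorted(_cds_pieces(t)):
                fh.write(f"{g.region}\t{src}\tCDS\t{s}\t{e}\t.\t{t.strand}\t{frame}\t{base}\n")


def read_models(path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models; records whose CDS falls outside exons are rejected
    with a logged warning and parsing continues."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    if dialect == "gtf":
        return _models_from_gtf_db(db)
    return _models_from_gff3_db(db)


def _models_from_gff3_db(db) -> list[GeneModel]:
    genes = []
    for grec in db.features_of_type("gene"):
        transcripts = []
        for trec in db.children(grec, level=1):
            if trec.featuretype not in ("mRNA", "transcript"):
                continue
            t = _transcript_from_children(db, trec)
            if t is not None:
                transcripts.append(t)
        if transcripts:
            biotype = grec.attributes.get("biotype", ["protein_coding"])[0]
            version = int(grec.attributes.get("version", ["1"])[0])
            genes.append(
                GeneModel(id=grec.id, transcripts=transcripts, biotype=biotype,
                          version=version)
            )
    return genes


def _transcript_from_children(db, trec) -> TranscriptModel | None:
    exons, cds = [], []
    for child in db.children(trec, level=1):
        if child.featuretype == "exon":
            exons.append(
                Exon(child.seqid, child.start, child.end, child.strand)
            )
        elif child.featuretype == "CDS":
            cds.append((child.start, child.end))
    if not exons:
        return None
    attrs = dict(trec.attributes)
    biotype = attrs.pop("biotype", ["misc_noncoding"])[0]
    source = attrs.pop("source_set", ["external"])[0]
    layer = attrs.pop("layer", [None])[0]
    evidence = attrs.pop("evidence_ids", [""])[0]
    extra = {
        k: v[0]
        for k, v in attrs.items()
        if k not in ("ID", "Parent", "gene_id", "transcript_id")
    }
    cds_start = min(s for s, _ in cds) if cds else None
    cds_end = max(e for _, e in cds) if cds else None
    try:
        t = TranscriptModel(
            id=trec.id,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            biotype=biotype,
            source=source,
            layer=int(layer) if layer is not None else None,
            evidence_ids=[e for e in evidence.split(",") if e],
            attributes=extra,
        )
        if t.is_coding:
            t.cds_transcript_span()  # raises if CDS outside exon union
    except ValueError as err:
        log.warning("rejecting transcript %s: %s", trec.id, err)
        return None
    return t


def _models_from_gtf_db(db) -> list[GeneModel]:
    by_gene: dict[str, dict[str, dict]] = {}
    for rec in db.all_features():
        if rec.featuretype not in ("exon", "CDS"):
            continue
        gid = rec.attributes["gene_id"][0]
        tid = rec.attributes["transcript_id"][0]
        slot = by_gene.setdefault(gid, {}).setdefault(
            tid, {"exons": [], "cds": [], "biotype": None}
        )
        if rec.featuretype == "exon":
            slot["exons"].append(Exon(rec.seqid, rec.start, rec.end, rec.strand))
        else:
            slot["cds"].append((rec.start, rec.end))
        bt = rec.attributes.get("biotype", [None])[0]
        if bt:
            slot["biotype"] = bt
    genes = []
    for gid, trs in sorted(by_gene.items()):
        transcripts = []
        for tid, slot in sorted(trs.items()):
            if not slot["exons"]:
                continue
            cds = slot["cds"]
            biotype = slot["biotype"] or ("protein_coding" if cds else "misc_noncoding")
            try:
                t = TranscriptModel(
                    id=tid,
                    exons=slot["exons"],
                    cds_start=min(s for s, _ in cds) if cds else None,
                    cds_end=max(e for _, e in cds) if cds else None,
                    biotype=biotype,
                )
                if t.is_coding:
                    t.cds_transcript_span()
            except ValueError as err:
                log.warning("rejecting transcript %s: %s", tid, err)
                continue
            transcripts.append(t)
        if transcripts:
            genes.append(
                GeneModel(id=gid, transcripts=transcripts, biotype=transcripts[0].biotype)
            )
    return genes


# ---------------------------------------------------------------------------
# Evidence alignments: GFF3 match/match_part or BED12
# ---------------------------------------------------------------------------

def read_evidence(path) -> list[EvidenceAlignment]:
    path = str(path)
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff") or "\tmatch\t" in head:
        return _read_evidence_gff3(path)
    return read_bed12(path)


def _parse_gff3_attrs(s: str) -> dict[str, str]:
    out = {}
    for item in s.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_evidence_gff3(path) -> list[EvidenceAlignment]:
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("match", "match_part"):
                continue
            attrs = _parse_gff3_attrs(f[8])
            if f[2] == "match":
                mid = attrs.get("ID", attrs.get("Name", ""))
                g = groups.setdefault(mid, {"blocks": [], "meta": {}})
                g["meta"] = {
                    "region": f[0],
                    "strand": f[6],
                    "query_id": attrs.get("Name", mid),
                    "query_type": attrs.get("query_type", "cdna"),
                    "identity": float(attrs.get("identity", 100.0)),
                    "coverage": float(attrs.get("coverage", 100.0)),
                    "cds": attrs.get("annotated_cds"),
                    "mate": attrs.get("mate_id"),
                }
            else:
                mid = attrs.get("Parent", "")
                g = groups.setdefault(mid, {"blocks": [], "meta": {}})
                target = attrs.get("Target", "").split()
                qs, qe = (int(target[1]), int(target[2])) if len(target) >= 3 else (0, 0)
                g["blocks"].append((int(f[3]), int(f[4]), qs, qe))
    out = []
    for mid, g in sorted(groups.items()):
        if not g["blocks"] or not g["meta"]:
            continue
        meta = g["meta"]
        cds = meta["cds"]
        out.append(
            EvidenceAlignment(
                query_id=meta["query_id"],
                query_type=meta["query_type"],
                region=meta["region"],
                strand=meta["strand"],
                blocks=sorted(g["blocks"]),
                percent_identity=meta["identity"],
                query_coverage=meta["coverage"],
                annotated_cds_on_query=tuple(int(x) for x in cds.split("-")) if cds else None,
                mate_id=meta["mate"],
            )
        )
    return out


def write_evidence_gff3(alignments: list[EvidenceAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(sorted(alignments, key=lambda a: (a.region, a.start))):
            mid = f"match{i:06d}"
            attrs = [
                f"ID={mid}",
                f"Name={a.query_id}",
                f"query_type={a.query_type}",
                f"identity={a.percent_identity:g}",
                f"coverage={a.query_coverage:g}",
            ]
            if a.annotated_cds_on_query:
                attrs.append(
                    f"annotated_cds={a.annotated_cds_on_query[0]}-{a.annotated_cds_on_query[1]}"
                )
            if a.mate_id:
                attrs.append(f"mate_id={a.mate_id}")
            fh.write(
                f"{a.region}\tevidence\tmatch\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t"
                + ";".join(attrs) + "\n"
            )
            for gs, ge, qs, qe in a.blocks:
                fh.write(
                    f"{a.region}\tevidence\tmatch_part\t{gs}\t{ge}\t.\t{a.strand}\t.\t"
                    f"Parent={mid};Target={a.query_id} {qs} {qe}\n"
                )


def read_bed12(path) -> list[EvidenceAlignment]:
    """BED12 read blocks -> alignments; BED is 0-based half-open on disk.

    On the minus strand query coordinates run backwards along the genome:
    the genomically last block holds the start of the query.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start = f[0], int(f[1])
            name = f[3] if len(f) > 3 else "read"
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            else:
                sizes, offsets = [int(f[2]) - chrom_start], [0]
            genomic = [
                (chrom_start + off + 1, chrom_start + off + sz)
                for off, sz in zip(offsets, sizes)
            ]
            blocks = []
            if strand == "-":
                qpos = 1
                for gs, ge in reversed(genomic):
                    blocks.append((gs, ge, qpos, qpos + (ge - gs)))
                    qpos += ge - gs + 1
            else:
                qpos = 1
                for gs, ge in genomic:
                    blocks.append((gs, ge, qpos, qpos + (ge - gs)))
                    qpos += ge - gs + 1
            mate = None
            if "/" in name:
                stem, num = name.rsplit("/", 1)
                if num in ("1", "2"):
                    mate = f"{stem}/{'2' if num == '1' else '1'}"
            out.append(
                EvidenceAlignment(
                    query_id=name,
                    query_type="read",
                    region=chrom,
                    strand=strand,
                    blocks=blocks,
                    mate_id=mate,
                )
            )
    return out


def write_bed12(alignments: list[EvidenceAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            start0 = a.start - 1
            sizes = ",".join(str(ge - gs + 1) for gs, ge, _, _ in a.blocks)
            offsets = ",".join(str(gs - a.start) for gs, ge, _, _ in a.blocks)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.region, start0, a.end, a.query_id, 0, a.strand,
                        start0, a.end, "0,0,0", len(a.blocks), sizes, offsets,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Simple feature files (introns, repeats, tags) as GFF3
# ---------------------------------------------------------------------------

def write_introns(introns: list[IntronFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in sorted(introns, key=lambda x: (x.region, x.start)):
            fh.write(
                f"{i.region}\trnaseq\tintron\t{i.start}\t{i.end}\t{i.depth}\t"
                f"{i.strand}\t.\tcanonical={'true' if i.canonical else 'false'}\n"
            )


def read_introns(path) -> list[IntronFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "intron":
                continue
            out.append(
                IntronFeature(
                    region=f[0], start=int(f[3]), end=int(f[4]), strand=f[6],
                    depth=int(float(f[5])),
                    canonical="canonical=true" in f[8],
                )
            )
    return out


def write_repeats(repeats: list[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(repeats, key=lambda x: (x.region, x.start)):
            fh.write(
                f"{r.region}\trepeat\trepeat_region\t{r.start}\t{r.end}\t.\t+\t.\t"
                f"repeat_class={r.repeat_class}\n"
            )


def read_repeats(path) -> list[RepeatFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            cls = _parse_gff3_attrs(f[8]).get("repeat_class", "unknown")
            out.append(RepeatFeature(f[0], int(f[3]), int(f[4]), cls))
    return out


def write_tags(tags: list[TagFeature], path) -> None:
    """Tags as BED6: position as a 1-bp interval, count in the score column."""
    with open(path, "w") as fh:
        for t in sorted(tags, key=lambda x: (x.region, x.position)):
            fh.write(
                f"{t.region}\t{t.position - 1}\t{t.position}\t{t.tag_type}\t"
                f"{t.count}\t{t.strand}\n"
            )


def read_tags(path) -> list[TagFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                TagFeature(
                    region=f[0], position=int(f[1]) + 1, strand=f[5],
                    tag_type=f[3], count=int(f[4]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

THRESHOLD_DEFAULTS = {
    "extension_kb": 200.0,        # locus extension each side, kb
    "coding_identity": 80.0,      # %, protein-vs-model coding call
    "coding_coverage": 80.0,      # %, protein-vs-model coding call
    "consensus_min_depth": 6.0,   # same-species models needed to score
    "consensus_bad_fraction": 0.75,
    "repeat_intron_fraction": 0.5,
    "stop_search_bp": 150.0,      # downstream stop-codon search limit
    "orf_fraction": 0.35,         # lincRNA ORF-coverage rejection threshold
}

THRESHOLD_RANGES = {
    "extension_kb": (0, 10_000),
    "coding_identity": (0, 100),
    "coding_coverage": (0, 100),
    "consensus_min_depth": (0, 1000),
    "consensus_bad_fraction": (0, 1),
    "repeat_intron_fraction": (0, 1),
    "stop_search_bp": (0, 100_000),
    "orf_fraction": (0, 1),
}

DEFAULT_LAYER_HIERARCHY = [
    ("targeted", 1),
    ("rnaseq", 1),
    ("similarity_good_near", 2),
    ("similarity_good", 3),
    ("similarity_small", 4),
]


class PipelineConfig:
    """Flat key/value run configuration: layer hierarchy + named thresholds."""

    def __init__(self, layer_hierarchy=None, thresholds=None, seed: int = 0):
        self.layer_hierarchy = list(layer_hierarchy or DEFAULT_LAYER_HIERARCHY)
        self.thresholds = dict(THRESHOLD_DEFAULTS)
        self.thresholds.update(thresholds or {})
        self.seed = seed
        layers = sorted({lay for _, lay in self.layer_hierarchy})
        if layers != list(range(1, len(layers) + 1)):
            raise ValueError(f"layers must be numbered 1..K contiguously, got {layers}")
        for k, v in self.thresholds.items():
            lo, hi = THRESHOLD_RANGES.get(k, (float("-inf"), float("inf")))
            if not (lo <= v <= hi):
                raise ValueError(f"threshold {k}={v} outside [{lo}, {hi}]")

    def layer_for(self, selector: str) -> int | None:
        for sel, lay in self.layer_hierarchy:
            if sel == selector:
                return lay
        return None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        thresholds, hierarchy, seed = {}, [], 0
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key == "seed":
                    seed = int(val)
                elif key.startswith("layer."):
                    hierarchy.append((key[len("layer."):], int(val)))
                else:
                    thresholds[key] = float(val)
        return cls(hierarchy or None, thresholds, seed)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed = {self.seed}\n")
            for sel, lay in self.layer_hierarchy:
                fh.write(f"layer.{sel} = {lay}\n")
            for k, v in sorted(self.thresholds.items()):
                fh.write(f"{k} = {v:g}\n")


def setup_logging(level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
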