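"""Domain types and assembly-coordinate logic shared by every stage.

The unit flowing through the whole system is the :class:`TranscriptModel`:
an ordered exon chain on one sequence region and strand, optionally carrying
a CDS, a biotype, a priority layer and the identifiers of the evidence that
supports it.  Everything upstream produces transcript models; everything
downstream filters, groups or relabels them.

Coordinates are 1-based and inclusive throughout (the GTF/GFF3 convention);
BED input/output converts at the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "SeqRegion",
    "AssemblyMapping",
    "Exon",
    "TranscriptModel",
    "GeneModel",
    "EvidenceAlignment",
    "IntronFeature",
    "RepeatFeature",
    "TagFeature",
    "AssemblyError",
    "build_toplevel",
    "project_coordinate",
    "revcomp",
    "translate_cds",
    "GAP",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    for (b1, b2, b3), aa in zip(itertools.product(bases, bases, bases), aas):
        _CODON_TABLE[b1 + b2 + b3] = aa


_build_codon_table()

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_cds(seq: str, sec_codon_indices: set[int] | None = None) -> str:
    """Translate a nucleotide CDS, codon by codon.

    Stop codons translate to ``*``; codon indices listed in
    *sec_codon_indices* translate TGA to selenocysteine ``U`` instead.
    """
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if sec_codon_indices and i // 3 in sec_codon_indices and codon == "TGA":
            aa.append("U")
        else:
            aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


class AssemblyError(ValueError):
    """Fatal inconsistency in assembly mappings."""


@dataclass(frozen=True)
class SeqRegion:
    name: str
    length: int
    coord_system: str  # contig | scaffold | chromosome
    is_toplevel: bool = False

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"region {self.name}: length must be >= 1")


@dataclass(frozen=True)
class AssemblyMapping:
    """One AGP component line: component interval == target interval."""

    component: str
    component_start: int
    component_end: int
    target: str
    target_start: int
    target_end: int
    orientation: str = "+"  # + | -

    def __post_init__(self):
        if (self.component_end - self.component_start) != (
            self.target_end - self.target_start
        ):
            raise AssemblyError(
                f"mapping {self.component}->{self.target}: span lengths differ"
            )
        if self.orientation not in "+-":
            raise AssemblyError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class Exon:
    region: str
    start: int
    end: int
    strand: str
    phase: int = -1  # -1 iff exon fully non-coding

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon {self.start}-{self.end}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Exon") -> bool:
        return (
            self.region == other.region
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon chain with optional CDS, flowing through every stage.

    Exons are kept sorted by ascending genomic start regardless of strand;
    5'->3' order on the minus strand is the reverse.  ``cds_start`` and
    ``cds_end`` are genomic (cds_start <= cds_end) and, when set, include the
    terminal stop codon.
    """

    id: str
    exons: list[Exon]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "misc_noncoding"
    source: str = "external"
    layer: int | None = None
    evidence_ids: list[str] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        regions = {e.region for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(regions) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id}: exons not colinear")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.id}: half-open CDS")

    # -- geometry ---------------------------------------------------------

    @property
    def region(self) -> str:
        return self.exons[0].region

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[tuple[int, int]]:
        """Intron spans as (first intronic bp, last intronic bp)."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.introns())

    def exon_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def coding_exons(self) -> list[tuple[int, int]]:
        """Exon intervals clipped to the CDS span (genomic)."""
        if not self.is_coding:
            return []
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s <= t:
                out.append((s, t))
        return out

    # -- sequence ---------------------------------------------------------

    def spliced_seq(self, genome: dict[str, str]) -> str:
        chrom = genome[self.region]
        seq = "".join(chrom[e.start - 1 : e.end] for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic bp to a 1-based position in the spliced transcript."""
        off = 0
        for e in self.exons:
            if e.start <= pos <= e.end:
                t = off + (pos - e.start) + 1
                return self.exon_length() - t + 1 if self.strand == "-" else t
            off += e.length
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` (tpos 1-based)."""
        if self.strand == "-":
            tpos = self.exon_length() - tpos + 1
        off = 0
        for e in self.exons:
            if tpos <= off + e.length:
                return e.start + (tpos - off - 1)
            off += e.length
        raise ValueError(f"transcript position {tpos} beyond transcript")

    def cds_transcript_span(self) -> tuple[int, int] | None:
        """CDS as a (start, end) interval in spliced-transcript coordinates."""
        if not self.is_coding:
            return None
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end)
        if a is None or b is None:
            raise ValueError(f"transcript {self.id}: CDS outside exons")
        return (min(a, b), max(a, b))

    def cds_seq(self, genome: dict[str, str]) -> str:
        span = self.cds_transcript_span()
        if span is None:
            return ""
        return self.spliced_seq(genome)[span[0] - 1 : span[1]]

    def translation(self, genome: dict[str, str]) -> str:
        sec = self.attributes.get("selenocysteine_codons")
        sec_idx = {int(x) for x in sec.split(",")} if sec else None
        return translate_cds(self.cds_seq(genome), sec_idx)

    def copy(self, **changes) -> "TranscriptModel":
        new = replace(self, **changes)
        if "exons" not in changes:
            new.exons = list(self.exons)
        if "evidence_ids" not in changes:
            new.evidence_ids = list(self.evidence_ids)
        if "attributes" not in changes:
            new.attributes = dict(self.attributes)
        return new


@dataclass
class GeneModel:
    id: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"
    version: int = 1  # stable-id version; bumps when coordinates change

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")
        if len({(t.region, t.strand) for t in self.transcripts}) > 1:
            raise ValueError(f"gene {self.id}: transcripts on mixed region/strand")

    @property
    def region(self) -> str:
        return self.transcripts[0].region

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def is_multi_exon(self) -> bool:
        return any(len(t.exons) > 1 for t in self.transcripts)

    def evidence_ids(self) -> set[str]:
        out: set[str] = set()
        for t in self.transcripts:
            out.update(t.evidence_ids)
        return out


@dataclass
class EvidenceAlignment:
    """A spliced alignment of one evidence sequence against the genome.

    ``blocks`` are (genomic_start, genomic_end, query_start, query_end),
    all 1-based inclusive, colinear and non-overlapping on both axes.
    """

    query_id: str
    query_type: str  # protein | cdna | est | read
    region: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    percent_identity: float = 100.0
    query_coverage: float = 100.0
    annotated_cds_on_query: tuple[int, int] | None = None
    mate_id: str | None = None

    def __post_init__(self):
        self.blocks = sorted(self.blocks, key=lambda b: b[0])
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity outside [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise ValueError("query_coverage outside [0, 100]")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"alignment {self.query_id}: genomic blocks overlap")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def implied_introns(self) -> list[tuple[int, int]]:
        return [
            (a[1] + 1, b[0] - 1) for a, b in zip(self.blocks, self.blocks[1:])
        ]


@dataclass(frozen=True)
class IntronFeature:
    """An observed splice junction: first to last intronic bp, inclusive."""

    region: str
    start: int
    end: int
    strand: str
    depth: int = 1
    canonical: bool = True


@dataclass(frozen=True)
class RepeatFeature:
    region: str
    start: int
    end: int
    repeat_class: str = "unknown"


@dataclass(frozen=True)
class TagFeature:
    """A transcription start/end tag (CAGE or ditag) at a single position."""

    region: str
    position: int
    strand: str
    tag_type: str  # cage | ditag_start | ditag_end
    count: int = 1


# ---------------------------------------------------------------------------
# Assembly mapping
# ---------------------------------------------------------------------------

GAP = None  # sentinel returned by project_coordinate for assembly gaps


def build_toplevel(
    mappings: list[AssemblyMapping], regions: list[SeqRegion]
) -> list[SeqRegion]:
    """Flag as toplevel every region that is not a component of another.

    Toplevel is a virtual coordinate system: the chromosomes plus any
    scaffold or contig not placed within a larger region.  Annotation runs
    on toplevel sequences only.
    """
    by_name = {r.name: r for r in regions}
    for m in mappings:
        if m.component not in by_name or m.target not in by_name:
            raise AssemblyError(
                f"mapping references unknown region "
                f"{m.component if m.component not in by_name else m.target!r}"
            )
        comp, targ = by_name[m.component], by_name[m.target]
        if m.component_end > comp.length or m.component_start < 1:
            raise AssemblyError(f"component span outside {comp.name}")
        if m.target_end > targ.length or m.target_start < 1:
            raise AssemblyError(f"target span outside {targ.name}")
    # overlapping target intervals on one target are fatal
    per_target: dict[str, list[tuple[int, int]]] = {}
    for m in mappings:
        per_target.setdefault(m.target, []).append((m.target_start, m.target_end))
    for name, ivals in per_target.items():
        ivals.sort()
        for a, b in zip(ivals, ivals[1:]):
            if b[0] <= a[1]:
                raise AssemblyError(f"overlapping target intervals on {name}")
    components = {m.component for m in mappings}
    return [
        replace(r, is_toplevel=True) for r in regions if r.name not in components
    ]


def project_coordinate(
    pos: tuple[str, int],
    mappings: list[AssemblyMapping],
    target_system: str,
    regions: list[SeqRegion],
    _visited: frozenset[str] = frozenset(),
):
    """Project (region, bp) into *target_system*; return (region, bp) or GAP.

    Projects up (component -> target) or down (target -> component) depending
    on which side of a mapping the position sits; chains through intermediate
    systems (contig -> chromosome via scaffold).  A position falling in an
    assembly gap projects to GAP (None) — not an error.
    """
    systems = {r.name: r.coord_system for r in regions}
    name, bp = pos
    if name not in systems:
        raise AssemblyError(f"unknown region {name!r}")
    _visited = _visited | {name}
    if systems[name] == target_system:
        return pos
    for m in mappings:
        if (
            m.component == name
            and systems.get(m.target) == target_system
            and m.component_start <= bp <= m.component_end
        ):
            off = bp - m.component_start
            if m.orientation == "+":
                return (m.target, m.target_start + off)
            return (m.target, m.target_end - off)
        if (
            m.target == name
            and systems.get(m.component) == target_system
            and m.target_start <= bp <= m.target_end
        ):
            off = bp - m.target_start
            if m.orientation == "+":
                return (m.component, m.component_start + off)
            return (m.component, m.component_end - off)
    # multi-hop projection (e.g. contig -> chromosome via scaffold)
    for m in mappings:
        if (
            m.component == name
            and m.target not in _visited
            and m.component_start <= bp <= m.component_end
        ):
            off = bp - m.component_start
            if m.orientation == "+":
                up = (m.target, m.target_start + off)
            else:
                up = (m.target, m.target_end - off)
            res = project_coordinate(up, mappings, target_system, regions, _visited)
            if res is not GAP:
                return res
        if (
            m.target == name
            and m.component not in _visited
            and m.target_start <= bp <= m.target_end
        ):
            off = bp - m.target_start
            if m.orientation == "+":
                down = (m.component, m.component_start + off)
            else:
                down = (m.component, m.component_end - off)
            res = project_coordinate(down, mappings, target_system, regions, _visited)
            if res is not GAP:
                return res
    return GAP
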