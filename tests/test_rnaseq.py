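"""RNA-seq stage: collapse, introns, retained-intron removal, isoform choice."""

import numpy as np
import pytest

from genebuild.core import EvidenceAlignment, IntronFeature
from genebuild.rnaseq import (
    Block,
    ProteinModelAlignment,
    ProtoTranscript,
    assign_coding,
    build_intron_features,
    collapse_blocks,
    link_by_pairing,
    remove_retained_intron_exons,
    select_isoform,
)


def read(blocks, name="r", region="chr1", strand="+", mate=None):
    qs = 1
    qblocks = []
    for gs, ge in blocks:
        qblocks.append((gs, ge, qs, qs + ge - gs))
        qs += ge - gs + 1
    return EvidenceAlignment(query_id=name, query_type="read", region=region,
                             strand=strand, blocks=qblocks, mate_id=mate)


class TestCollapseBlocks:
    def test_overlapping_reads_one_block(self):
        blocks = collapse_blocks([read([(100, 200)]), read([(150, 250)])])
        assert [(b.start, b.end) for b in blocks] == [(100, 250)]

    def test_disjoint_reads_distinct_blocks(self):
        blocks = collapse_blocks([read([(100, 200)]), read([(400, 500)])])
        assert [(b.start, b.end) for b in blocks] == [(100, 200), (400, 500)]

    def test_mean_depth_recorded(self):
        # two reads fully tiling 100-199 -> depth 2.0
        blocks = collapse_blocks([read([(100, 199)]), read([(100, 199)])])
        assert blocks[0].mean_depth == pytest.approx(2.0)

    def test_fixture_exon_depth_near_nominal(self, small_fixture, small_evidence):
        blocks = collapse_blocks(small_evidence.reads)
        truth = next(g for g in small_fixture.genes
                     if not g.is_lincrna and len(g.transcript.exons) >= 3)
        interior = truth.transcript.exons[1]
        cover = [b for b in blocks if b.start <= interior.start and interior.end <= b.end]
        assert cover, "interior exon not covered by any collapsed block"


class TestIntronFeatures:
    genome = {"chr1": "A" * 99 + "C" + "GT" + "A" * 46 + "AG" + "C" * 100}

    def test_depth_counts_supporting_reads(self):
        reads = [read([(50, 100), (151, 200)], name=f"r{i}") for i in range(7)]
        (intron,) = build_intron_features(reads, self.genome)
        assert intron.depth == 7
        assert (intron.start, intron.end) == (101, 150)

    def test_gt_ag_is_canonical_forward(self):
        (intron,) = build_intron_features([read([(50, 100), (151, 200)])], self.genome)
        assert intron.canonical and intron.strand == "+"

    def test_ct_ac_gives_minus_strand(self):
        genome = {"chr1": "A" * 100 + "CT" + "A" * 46 + "AC" + "C" * 100}
        (intron,) = build_intron_features([read([(50, 100), (151, 200)])], genome)
        assert intron.canonical and intron.strand == "-"

    def test_other_dinucleotides_noncanonical(self):
        genome = {"chr1": "A" * 300}
        (intron,) = build_intron_features([read([(50, 100), (151, 200)])], genome)
        assert not intron.canonical


class TestRemoveRetained:
    def test_contained_intron_splits_block(self):
        blocks = [Block("chr1", 100, 400, 30.0)]
        introns = [IntronFeature("chr1", 180, 320, "+", depth=5)]
        out = remove_retained_intron_exons(blocks, introns)
        assert [(b.start, b.end) for b in out] == [(100, 179), (321, 400)]

    def test_no_contained_intron_unchanged(self):
        blocks = [Block("chr1", 100, 400, 30.0)]
        out = remove_retained_intron_exons(
            blocks, [IntronFeature("chr1", 500, 600, "+", depth=5)]
        )
        assert [(b.start, b.end) for b in out] == [(100, 400)]

    def test_overlapping_but_not_contained_unchanged(self):
        blocks = [Block("chr1", 100, 400, 30.0)]
        out = remove_retained_intron_exons(
            blocks, [IntronFeature("chr1", 350, 500, "+", depth=5)]
        )
        assert [(b.start, b.end) for b in out] == [(100, 400)]

    def test_below_min_spliced_ignored(self):
        blocks = [Block("chr1", 100, 400, 30.0)]
        out = remove_retained_intron_exons(
            blocks, [IntronFeature("chr1", 180, 320, "+", depth=1)], min_spliced=2
        )
        assert [(b.start, b.end) for b in out] == [(100, 400)]


def paired_reads(block_a, block_b, n, stem):
    """n read pairs linking two genomic intervals."""
    out = []
    for i in range(n):
        out.append(read([block_a], name=f"{stem}{i}/1", mate=f"{stem}{i}/2"))
        out.append(read([block_b], name=f"{stem}{i}/2", mate=f"{stem}{i}/1"))
    return out


class TestLinkByPairing:
    blocks = [Block("chr1", 100, 200, 10.0), Block("chr1", 300, 400, 10.0),
              Block("chr1", 500, 600, 10.0)]

    def test_chained_pairs_one_proto(self):
        reads = paired_reads((120, 180), (320, 380), 2, "ab")
        reads += paired_reads((320, 380), (520, 580), 2, "bc")
        protos = link_by_pairing(self.blocks, reads)
        assert len(protos) == 1 and len(protos[0].blocks) == 3

    def test_no_pairs_singletons(self):
        reads = [read([(120, 180)], name="solo")]
        protos = link_by_pairing(self.blocks, reads)
        assert len(protos) == 3

    def test_below_min_pairs_not_linked(self):
        reads = paired_reads((120, 180), (320, 380), 1, "ab")
        protos = link_by_pairing(self.blocks, reads, min_pairs=2)
        assert len(protos) == 3

    def test_matches_component_oracle(self):
        """Proto-transcript membership equals brute-force components over
        block pairs linked by >= min_pairs read pairs."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            n_blocks = int(rng.integers(2, 8))
            blocks = [
                Block("chr1", 1000 * i + 1, 1000 * i + 200, 5.0)
                for i in range(n_blocks)
            ]
            reads, edges = [], {}
            for p in range(int(rng.integers(0, 12))):
                a, b = rng.integers(0, n_blocks, size=2)
                reads += paired_reads(
                    (blocks[a].start + 10, blocks[a].start + 60),
                    (blocks[b].start + 10, blocks[b].start + 60),
                    1, f"p{p}_",
                )
                key = tuple(sorted((int(a), int(b))))
                if key[0] != key[1]:
                    edges[key] = edges.get(key, 0) + 1
            protos = link_by_pairing(blocks, reads, min_pairs=2)
            # oracle: BFS over edges with multiplicity >= 2
            strong = [e for e, c in edges.items() if c >= 2]
            comp = list(range(n_blocks))
            for a, b in strong:
                ra, rb = comp[a], comp[b]
                comp = [ra if c == rb else c for c in comp]
            expected = {}
            for i in range(n_blocks):
                expected.setdefault(comp[i], set()).add(blocks[i].start)
            got = {frozenset(b.start for b in p.blocks) for p in protos}
            assert got == {frozenset(v) for v in expected.values()}


def enumerate_chains(blocks, introns):
    """All exon–intron chains consistent with blocks and introns (oracle)."""
    blocks = sorted(blocks, key=lambda b: b.start)
    edges = []
    for intron in introns:
        for ai, a in enumerate(blocks):
            for bi, b in enumerate(blocks):
                if ai < bi and a.start <= intron.start - 1 <= a.end \
                        and b.start <= intron.end + 1 <= b.end:
                    edges.append((ai, bi, intron))
    chains = []

    def extend(path, used_introns):
        chains.append((list(path), list(used_introns)))
        for a, b, intron in edges:
            if a != path[-1]:
                continue
            # consecutive introns must leave a non-empty exon between them
            if used_introns and used_introns[-1].end + 1 > intron.start - 1:
                continue
            extend(path + [b], used_introns + [intron])

    for i in range(len(blocks)):
        extend([i], [])
    return blocks, chains


class TestSelectIsoform:
    def proto(self, blocks):
        return ProtoTranscript(region="chr1", blocks=blocks)

    def test_deeper_junction_wins(self):
        blocks = [Block("chr1", 100, 200, 10.0), Block("chr1", 300, 400, 10.0),
                  Block("chr1", 500, 600, 10.0)]
        introns = [IntronFeature("chr1", 201, 299, "+", depth=9),
                   IntronFeature("chr1", 201, 499, "+", depth=5)]
        (model,) = select_isoform(self.proto(blocks), introns)
        assert (201, 299) in model.introns()

    def test_single_unambiguous_chain(self):
        blocks = [Block("chr1", 100, 200, 10.0), Block("chr1", 300, 400, 10.0)]
        introns = [IntronFeature("chr1", 201, 299, "+", depth=4)]
        (model,) = select_isoform(self.proto(blocks), introns)
        assert [(e.start, e.end) for e in model.exons] == [(100, 200), (300, 400)]

    def test_no_consistent_chain_fragments(self, caplog):
        blocks = [Block("chr1", 100, 200, 10.0), Block("chr1", 300, 400, 10.0)]
        with caplog.at_level("WARNING", logger="genebuild"):
            models = select_isoform(self.proto(blocks), [])
        assert len(models) == 2
        assert all(len(m.exons) == 1 for m in models)

    def test_matches_exhaustive_chain_oracle(self):
        """Chosen chain attains the maximum score over all enumerable chains."""
        rng = np.random.default_rng(41)
        for _ in range(25):
            n_blocks = int(rng.integers(1, 6))
            blocks = [
                Block("chr1", 1000 * i + 1, 1000 * i + int(rng.integers(100, 900)),
                      float(rng.integers(1, 30)))
                for i in range(n_blocks)
            ]
            introns = []
            for _ in range(int(rng.integers(0, 7))):
                a, b = sorted(rng.integers(0, n_blocks, size=2))
                if a == b:
                    continue
                s = blocks[a].start + int(rng.integers(1, blocks[a].end - blocks[a].start))
                e = blocks[b].start + int(rng.integers(0, blocks[b].end - blocks[b].start - 1))
                if e + 1 > blocks[b].end or s - 1 < blocks[a].start:
                    continue
                introns.append(IntronFeature("chr1", s, e, "+",
                                             depth=int(rng.integers(1, 50))))
            # drop introns whose flanks fall outside their blocks
            introns = [
                i for i in introns
                if any(b.start <= i.start - 1 <= b.end for b in blocks)
                and any(b.start <= i.end + 1 <= b.end for b in blocks)
                and i.start <= i.end
            ]
            oblocks, chains = enumerate_chains(blocks, introns)
            if not chains:
                continue
            best = max(
                sum(i.depth for i in ch_introns)
                + sum(oblocks[i].mean_depth for i in ch_blocks)
                for ch_blocks, ch_introns in chains
            )
            models = select_isoform(self.proto(blocks), introns)
            if len(models) != 1:
                continue  # fragmented: no edges existed
            (model,) = models
            depth_by_span = {(i.start, i.end): i.depth for i in introns}
            got = sum(depth_by_span[s] for s in model.introns())
            block_of = {
                b.start: b.mean_depth for b in blocks
            }
            # each exon lies within exactly one source block
            exon_depth = 0.0
            for e in model.exons:
                src = next(b for b in blocks if b.start <= e.start <= b.end)
                exon_depth += src.mean_depth
            assert got + exon_depth == pytest.approx(best)


class TestAssignCoding:
    def setup_model(self):
        cds = "ATG" + "AAA" * 30 + "TAA"
        genome = {"chr1": "C" * 50 + cds + "C" * 50}
        from conftest import make_transcript

        m = make_transcript([(1, len(genome["chr1"]))], tid="m1", source="rnaseq")
        return m, genome

    @pytest.mark.parametrize(
        "identity,coverage,coding",
        [(85.0, 90.0, True), (85.0, 70.0, False), (70.0, 90.0, False),
         (80.0, 80.0, True)],
    )
    def test_threshold_truth_table(self, identity, coverage, coding):
        m, genome = self.setup_model()
        alns = [ProteinModelAlignment("m1", "p1", identity, coverage)]
        (out,) = assign_coding([m], alns, genome)
        assert out.is_coding is coding
        assert out.biotype == ("protein_coding" if coding else "misc_noncoding")

    def test_no_alignments_noncoding(self):
        m, genome = self.setup_model()
        (out,) = assign_coding([m], [], genome)
        assert not out.is_coding

    def test_cds_is_longest_orf(self):
        m, genome = self.setup_model()
        (out,) = assign_coding([m], [ProteinModelAlignment("m1", "p", 99, 99)], genome)
        assert (out.cds_start, out.cds_end) == (51, 51 + 95)


def test_max_pair_span_filter_discards_implausible_pairs():
    blocks = [Block("chr1", 100, 200, 10.0), Block("chr1", 900_000, 900_100, 10.0)]
    reads = paired_reads((120, 180), (900_010, 900_060), 3, "far")
    linked = link_by_pairing(blocks, reads, min_pairs=2)
    assert len(linked) == 1  # off by default: the distant pair links
    capped = link_by_pairing(blocks, reads, min_pairs=2, max_pair_span=10_000)
    assert len(capped) == 2
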