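"""Targeted stage: locus grouping, stop handling, selection, alignment oracle."""

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genebuild.core import EvidenceAlignment, TranscriptModel
from genebuild.fixtures import SENSE_CODONS
from genebuild.targeted import (
    AlignmentScoring,
    CandidateLocus,
    apply_selenocysteine,
    best_targeted_select,
    cdna2genome_models,
    classify_frameshift_introns,
    extend_locus,
    group_hits,
    handle_internal_stops,
    models_from_locus,
    score_translation_match,
)

from conftest import make_transcript


def hit(pid, start, end, region="chr1", strand="+"):
    return EvidenceAlignment(
        query_id=pid, query_type="protein", region=region, strand=strand,
        blocks=[(start, end, 1, end - start + 1)],
    )


class TestGroupHits:
    def test_close_hits_one_locus(self):
        hits = [hit("p", s, s + 100) for s in (1000, 2000, 3000)]
        loci = group_hits(hits, max_gap_bp=200_000)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1000, 3100)

    def test_distant_hits_two_loci(self):
        loci = group_hits([hit("p", 1000, 1100), hit("p", 501_000, 501_100)],
                          max_gap_bp=200_000)
        assert len(loci) == 2

    def test_different_proteins_never_group(self):
        loci = group_hits([hit("a", 100, 200), hit("b", 150, 250)])
        assert len(loci) == 2

    def test_matches_single_linkage_oracle(self):
        """Locus membership equals brute-force single-linkage clustering."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(1, 12))
            gap = int(rng.integers(50, 500))
            starts = sorted(int(x) for x in rng.integers(1, 10_000, size=n))
            hits = [hit("p", s, s + int(rng.integers(10, 80))) for s in starts]
            loci = group_hits(hits, max_gap_bp=gap)
            # oracle: iterate merging any two clusters with gap <= threshold
            clusters = [[h] for h in hits]
            changed = True
            while changed:
                changed = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        lo1 = min(h.start for h in clusters[i])
                        hi1 = max(h.end for h in clusters[i])
                        lo2 = min(h.start for h in clusters[j])
                        hi2 = max(h.end for h in clusters[j])
                        d = max(lo1, lo2) - min(hi1, hi2) - 1
                        if d <= gap:
                            clusters[i] += clusters.pop(j)
                            changed = True
                            break
                    if changed:
                        break
            expected = sorted(
                tuple(sorted(id(h) for h in c)) for c in clusters
            )
            got = sorted(tuple(sorted(id(h) for h in l.hits)) for l in loci)
            assert got == expected


class TestExtendLocus:
    def locus(self, start, end):
        return CandidateLocus("p", "chr1", "+", start, end, [])

    def test_extends_200kb_each_side(self):
        out = extend_locus(self.locus(300_000, 310_000), region_length=1_000_000)
        assert (out.start, out.end) == (100_000, 510_000)

    def test_clamps_at_region_start(self):
        out = extend_locus(self.locus(50_000, 60_000), region_length=1_000_000)
        assert out.start == 1

    def test_short_region_becomes_whole_region(self):
        out = extend_locus(self.locus(10_000, 20_000), region_length=150_000)
        assert (out.start, out.end) == (1, 150_000)


class TestInternalStops:
    def model_for(self, cds):
        genome = {"chr1": "TTTT" + cds + "TTTT"}
        m = make_transcript([(5, 4 + len(cds))], cds=(5, 4 + len(cds)),
                            biotype="protein_coding")
        return m, genome

    def test_no_stops_unchanged(self):
        m, genome = self.model_for("ATGAAACCCTAA")
        status, out = handle_internal_stops(m, genome)
        assert status == "unchanged" and out is m

    def test_single_stop_excised_by_3bp_intron(self):
        m, genome = self.model_for("ATGAAATGACCCTAA")
        status, out = handle_internal_stops(m, genome)
        assert status == "modified"
        assert len(out.exons) == len(m.exons) + 1
        intron_lengths = [e - s + 1 for s, e in out.introns()]
        assert intron_lengths == [3]
        aa = out.translation(genome)
        assert "*" not in aa[:-1] and aa == "MKP*"

    def test_two_stops_rejected(self):
        m, genome = self.model_for("ATGTGAAAATGACCCTAA")
        status, out = handle_internal_stops(m, genome)
        assert status == "rejected" and out is None

    def test_partial_codon_rejected(self):
        m, genome = self.model_for("ATGAAACCCTAAG")  # 13 bp
        status, _ = handle_internal_stops(m, genome)
        assert status == "rejected"

    def test_selenocysteine_stop_not_counted(self):
        # TGA at codon 1 flagged as Sec; the unflagged TGA still rejects as
        # a single internal stop would, so here it is excised instead
        m, genome = self.model_for("ATGTGAAAATAA")
        m = apply_selenocysteine(m, [2], genome)
        status, out = handle_internal_stops(m, genome)
        assert status == "unchanged"
        assert out.translation(genome) == "MUK*"


class TestSelenocysteine:
    def test_flagged_position_not_a_stop_warns_no_change(self, caplog):
        genome = {"chr1": "ATGAAACCCTAA"}
        m = make_transcript([(1, 12)], cds=(1, 12))
        with caplog.at_level("WARNING", logger="genebuild"):
            out = apply_selenocysteine(m, [2], genome)
        assert out is m
        assert any("not TGA" in r.message for r in caplog.records)

    def test_unflagged_stop_still_internal(self):
        genome = {"chr1": "ATGTGAAAATGATAA"}
        m = make_transcript([(1, 15)], cds=(1, 15))
        m = apply_selenocysteine(m, [2], genome)  # flags first TGA only
        status, out = handle_internal_stops(m, genome)
        assert status == "modified"  # second TGA excised
        assert out.translation(genome) == "MUK*"


class TestFrameshiftIntrons:
    def ladder(self, lengths):
        exons, pos = [], 1
        for L in lengths + [None]:
            exons.append((pos, pos + 9))
            if L is None:
                break
            pos += 10 + L
        return make_transcript(exons)

    def test_flags_exactly_1_2_4_5(self):
        m = self.ladder([1, 2, 3, 4, 5, 6])
        out = classify_frameshift_introns(m)
        assert out.attributes["frameshift_introns"] == "1,2,4,5"

    def test_no_introns_no_attribute(self):
        out = classify_frameshift_introns(make_transcript([(1, 10)]))
        assert "frameshift_introns" not in out.attributes

    def test_3bp_intron_not_flagged(self):
        out = classify_frameshift_introns(self.ladder([3]))
        assert "frameshift_introns" not in out.attributes

    def test_idempotent(self):
        m = self.ladder([1, 7, 4])
        once = classify_frameshift_introns(m)
        twice = classify_frameshift_introns(once)
        assert once.attributes == twice.attributes


# ---------------------------------------------------------------------------
# Local affine alignment vs independent oracle
# ---------------------------------------------------------------------------

def oracle_local_affine(a, b, sub, gap_open, gap_extend):
    """Best local alignment score by exhaustive recursion over extensions.

    A gap of length L costs gap_open + (L-1)*gap_extend; the alignment may
    start and stop anywhere (score never below 0).
    """

    @lru_cache(maxsize=None)
    def g(i, j, last):
        best = 0.0
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + g(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if last == "D" else gap_open
            best = max(best, -cost + g(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend if last == "I" else gap_open
            best = max(best, -cost + g(i, j + 1, "I"))
        return best

    return max(
        g(i, j, "M") for i in range(len(a) + 1) for j in range(len(b) + 1)
    )


AA = "ACDEFGHIKLMNPQRSTVWY"


class TestScoreTranslationMatch:
    def test_identical_sequences_closed_form(self):
        scoring = AlignmentScoring(match=5, mismatch=-4, use_blosum=False)
        for n in (1, 4, 9):
            s = ("MKLV" * 3)[:n]
            assert score_translation_match(s, s, scoring) == 5 * n

    def test_disjoint_alphabets_score_zero(self):
        scoring = AlignmentScoring(match=5, mismatch=-4, use_blosum=False)
        assert score_translation_match("KKKK", "DDDD", scoring) == 0

    def test_non_amino_acid_symbols_fatal(self):
        with pytest.raises(ValueError):
            score_translation_match("MK1V", "MKLV")
        with pytest.raises(ValueError):
            score_translation_match("", "MKLV")

    @pytest.mark.parametrize("use_blosum", [False, True])
    def test_matches_bruteforce_oracle(self, use_blosum):
        rng = np.random.default_rng(23)
        scoring = AlignmentScoring(match=5, mismatch=-4, gap_open=12,
                                   gap_extend=2, use_blosum=use_blosum)
        if use_blosum:
            matrix = substitution_matrices.load("BLOSUM62")
            sub = lambda x, y: float(matrix[x, y])
        else:
            sub = lambda x, y: 5.0 if x == y else -4.0
        for _ in range(100):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(1, 13))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(1, 13))))
            got = score_translation_match(a, b, scoring)
            want = oracle_local_affine(a, b, sub, 12, 2)
            assert got == pytest.approx(want), (a, b)


class TestBestTargetedSelect:
    def build_pair(self):
        """Two candidates for one protein: full-length and 10-aa deletion."""
        codons = [SENSE_CODONS[i % 30] for i in range(40)]
        cds_full = "ATG" + "".join(codons) + "TAA"
        genome = {"chr1": "T" * 10 + cds_full + "T" * 10}
        full = make_transcript([(11, 10 + len(cds_full))],
                               cds=(11, 10 + len(cds_full)), tid="full")
        # candidate missing 10 internal codons (framed deletion)
        s, e = 11 + 33, 11 + 63 - 1  # 30 bp = 10 codons removed
        partial = make_transcript(
            [(11, s - 1), (e + 1, 10 + len(cds_full))],
            cds=(11, 10 + len(cds_full)), tid="part",
        )
        from genebuild.core import translate_cds

        protein = translate_cds(cds_full).rstrip("*")
        return genome, protein, full, partial

    def test_full_length_beats_deletion(self):
        genome, protein, full, partial = self.build_pair()
        best = best_targeted_select([partial, full], protein, genome)
        assert best.id == "full"
        # verified independently against the brute-force oracle
        matrix = substitution_matrices.load("BLOSUM62")
        sub = lambda x, y: float(matrix[x, y])
        sc = {
            m.id: oracle_local_affine(
                m.translation(genome).rstrip("*")[:12], protein[:12], sub, 12, 2
            )
            for m in (full, partial)
        }
        assert sc["full"] >= sc["part"]

    def test_single_candidate_selected(self):
        genome, protein, full, _ = self.build_pair()
        assert best_targeted_select([full], protein, genome) is full

    def test_exact_tie_breaks_deterministically(self):
        genome, protein, full, _ = self.build_pair()
        dup = full.copy()
        dup.id = "aaa_first"
        assert best_targeted_select([full, dup], protein, genome).id == "aaa_first"
        assert best_targeted_select([dup, full], protein, genome).id == "aaa_first"

    def test_selection_order_invariant(self):
        genome, protein, full, partial = self.build_pair()
        a = best_targeted_select([full, partial], protein, genome)
        b = best_targeted_select([partial, full], protein, genome)
        assert a.id == b.id


class TestCdna2Genome:
    def clean_mrna(self, n_codons=60, utr5=100, utr3=80):
        cds = "ATG" + "".join(SENSE_CODONS[i % 40] for i in range(n_codons)) + "TAA"
        return "C" * utr5 + cds + "C" * utr3, utr5, len(cds)

    def test_full_alignment_gives_5prime_utr(self):
        mrna, utr5, cds_len = self.clean_mrna()
        genome = {"chr1": "T" * 50 + mrna + "T" * 50}
        aln = EvidenceAlignment(
            query_id="cd1", query_type="cdna", region="chr1", strand="+",
            blocks=[(51, 50 + len(mrna), 1, len(mrna))],
            annotated_cds_on_query=(utr5 + 1, utr5 + cds_len),
        )
        (model,) = cdna2genome_models([aln], genome)
        assert model.cds_start - model.start == utr5
        assert model.translation(genome).startswith("M")

    def test_cds_split_across_intron_keeps_frame(self):
        mrna, utr5, cds_len = self.clean_mrna()
        # split the mRNA at a point inside the CDS; 100 bp intron between
        cut = utr5 + 50
        left, right = mrna[:cut], mrna[cut:]
        genome = {"chr1": "T" * 20 + left + "G" * 100 + right + "T" * 20}
        b1 = (21, 20 + cut, 1, cut)
        b2 = (21 + cut + 100, 20 + cut + 100 + len(right), cut + 1, len(mrna))
        aln = EvidenceAlignment(
            query_id="cd2", query_type="cdna", region="chr1", strand="+",
            blocks=[b1, b2],
            annotated_cds_on_query=(utr5 + 1, utr5 + cds_len),
        )
        (model,) = cdna2genome_models([aln], genome)
        assert len(model.exons) == 2
        assert len(model.coding_exons()) == 2
        aa = model.translation(genome)
        assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1]

    def test_missing_cds_start_rejected(self, caplog):
        mrna, utr5, cds_len = self.clean_mrna()
        genome = {"chr1": mrna}
        # alignment only covers the 3' half; CDS start unmapped
        start_q = utr5 + 200
        aln = EvidenceAlignment(
            query_id="cd3", query_type="cdna", region="chr1", strand="+",
            blocks=[(start_q, len(mrna), start_q, len(mrna))],
            annotated_cds_on_query=(utr5 + 1, utr5 + cds_len),
        )
        with caplog.at_level("WARNING", logger="genebuild"):
            assert cdna2genome_models([aln], genome) == []
        assert any("not covered" in r.message for r in caplog.records)


def test_models_from_locus_slides_to_splice_sites():
    """Block edges off by a few bp snap to the nearest GT..AG pair."""
    exon1, exon2 = "ATGAAACCC", "GGGTTTTAA"
    intron = "GT" + "A" * 50 + "AG"
    genome = {"chr1": "T" * 10 + exon1 + intron + exon2 + "T" * 10}
    # true exon1 = 11..19, intron 20..73, exon2 = 74..82
    h = EvidenceAlignment(
        query_id="p", query_type="protein", region="chr1", strand="+",
        blocks=[(11, 21, 1, 11), (76, 82, 12, 18)],  # edges off by 2 bp
    )
    locus = CandidateLocus("p", "chr1", "+", 11, 82, [h])
    (model,) = models_from_locus(locus, genome)
    assert model.introns() == [(20, 73)]
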