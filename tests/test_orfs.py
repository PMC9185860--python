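import random

import pytest

from circkit import oracle
from circkit.junctions import BacksplicedJunction
from circkit.models import GenomeSequence, build_transcript, revcomp, spliced_sequence
from circkit.orfs import (
    CdsProjection,
    CircOrf,
    CircularSequence,
    build_circle,
    classify_novelty,
    enumerate_orfs,
    map_orf_to_protein,
    project_cds,
)
from circkit.reference import rank_and_assign


def circle(seq):
    return CircularSequence(seq, [], "+")


def orf_view(o):
    return (o.start, o.length_nt, o.crossings, o.endless, o.peptide)


def oracle_view(o):
    return (o.start, o.length_nt, o.crossings, o.endless, o.peptide)


class TestEnumerate:
    def test_plain_linear_orf(self):
        (o,) = enumerate_orfs(circle("ATGAAATAA"))
        assert orf_view(o) == (0, 9, 0, False, "MK")
        assert o.orf_class == "0C"

    def test_single_crossing_orf(self):
        (o,) = enumerate_orfs(circle("TAAATGCCC"))
        assert orf_view(o) == (3, 9, 1, False, "MP")

    def test_double_crossing_orf(self):
        (o,) = enumerate_orfs(circle("ATGAAAAAAA"))
        assert orf_view(o) == (0, 24, 2, False, "MKKNEKK")
        assert o.orf_class == "2C"

    def test_endless_orf_reports_minimal_period(self):
        (o,) = enumerate_orfs(circle("ATGGCTGCT"))
        assert o.endless
        assert o.crossings is None
        assert o.orf_class == "edlsC"
        assert o.peptide == "MAA"

    def test_min_peptide_drops_finite_but_never_endless(self):
        assert enumerate_orfs(circle("ATGAAATAA"), min_peptide=3) == []
        assert len(enumerate_orfs(circle("ATGGCTGCT"), min_peptide=50)) == 1

    def test_too_short_circle_is_an_error(self):
        with pytest.raises(ValueError, match="< 3"):
            enumerate_orfs(circle("AT"))

    def test_oracle_equivalence_on_random_circles(self):
        rng = random.Random(1234)
        for _ in range(300):
            L = rng.randint(9, 300)
            seq = "".join(rng.choice("ACGT") for _ in range(L))
            eng = [orf_view(o) for o in enumerate_orfs(circle(seq))]
            orc = [oracle_view(o) for o in oracle.scan_circle(seq)]
            assert eng == orc

    @staticmethod
    def _preceding_stop(seq, start):
        """End of the governing in-frame stop before ``start`` (same linear
        reading), or None if the maximal-ORF context is truncated at 0."""
        last = None
        for p in range(start % 3, start, 3):
            if seq[p:p + 3] in ("TAA", "TAG", "TGA"):
                last = p + 3
        return last

    def test_rotation_covariance_of_junction_free_orfs(self):
        """Rotating the circle start preserves every 0-crossing ORF whose
        whole stop-delimited context window avoids both the old and the
        new junction position (maximal-ORF starts depend on the preceding
        in-frame stop, so the window, not just the ORF, must stay intact)."""
        rng = random.Random(99)
        checked = 0
        for _ in range(250):
            L = rng.randint(30, 120)
            seq = "".join(rng.choice("ACGT") for _ in range(L))
            orig = enumerate_orfs(circle(seq))
            for r in sorted({rng.randint(1, L - 1) for _ in range(6)}):
                rotated = seq[r:] + seq[:r]
                rot = {
                    (o.start, o.length_nt, o.peptide)
                    for o in enumerate_orfs(circle(rotated))
                }
                for o in orig:
                    if o.endless or o.crossings != 0:
                        continue
                    q = self._preceding_stop(seq, o.start)
                    if q is None:
                        continue  # context truncated at the unroll origin
                    if not (r <= q - 3 or r >= o.start + o.length_nt):
                        continue  # new junction inside the context window
                    assert (
                        (o.start - r) % L, o.length_nt, o.peptide
                    ) in rot
                    checked += 1
        assert checked > 50

    def test_every_orf_has_exactly_one_class(self):
        rng = random.Random(5)
        classes = {"0C", "1C5'", "1C3'", "2C", "edlsC"}
        for _ in range(50):
            L = rng.randint(9, 120)
            seq = "".join(rng.choice("ACGT") for _ in range(L))
            orfs = enumerate_orfs(circle(seq))
            assert all(o.orf_class in classes for o in orfs)
            per_class = {}
            for o in orfs:
                per_class[o.orf_class] = per_class.get(o.orf_class, 0) + 1
            assert sum(per_class.values()) == len(orfs)


def scenario_setup(seq, cds_cover=True):
    """A one-exon-pair world: circle == exons 1..2, CDS covers the circle."""
    L = len(seq)
    e1 = L // 2
    genome = GenomeSequence({"c": seq + "G" * 40})
    exons = [(0, e1), (e1, L)]
    cds = [(0, e1, 0), (e1, L, (3 - e1 % 3) % 3)] if cds_cover else None
    t = build_transcript("T", "g", "G", "+", "c", exons, cds)
    j = BacksplicedJunction("c", 0, L, "+")
    (a,) = rank_and_assign([j], [t])
    return a, [t], genome


class TestBuildCircle:
    def test_zero_offsets_equal_spliced_sequence(self, bundle):
        assignments = rank_and_assign(bundle["junctions"], bundle["models"])
        models_by_id = {t.transcript_id: t for t in bundle["models"]}
        for a in assignments:
            c = build_circle(a, bundle["models"], bundle["genome"])
            m, n = a.exon_pair
            expected = spliced_sequence(
                models_by_id[a.transcript_id], bundle["genome"], (m, n)
            )
            assert c.seq == expected
            assert c.L == sum(b.circ_end - b.circ_start for b in c.blocks)

    def test_positive_donor_offset_extends_three_prime_end(self):
        genome = GenomeSequence({"c": "ATGAAATAAGGTT"})
        t = build_transcript("T", "g", "G", "+", "c", [(0, 4), (5, 9)])
        j = BacksplicedJunction("c", 0, 11, "+")  # donor 2 nt into the intron
        (a,) = rank_and_assign([j], [t], tolerance=2)
        assert a.match.donor_offset == 2
        c = build_circle(a, [t], genome)
        assert c.seq == "ATGAATAAGG"  # exon1 + exon2 + 2 intronic nt

    def test_minus_strand_circle_hand_traced(self):
        # genome: exon1 [10,16)="GGGCAT", exon2 [0,4)="AAAT"; on '-' the
        # transcript reads revcomp("GGGCAT") + revcomp("AAAT") = ATGCCC ATTT
        genome = GenomeSequence({"c": "AAATCCCCCCGGGCAT"})
        t = build_transcript("T", "g", "G", "-", "c", [(10, 16), (0, 4)])
        j = BacksplicedJunction("c", 0, 16, "-")
        (a,) = rank_and_assign([j], [t])
        c = build_circle(a, [t], genome)
        assert c.seq == "ATGCCCATTT"
        assert c.seq == revcomp(genome.fetch("c", 10, 16))[:6] + revcomp(
            genome.fetch("c", 0, 4)
        )

    def test_offset_consuming_an_exon_is_an_error(self):
        genome = GenomeSequence({"c": "ATGAAATAAGGTT"})
        t = build_transcript("T", "g", "G", "+", "c", [(0, 4), (5, 9)])
        j = BacksplicedJunction("c", 0, 11, "+")
        (a,) = rank_and_assign([j], [t], tolerance=2)
        a.match = type(a.match)(a.match.transcript_id, 1, 2, 0, -5)
        with pytest.raises(ValueError, match="exon"):
            build_circle(a, [t], genome)

    def test_genomic_back_projection(self):
        genome = GenomeSequence({"c": "ATGAAATAAGGTT"})
        t = build_transcript("T", "g", "G", "+", "c", [(0, 4), (5, 9)])
        j = BacksplicedJunction("c", 0, 9, "+")
        (a,) = rank_and_assign([j], [t])
        c = build_circle(a, [t], genome)
        assert c.genomic_position(0) == ("c", 0)
        assert c.genomic_position(4) == ("c", 5)  # first base of exon 2


class TestProjectCds:
    def test_full_cover_single_phase_zero_interval(self):
        a, models, genome = scenario_setup("ATGAAATAAGGG")
        c = build_circle(a, models, genome)
        p = project_cds(a, c, models)
        assert p.present
        assert p.intervals == [(0, c.L, 0)]
        assert p.cds_pos == list(range(c.L))

    def test_noncoding_transcript_not_present(self):
        a, models, genome = scenario_setup("ATGAAATAAGGG", cds_cover=False)
        c = build_circle(a, models, genome)
        p = project_cds(a, c, models)
        assert not p.present
        assert all(v == -1 for v in p.cds_pos)

    def test_cds_starting_mid_exon_offsets_projection(self):
        # CDS begins 3 nt into exon 1 of a 12 nt circle
        seq = "GGGATGAAATAA"
        genome = GenomeSequence({"c": seq + "A" * 20})
        t = build_transcript(
            "T", "g", "G", "+", "c", [(0, 6), (6, 12)],
            cds_intervals=[(3, 6, 0), (6, 12, 0)],
        )
        j = BacksplicedJunction("c", 0, 12, "+")
        (a,) = rank_and_assign([j], [t])
        c = build_circle(a, [t], genome)
        p = project_cds(a, c, [t])
        assert p.intervals == [(3, 12, 0)]
        assert p.cds_pos[:4] == [-1, -1, -1, 0]


class TestClassifyNovelty:
    def test_zero_crossing_never_novel(self):
        o = CircOrf(0, 9, 0, "0C", "MK")
        out = classify_novelty(o, CdsProjection(False, cds_pos=[-1] * 12), 12)
        assert (out.novel_n, out.novel_c) == (False, False)

    def test_multi_crossing_novel_at_both_ends(self):
        o = CircOrf(0, 24, 2, "2C", "MKKNEKK")
        out = classify_novelty(o, CdsProjection(False, cds_pos=[-1] * 10), 10)
        assert out.orf_class == "2C"
        assert (out.novel_n, out.novel_c) == (True, True)

    def test_parental_five_prime_segment_gives_novel_c(self):
        # L=10: ORF starts at 0 in parental frame, crosses once, and the
        # post-junction codons are frame-shifted relative to the CDS.
        seq = "ATGAAAAACC"  # frame 0: ATG AAA AAC C|AT GAA ... find stop
        L = len(seq)
        cds = CdsProjection(True, [(0, L, 0)], list(range(L)))
        orfs = [o for o in enumerate_orfs(circle(seq)) if o.crossings == 1
                and o.start % 3 == 0 and (o.start - L) % 3 != 0]
        if orfs:
            out = classify_novelty(orfs[0], cds, L)
            assert out.orf_class == "1C3'"
            assert (out.novel_n, out.novel_c) == (False, True)

    def test_scenario_circles_have_designed_flags(self, bundle, annotated):
        truth = bundle["truth"]["junctions"]
        for key_s, entry in truth.items():
            if not entry.get("orf"):
                continue
            contig, span, strand = key_s.split(":")
            start, end = map(int, span.split("-"))
            orfs = annotated.orfs[(contig, start, end, strand)]
            assert len(orfs) == 1
            o = orfs[0]
            assert o.orf_class == entry["orf"]["class"]
            assert o.novel_n == entry["orf"]["novel_n"]
            assert o.novel_c == entry["orf"]["novel_c"]

    def test_frame_preserving_junction_qualifier(self):
        seq = "GGGTAAATGCCC"  # L=12; ORF start 6 reads through the junction
        L = len(seq)
        cds = CdsProjection(True, [(0, L, 0)], list(range(L)))
        o = next(o for o in enumerate_orfs(circle(seq)) if o.start == 6)
        assert o.crossings == 1
        out = classify_novelty(o, cds, L)
        assert out.qualifier == "frame-preserving"
        assert (out.novel_n, out.novel_c) == (False, False)

    def test_noncoding_host_qualifier(self):
        seq = "GGGTAAATGCCC"
        o = next(o for o in enumerate_orfs(circle(seq)) if o.start == 6)
        out = classify_novelty(
            o, CdsProjection(False, cds_pos=[-1] * len(seq)), len(seq)
        )
        assert out.qualifier == "no-parental-frame"
        assert (out.novel_n, out.novel_c) == (True, True)


class TestMapOrfToProtein:
    def test_fully_parental_orf(self):
        L = 9
        p = CdsProjection(True, [(0, L, 0)], list(range(L)))
        o = CircOrf(0, 9, 0, "0C", "MK")
        aln = map_orf_to_protein(o, p, L, 100)
        assert (aln.residue_start, aln.residue_end) == (1, 2)
        assert (aln.novel_n_aa, aln.novel_c_aa) == (0, 0)

    def test_novel_n_overhang_counted(self):
        # CDS covers circle positions 3..8 only: the first codon is novel.
        cds_pos = [-1, -1, -1, 0, 1, 2, 3, 4, 5]
        p = CdsProjection(True, [(3, 9, 0)], cds_pos)
        o = CircOrf(0, 9, 0, "0C", "MK")
        aln = map_orf_to_protein(o, p, 9, 100)
        assert (aln.residue_start, aln.residue_end) == (1, 1)
        assert (aln.novel_n_aa, aln.novel_c_aa) == (1, 0)

    def test_no_parental_codons_reports_full_overhangs(self):
        p = CdsProjection(True, [(0, 3, 1)], [1, 2, 3, -1, -1, -1, -1, -1, -1])
        o = CircOrf(0, 9, 0, "0C", "MK")
        aln = map_orf_to_protein(o, p, 9, 100)
        assert aln.residue_start is None
        assert (aln.novel_n_aa, aln.novel_c_aa) == (2, 2)

    def test_endless_orf_has_no_alignment(self):
        p = CdsProjection(True, [(0, 9, 0)], list(range(9)))
        with pytest.raises(ValueError, match="endless"):
            map_orf_to_protein(CircOrf(0, 0, None, "edlsC", "MAA"), p, 9, 10)


def test_endlessness_closed_form_on_frame_cycles():
    """For L % 3 == 0, a frame yields an endless ORF iff its codon cycle is
    stop-free and contains a start codon."""
    rng = random.Random(2024)
    checked = 0
    for _ in range(200):
        L = 3 * rng.randint(3, 40)
        seq = "".join(rng.choice("ACGT") for _ in range(L))
        endless_frames = {
            o.start % 3 for o in enumerate_orfs(circle(seq)) if o.endless
        }
        for f in range(3):
            expected = oracle.frame_is_stop_free(seq, f) and \
                oracle.frame_has_start(seq, f)
            assert (f in endless_frames) == expected
            checked += 1
    assert checked == 600
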