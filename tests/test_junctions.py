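import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.junctions import (
    COMPARTMENTS,
    BacksplicedJunction,
    compartment_venn,
    localization_profiles,
    merge_junctions,
    parse_archive,
    parse_bed,
    parse_ciri,
    reconcile,
    write_bed,
)

CIRI_HEADER = (
    "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
    "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\tcircRNA_type\t"
    "gene_id\tstrand\n"
)


def ciri_file(tmp_path, rows):
    p = tmp_path / "calls.tsv"
    p.write_text(CIRI_HEADER + "".join(rows))
    return p


def ciri_row(chrom="chrT", start=101, end=300, reads=5, strand="+"):
    return (
        f"{chrom}:{start}|{end}\t{chrom}\t{start}\t{end}\t{reads}\t"
        f"{reads},0,0\t10\t0.5\texon\tg\t{strand}\n"
    )


class TestParseCiri:
    def test_one_based_coordinates_converted(self, tmp_path):
        (j,) = parse_ciri(ciri_file(tmp_path, [ciri_row()]), "s", min_reads=2)
        assert j.key == ("chrT", 100, 300, "+")
        assert j.read_support == {"s": 5}

    def test_min_reads_filter(self, tmp_path):
        path = ciri_file(tmp_path, [ciri_row(reads=5)])
        assert parse_ciri(path, "s", min_reads=6) == []
        assert len(parse_ciri(path, "s", min_reads=5)) == 1

    def test_duplicate_rows_collapse_to_one_junction(self, tmp_path):
        path = ciri_file(tmp_path, [ciri_row(), ciri_row()])
        (j,) = parse_ciri(path, "s", min_reads=2)
        assert j.sources == {"s"}

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("circRNA_ID\tchr\tstrand\nx\tchrT\t+\n")
        with pytest.raises(ValueError, match="circRNA_start"):
            parse_ciri(p, "s")

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        path = ciri_file(tmp_path, [ciri_row(start="abc")])
        with pytest.raises(ValueError, match="row 2"):
            parse_ciri(path, "s")


class TestParseBed:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrT\t100\t300\tj1\t5\t+\n")
        (j,) = parse_bed(p, "s")
        assert j.key == ("chrT", 100, 300, "+")
        assert j.read_support == {"s": 5}

    def test_strandless_row_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrT\t100\t300\tj1\t5\t.\n")
        with pytest.raises(ValueError, match="strand required"):
            parse_bed(p, "s")

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert parse_bed(p, "s") == []

    def test_fewer_than_six_columns_is_an_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrT\t100\t300\n")
        with pytest.raises(ValueError, match="6 columns"):
            parse_bed(p, "s")


class TestParseArchive:
    def test_circbase_position_string(self, tmp_path):
        p = tmp_path / "cb.tsv"
        p.write_text(
            "circRNA_ID\tposition\tstrand\nhsa_circ_0000001\tchr1:101-300\t+\n"
        )
        (j,) = parse_archive(p, "circbase")
        assert j.key == ("chr1", 100, 300, "+")
        assert j.accessions == {"circbase": "hsa_circ_0000001"}

    def test_malformed_position_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "cb.tsv"
        p.write_text(
            "circRNA_ID\tposition\tstrand\n"
            "hsa_circ_0000001\tchr1:101\t+\n"
            "hsa_circ_0000002\tchr1:101-300\t+\n"
        )
        with caplog.at_level("WARNING"):
            out = parse_archive(p, "circbase")
        assert len(out) == 1
        assert any("skipped 1" in r.message for r in caplog.records)

    def test_zero_based_column_map_adopts_coordinates(self, tmp_path):
        p = tmp_path / "cdb.tsv"
        p.write_text(
            "circRNA_ID\tchrom\tstart\tend\tstrand\nc1\tchr1\t100\t300\t+\n"
        )
        (j,) = parse_archive(p, "circrnadb", column_map={"zero_based": True})
        assert (j.start, j.end) == (100, 300)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            parse_archive(tmp_path / "x.tsv", "mystery")


def J(contig, start, end, strand="+"):
    return BacksplicedJunction(contig, start, end, strand)


class TestReconcile:
    def test_two_set_example(self):
        j1, j2, j3 = J("c", 0, 10), J("c", 20, 30), J("c", 40, 50)
        v = reconcile({"A": [j1, j2], "B": [j2, j3]})
        assert v.count("A") == 1
        assert v.count("B") == 1
        assert v.count("A", "B") == 1
        assert v.union_size == 3

    def test_identical_sets_fill_only_full_intersection(self):
        js = [J("c", 0, 10), J("c", 20, 30)]
        v = reconcile({"A": js, "B": list(js)})
        assert v.count("A", "B") == 2
        assert v.count("A") == 0 and v.count("B") == 0

    def test_single_set_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            reconcile({"A": [J("c", 0, 10)]})

    def test_designed_three_set_partition_recovered(self, bundle):
        """The fixture's hand-bookkept 7-region Venn is reproduced."""
        truth = bundle["truth"]["venn_archives"]
        spec = bundle["spec"]
        junctions = {j.jid: j for j in spec.junctions}
        by_jid = dict(zip([j.jid for j in spec.junctions], bundle["junctions"]))
        sets = {
            "circbase": [by_jid[i] for i, jb in junctions.items()
                         if "circbase" in jb.archives],
            "circrnadb": [by_jid[i] for i, jb in junctions.items()
                          if "circrnadb" in jb.archives],
            "rnaseq": [by_jid[i] for i, jb in junctions.items()
                       if jb.in_rnaseq],
        }
        v = reconcile(sets)
        got = {"|".join(region): n for region, n in v.region_counts.items()}
        assert got == truth["regions"]
        assert v.union_size == bundle["truth"]["n_junctions"]

    def test_order_invariance(self):
        rng = random.Random(0)
        js = [J("c", 10 * i, 10 * i + 5) for i in range(12)]
        sets = {"A": js[:8], "B": js[4:], "C": js[::2]}
        v1 = reconcile(sets)
        for _ in range(5):
            labels = list(sets)
            rng.shuffle(labels)
            shuffled = {}
            for l in labels:
                items = list(sets[l])
                rng.shuffle(items)
                shuffled[l] = items
            v2 = reconcile(shuffled)
            assert sorted(v1.region_counts.values()) == sorted(
                v2.region_counts.values()
            )
            for region, n in v1.region_counts.items():
                assert v2.region_counts[tuple(
                    l for l in v2.set_labels if l in region
                )] == n


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 50), st.integers(1, 20), st.sampled_from("+-")),
        min_size=1, max_size=20,
    )
)
def test_bed_round_trip_idempotent(tmp_path_factory, raw):
    """Parsing, writing to BED and re-parsing yields identical keys."""
    tmp = tmp_path_factory.mktemp("bed")
    js = merge_junctions(
        [BacksplicedJunction("c", 100 * s, 100 * s + ln, strand)
         for s, ln, strand in raw]
    )
    path = tmp / "out.bed"
    write_bed(js.values(), path)
    reparsed = parse_bed(path, "x")
    assert {j.key for j in reparsed} == set(js)


class TestLocalization:
    def test_presence_profile(self):
        j1 = J("c", 0, 10)
        profiles = localization_profiles(
            {"cytoplasm": [j1], "polysome": [j1], "nucleoplasm": []}
        )
        (p,) = profiles
        assert p.present == {
            "cytoplasm": True, "polysome": True,
            "nucleoplasm": False, "chromatin": False,
        }

    def test_empty_compartment_allowed(self):
        assert localization_profiles({"chromatin": []}) == []

    def test_unknown_compartment_lists_vocabulary(self):
        with pytest.raises(ValueError, match="cytoplasm"):
            localization_profiles({"mitochondrion": []})

    def test_designed_compartment_overlap_recovered(self, bundle):
        spec = bundle["spec"]
        by_jid = dict(zip([j.jid for j in spec.junctions], bundle["junctions"]))
        calls = {
            c: [by_jid[jb.jid] for jb in spec.junctions
                if c in jb.compartments]
            for c in COMPARTMENTS
        }
        profiles = localization_profiles(calls)
        v = compartment_venn(profiles)
        got = {"|".join(r): n for r, n in v.region_counts.items()}
        assert got == bundle["truth"]["venn_compartments"]["regions"]
        assert v.union_size == len(profiles)


def test_merge_keeps_read_support_per_source():
    a = BacksplicedJunction("c", 0, 10, "+", {"s1"}, {"s1": 5})
    b = BacksplicedJunction("c", 0, 10, "+", {"s2"}, {"s2": 7})
    merged = merge_junctions([a], [b])
    (j,) = merged.values()
    assert j.sources == {"s1", "s2"}
    assert j.read_support == {"s1": 5, "s2": 7}
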