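"""Annotation compilation: parsing, location, aggregation, naming."""

import pytest

from mircurate.annotation import (
    aggregate_candidates,
    assign_uniform_names,
    load_fasta,
    locate_precursor,
    parse_annotation_source,
    source_region_counts,
    write_fasta,
    write_gff3,
)
from mircurate.core import GenomicInterval, MatureRecord, PrecursorRecord


def _write(path, text):
    path.write_text(text)
    return str(path)


GENOME = {
    "chr1": "A" * 100 + "GGGACGUACGUACGUAGGGCCAAAAGCAUGCAUGCAUGCA".replace("U", "T")
    + "TTTTGCATGCATGCATGCTTTTGGCCCTACGTACGTACGTCCC" + "A" * 100,
}


def test_parse_nested_matures(tmp_path):
    gff = _write(
        tmp_path / "a.gff3",
        "##gff-version 3\n"
        "chr1\tsrc\tmiRNA_primary_transcript\t101\t183\t.\t+\t.\tID=pre1\n"
        "chr1\tsrc\tmiRNA\t104\t124\t.\t+\t.\tID=pre1-5p\n"
        "chr1\tsrc\tmiRNA\t160\t180\t.\t+\t.\tID=pre1-3p\n",
    )
    recs = parse_annotation_source(gff, GENOME, source_tag="db1")
    assert len(recs) == 1
    rec = recs[0]
    assert rec.interval == GenomicInterval("chr1", 100, 183, "+")
    assert len(rec.matures) == 2
    assert {m.arm for m in rec.matures} == {"5p", "3p"}
    assert rec.matures[0].sequence == rec.sequence[3:24]
    assert "U" in rec.sequence and "T" not in rec.sequence


def test_orphan_mature_is_rejected_by_name(tmp_path):
    gff = _write(
        tmp_path / "b.gff3",
        "##gff-version 3\n"
        "chr1\tsrc\tmiRNA_primary_transcript\t101\t183\t.\t+\t.\tID=pre1\n"
        "chr1\tsrc\tmiRNA\t501\t521\t.\t+\t.\tID=lost-mature\n",
    )
    with pytest.raises(ValueError, match="lost-mature"):
        parse_annotation_source(gff, GENOME, source_tag="db1")


def test_minus_strand_sequence_is_transcribed_strand(tmp_path):
    genome = {"toy": "ACGTACGTAC"}
    gff = _write(
        tmp_path / "c.gff3",
        "##gff-version 3\n"
        "toy\tsrc\tmiRNA_primary_transcript\t1\t10\t.\t-\t.\tID=neg1\n",
    )
    (rec,) = parse_annotation_source(gff, genome, source_tag="db1")
    assert rec.sequence == "GUACGUACGU"  # revcomp of ACGTACGTAC, T->U


def test_missing_chromosome_errors(tmp_path):
    gff = _write(
        tmp_path / "d.gff3",
        "##gff-version 3\n"
        "chrZ\tsrc\tmiRNA_primary_transcript\t1\t50\t.\t+\t.\tID=x\n",
    )
    with pytest.raises(ValueError, match="chrZ"):
        parse_annotation_source(gff, GENOME, source_tag="db1")


class TestLocatePrecursor:
    genome = {
        "c1": "T" * 100 + "GATTACAGATTACAGATTACAGATTACAGATTACAGATTACA" + "T" * 60,
        "c2": "G" * 220,
    }
    query = "GAUUACAGAUUACAGAUUACAGAUUACAGAUUACAGAUUACA"

    def test_exact_planting(self):
        hits = locate_precursor(self.query, self.genome, max_mismatch=0)
        assert GenomicInterval("c1", 100, 142, "+") in hits

    def test_reverse_complement_hit(self):
        from mircurate.core import revcomp_rna

        rc = revcomp_rna(self.query)
        hits = locate_precursor(rc, self.genome, max_mismatch=0)
        assert any(h.strand == "-" and h.start == 100 for h in hits)

    def test_mismatch_threshold(self):
        mutated = "CCC" + self.query[3:]  # 3 substitutions vs planted site
        hits = [
            h
            for h in locate_precursor(mutated, self.genome, max_mismatch=2)
            if h.chrom == "c1"
        ]
        assert hits == []

    def test_contig_order_invariance(self):
        flipped = dict(reversed(list(self.genome.items())))
        assert locate_precursor(self.query, self.genome, 1) == locate_precursor(
            self.query, flipped, 1
        )


def _rec(rid, chrom, start, end, strand="+", seq=None, sources=("s",)):
    n = end - start
    return PrecursorRecord(
        id=rid,
        sequence=seq or "ACGU" * (n // 4) + "A" * (n % 4),
        sources=set(sources),
        interval=GenomicInterval(chrom, start, end, strand),
    )


class TestAggregate:
    def test_identical_locus_two_sources(self):
        a = _rec("x", "chr1", 100, 200, sources=("s1",))
        b = _rec("y", "chr1", 100, 200, sources=("s2",))
        recs, catalog = aggregate_candidates([("s1", [a]), ("s2", [b])])
        assert len(recs) == 1
        assert recs[0].sources == {"s1", "s2"}
        assert set(catalog) == {"s1", "s2"}

    def test_disjoint_loci_stay_separate(self):
        a = _rec("x", "chr1", 100, 200)
        b = _rec("y", "chr1", 400, 500)
        recs, _ = aggregate_candidates([("s1", [a]), ("s2", [b])])
        assert len(recs) == 2

    def test_opposite_strands_never_merge(self):
        a = _rec("x", "chr1", 100, 200, "+")
        b = _rec("y", "chr1", 100, 200, "-")
        recs, _ = aggregate_candidates([("s1", [a]), ("s2", [b])])
        assert len(recs) == 2

    def test_matures_deduplicated_on_merge(self):
        a = _rec("x", "chr1", 100, 200)
        a.add_mature(MatureRecord("m1", "unknown", 5, 21, a.sequence[5:26]))
        b = _rec("y", "chr1", 100, 200)
        b.add_mature(MatureRecord("m2", "unknown", 5, 21, b.sequence[5:26]))
        b.add_mature(MatureRecord("m3", "unknown", 60, 21, b.sequence[60:81]))
        (rec,), _ = aggregate_candidates([("s1", [a]), ("s2", [b])])
        assert len(rec.matures) == 2

    def test_idempotent(self):
        sets = [
            ("s1", [_rec("x", "chr1", 100, 200), _rec("u", "chr2", 10, 110)]),
            ("s2", [_rec("y", "chr1", 120, 210)]),
        ]
        recs1, _ = aggregate_candidates(sets)
        recs2, _ = aggregate_candidates([("agg", recs1)])
        assert [(r.id, r.interval, tuple(sorted(r.sources - {"agg"}))) for r in recs2] == [
            (r.id, r.interval, tuple(sorted(r.sources))) for r in recs1
        ]

    def test_order_independence(self):
        sets = [
            ("s1", [_rec("x", "chr1", 100, 200)]),
            ("s2", [_rec("y", "chr1", 150, 250), _rec("z", "chr3", 5, 105)]),
        ]
        recs_fwd, cat_fwd = aggregate_candidates(sets)
        recs_rev, cat_rev = aggregate_candidates(list(reversed(sets)))
        assert len(recs_fwd) == len(recs_rev)
        assert {r.id for r in recs_fwd} == {r.id for r in recs_rev}
        assert {s: set(v) for s, v in cat_fwd.items()} == {
            s: set(v) for s, v in cat_rev.items()
        }


class TestRegionCounts:
    def test_simple_overlap(self):
        counts = source_region_counts({"S1": {"x"}, "S2": {"x", "y"}})
        assert counts == {("S1", "S2"): 1, ("S2",): 1}

    def test_disjoint_singletons(self):
        catalog = {f"S{i}": {f"id{i}"} for i in range(4)}
        counts = source_region_counts(catalog)
        assert len(counts) == 4 and all(v == 1 for v in counts.values())

    def test_identical_sources_single_region(self):
        ids = {f"p{i}" for i in range(7)}
        counts = source_region_counts({f"S{i}": set(ids) for i in range(4)})
        assert counts == {("S0", "S1", "S2", "S3"): 7}

    def test_counts_sum_to_union(self):
        catalog = {"a": {"1", "2", "3"}, "b": {"2", "4"}, "c": {"4", "5", "1"}}
        counts = source_region_counts(catalog)
        assert sum(counts.values()) == len({"1", "2", "3", "4", "5"})


class TestUniformNames:
    def test_novel_locus_naming(self):
        recs = []
        for k in range(85):
            tag = "".join("ACGU"[(k >> (2 * i)) & 3] for i in range(4))
            r = _rec(f"cand{k}", "chr1", 1000 * k + 10, 1000 * k + 110,
                     seq=tag + "ACGU" * 24, sources=("predicted",))
            r.add_mature(MatureRecord(f"cand{k}-m", "unknown", 5, 21, r.sequence[5:26]))
            recs.append(r)
        assign_uniform_names(recs, "zma")
        assert recs[84].id == "zma-MIR_N85a"
        assert recs[84].matures[0].name == "zma-miR_N85a-5p"

    def test_sibling_loci_share_index_with_letters(self):
        seq = "ACGU" * 25
        a = _rec("h1", "chr1", 10, 110, seq=seq, sources=("predicted",))
        b = _rec("h2", "chr2", 10, 110, seq=seq, sources=("predicted",))
        assign_uniform_names([a, b], "ath")
        assert {a.id, b.id} == {"ath-MIR_N1a", "ath-MIR_N1b"}

    def test_database_name_preserved(self):
        r = _rec("ath-MIR156b", "chr1", 10, 110, sources=("mirbase",))
        assign_uniform_names([r], "ath")
        assert r.id == "ath-MIR156b"

    def test_duplicate_names_error(self):
        a = _rec("dup", "chr1", 10, 110, sources=("db",))
        b = _rec("dup", "chr2", 10, 110, sources=("db",))
        with pytest.raises(ValueError, match="duplicate"):
            assign_uniform_names([a, b], "ath")

    def test_bad_prefix_rejected(self):
        with pytest.raises(ValueError):
            assign_uniform_names([], "Zea")


def test_gff3_fasta_round_trip(tmp_path):
    genome = {"chr1": "ACGT" * 300}
    src = []
    for i, (s, e) in enumerate([(100, 200), (500, 620), (800, 900)]):
        r = PrecursorRecord(
            id=f"pre{i}",
            sequence=genome["chr1"][s:e].replace("T", "U"),
            sources={"db"},
            interval=GenomicInterval("chr1", s, e, "+"),
        )
        r.add_mature(MatureRecord(f"pre{i}-m", "unknown", 4, 21, r.sequence[4:25]))
        src.append(r)
    recs, _ = aggregate_candidates([("db", src)])
    gff = tmp_path / "out.gff3"
    write_gff3(recs, str(gff))
    write_fasta(recs, str(tmp_path / "out.fa"))
    reparsed = parse_annotation_source(str(gff), genome, source_tag="db")
    recs2, _ = aggregate_candidates([("db", reparsed)])
    assert [(r.id, r.interval, r.sequence) for r in recs2] == [
        (r.id, r.interval, r.sequence) for r in recs
    ]
    assert [[(m.offset, m.length) for m in r.matures] for r in recs2] == [
        [(m.offset, m.length) for m in r.matures] for r in recs
    ]
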