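"""Read parsing, cleaning rules, tag collapsing and category accounting."""

import collections

import pytest
from hypothesis import given, settings, strategies as st

from smallrna_crstress import sequence_io as sio
from smallrna_crstress import study_tables

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _lib(seqs, name="lib"):
    return sio.RawLibrary(name=name, reads=[sio.RawRead(s) for s in seqs])


class TestParseReads:
    def test_fastq_single_read(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGUACGUACGUACGUACGUA\n+\n" + "I" * 21 + "\n")
        lib = sio.parse_reads(p, "fastq")
        assert len(lib) == 1
        assert lib.reads[0].sequence == "ACGTACGTACGTACGTACGTA"  # U -> T
        assert len(lib.reads[0].sequence) == 21

    def test_collapsed_fasta_multiplicity(self, tmp_path):
        p = tmp_path / "c.fasta"
        p.write_text(">tag1_x257\nACGTACGTACGTACGTACGTA\n")
        lib = sio.parse_reads(p, "collapsed-fasta")
        assert len(lib) == 257
        assert len({r.sequence for r in lib.reads}) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fastq"
        p.write_text("")
        assert len(sio.parse_reads(p, "fastq")) == 0

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="unknown format"):
            sio.parse_reads(p, "bam")

    def test_bad_count_suffix_names_record(self, tmp_path):
        p = tmp_path / "c.fasta"
        p.write_text(">tag1_xNOPE\nACGT\n")
        with pytest.raises(ValueError, match="record 0"):
            sio.parse_reads(p, "collapsed-fasta")

    def test_collapsed_roundtrip(self, tmp_path):
        table = sio.TagTable()
        table.add("ACGTACGTACGTACGTACGTA", "CK", 257)
        table.add("TTGCACGTACGTACGTACG", "CK", 3)
        out = tmp_path / "rt.fasta"
        sio.write_collapsed_fasta(table, "CK", out)
        back = sio.collapse(sio.parse_reads(out, "collapsed-fasta"), "CK")
        assert back.tags == table.tags


class TestCleanReads:
    @pytest.mark.parametrize(
        "insert,expect_kept,reason",
        [
            ("ACGTTGCAGTCCAGTTACGAT", True, None),            # 21 nt with adapter
            ("ACGTTGCAGTCCAGTT", False, "too_short"),         # 16 nt <= 18
            ("ACGTTGCAGTCCAGTTAC", False, "too_short"),       # 18 nt: bound exclusive
            ("ACGTTGCAGTCCAGTTACG", True, None),              # 19 nt survives
            ("ACGTTGCAGTCCAGTTACGATACGTTGCAG", False, "too_long"),  # 30 nt
            ("AAAAAAAAAAAAAAAAAAAAA", False, "poly_a"),
        ],
    )
    def test_length_and_polya_rules(self, insert, expect_kept, reason):
        lib = _lib([insert + ADAPTER])
        cleaned, report = sio.clean_reads(lib, ADAPTER)
        if expect_kept:
            assert [r.sequence for r in cleaned.reads] == [insert]
        else:
            assert len(cleaned) == 0
            assert report.discarded[reason] == 1

    def test_adapter_null_and_insert_null(self):
        lib = _lib(["ACGTTGCAGTCCAGTTACGAT" + "C" * 21, ADAPTER + "ACGT"])
        cleaned, report = sio.clean_reads(lib, ADAPTER)
        assert len(cleaned) == 0
        assert report.discarded["adapter3_null"] == 1
        assert report.discarded["insert_null"] == 1

    def test_adapter5_contaminant(self):
        five = "GTTCAGAGTTCTACAGTCCGACGATC"
        lib = _lib([five + "ACGTTGCAG" + ADAPTER])
        cleaned, report = sio.clean_reads(lib, ADAPTER, adapter5=five)
        assert len(cleaned) == 0
        assert report.discarded["adapter5_contaminant"] == 1

    def test_one_adapter_mismatch_tolerated(self):
        mutated = "TGGTATTCTCGGGTGCCAAGG"  # one substitution
        lib = _lib(["ACGTTGCAGTCCAGTTACGAT" + mutated])
        cleaned, _ = sio.clean_reads(lib, ADAPTER)
        assert [r.sequence for r in cleaned.reads] == ["ACGTTGCAGTCCAGTTACGAT"]

    def test_recleaning_trimmed_reads_is_identity(self):
        lib = _lib([s + ADAPTER for s in ("ACGTTGCAGTCCAGTTACGAT", "TTGCACGTACGTACGTACG")])
        once, _ = sio.clean_reads(lib, ADAPTER)
        twice, report = sio.clean_reads(once, adapter3=None)
        assert [r.sequence for r in twice.reads] == [r.sequence for r in once.reads]
        assert report.kept == len(once)

    def test_conflicting_bounds_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            sio.clean_reads(_lib(["ACGT"]), ADAPTER, min_len=30, max_len=18)

    def test_zero_survivors_valid(self):
        cleaned, report = sio.clean_reads(_lib(["ACGTACGT"]), ADAPTER)
        assert len(cleaned) == 0 and report.kept == 0


class TestCollapse:
    def test_counting(self):
        t = sio.collapse(_lib(["ACGTACGTACGTACGTACGTA"] * 2 + ["TTGCACGTACGTACGTACG"]), "CK")
        assert t.count("ACGTACGTACGTACGTACGTA", "CK") == 2
        assert t.count("TTGCACGTACGTACGTACG", "CK") == 1

    def test_empty_library(self):
        assert len(sio.collapse(_lib([]), "CK")) == 0

    def test_merge_duplicate_label_rejected(self):
        a = sio.collapse(_lib(["ACGTACGT"]), "CK")
        with pytest.raises(ValueError, match="duplicate"):
            sio.merge_tables(a, sio.collapse(_lib(["ACGTACGT"]), "CK"))

    def test_merge_unions_labels(self):
        a = sio.collapse(_lib(["AAACCCGGGTTTAAACCCGGG"]), "CK")
        b = sio.collapse(_lib(["AAACCCGGGTTTAAACCCGGG"] * 3), "Cr200")
        m = sio.merge_tables(a, b)
        assert m.tags["AAACCCGGGTTTAAACCCGGG"] == {"CK": 1, "Cr200": 3}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=16, max_size=30), max_size=60))
    def test_conservation_property(self, seqs):
        """Sum of tag counts after collapse equals the read count."""
        t = sio.collapse(_lib(seqs), "CK")
        assert t.total("CK") == len(seqs)
        assert len(t) == len(set(seqs))


class TestLengthDistribution:
    def test_mode(self):
        lib = _lib(["A" * 10 + "CGTTGCAGTCC"] * 5 + ["ACGTTGCAGTCCAGTTACGATTTT"] * 3)
        t = sio.collapse(lib, "CK")
        hist, mode = sio.length_distribution(t, "CK")
        assert hist == {21: 5, 24: 3}
        assert mode == 21
        assert sum(hist.values()) == t.total("CK")

    def test_single_tag(self):
        t = sio.collapse(_lib(["ACGTTGCAGTCCAGTTACG"]), "CK")
        _, mode = sio.length_distribution(t, "CK")
        assert mode == 19

    def test_synthetic_library_mode_is_21(self, small_dataset):
        from smallrna_crstress.sequence_io import clean_reads, collapse

        lib = small_dataset.libraries["CK"]
        cleaned, _ = clean_reads(lib, small_dataset.spec.adapter3)
        _, mode = sio.length_distribution(collapse(cleaned, "CK"), "CK")
        assert mode == 21


class TestCategoryAccounting:
    def test_single_category(self):
        t = sio.collapse(_lib(["ACGTTGCAGTCCAGTTACGAT"] * 4), "CK")
        stats = sio.category_accounting(t, {"ACGTTGCAGTCCAGTTACGAT": "rRNA"}, "CK")
        assert stats.total_pct("rRNA") == 100.0
        assert stats.total_pct("miRNA") == 0.0

    def test_missing_assignment_is_internal_error(self):
        t = sio.collapse(_lib(["ACGTTGCAGTCCAGTTACGAT"]), "CK")
        with pytest.raises(RuntimeError, match="no category"):
            sio.category_accounting(t, {}, "CK")

    def test_printed_category_percentages(self):
        """Recompute the published per-category shares from raw counts."""
        df = study_tables.category_table()
        for lib, n_total in (("CK", study_tables.N_CK), ("Cr200", study_tables.N_CR200)):
            sub = df[(df.library == lib) & (df.category != "total")]
            assert int(sub.total.sum()) == n_total
            pct = {
                r.category: round(100.0 * r.total / n_total, 2) for r in sub.itertuples()
            }
            if lib == "CK":
                assert pct["miRNA"] == 9.27
                assert pct["unannotated"] == 82.36
            else:
                assert pct["miRNA"] == 10.53
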