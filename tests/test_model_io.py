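"""Data model invariants and file-format round trips."""

from __future__ import annotations

import numpy as np
import pytest

from lncforge import io as io_mod
from lncforge.model import (
    CodingScoreTable,
    GenomicInterval,
    HomologyHit,
    TranscriptModel,
    ValidationError,
    exonic_overlap_nt,
    reverse_complement,
)

from conftest import make_transcript


class TestModelInvariants:
    def test_interval_rejects_inverted_coordinates(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 5)

    def test_transcript_length_invariant_under_exon_input_order(self):
        fwd = make_transcript("t", exons=[(0, 100), (200, 350)])
        rev = make_transcript("t", exons=[(200, 350), (0, 100)])
        assert fwd.length == rev.length == 250
        assert [e.start for e in rev.exons] == [0, 200]

    def test_transcript_rejects_mixed_chroms_and_overlaps(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t",
                [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 20, 30)],
            )
        with pytest.raises(ValidationError):
            make_transcript("t", exons=[(0, 100), (50, 150)])

    def test_sequence_length_must_match_exonic_length(self):
        with pytest.raises(ValidationError):
            make_transcript("t", exons=[(0, 10)], sequence="ACGT")

    def test_exonic_overlap_counts_shared_exon_bases_only(self):
        a = make_transcript("a", exons=[(0, 100), (200, 300)])
        b = make_transcript("b", exons=[(50, 250)])
        # [50,100) + [200,250)
        assert exonic_overlap_nt(a, b) == 100

    def test_duplicate_score_entries_rejected(self):
        with pytest.raises(ValidationError):
            CodingScoreTable([("t1", 0.5), ("t1", -0.5)])


class TestGtf:
    def test_one_based_inclusive_converted_to_half_open(self, tmp_path):
        gtf = tmp_path / "in.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (t,) = io_mod.read_gtf(gtf)
        assert [(e.start, e.end) for e in t.exons] == [(99, 200), (300, 400)]
        assert t.length == 201
        assert t.strand == "+"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert io_mod.read_gtf(p) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(io_mod.ParseError, match=":1"):
            io_mod.read_gtf(p)

    def test_write_emits_one_based_and_dot_for_unknown_strand(self, tmp_path):
        t = make_transcript("t1", exons=[(0, 200)], strand=".")
        out = tmp_path / "out.gtf"
        io_mod.write_gtf([t], out)
        line = out.read_text().strip()
        fields = line.split("\t")
        assert fields[3] == "1" and fields[4] == "200"
        assert fields[6] == "."

    def test_round_trip_identity_on_randomized_transcripts(self, tmp_path, rng):
        transcripts = []
        for i in range(100):
            chrom = f"chr{rng.integers(1, 4)}"
            strand = ["+", "-", "."][int(rng.integers(0, 3))]
            n_ex = int(rng.integers(1, 5))
            pos = int(rng.integers(0, 10_000))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(50, 500))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(30, 400))
            transcripts.append(
                make_transcript(f"t{i:03d}", chrom=chrom, exons=exons, strand=strand)
            )
        path = tmp_path / "rt.gtf"
        io_mod.write_gtf(transcripts, path)
        back = {t.id: t for t in io_mod.read_gtf(path)}
        assert set(back) == {t.id for t in transcripts}
        for t in transcripts:
            b = back[t.id]
            assert b.exons == t.exons
            assert b.strand == t.strand

    def test_gene_grouping_by_gene_id(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\ts\texon\t200\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
            'chr1\ts\texon\t1000\t1100\t.\t-\t.\tgene_id "g2"; transcript_id "t3";\n'
        )
        genes = {g.id: g for g in io_mod.read_gene_models(gtf)}
        assert set(genes) == {"g1", "g2"}
        assert len(genes["g1"].transcripts) == 2
        assert genes["g1"].span.start == 0 and genes["g1"].span.end == 300


class TestFasta:
    def test_round_trip_and_uppercasing(self, tmp_path, rng):
        records = {
            f"seq{i}": "".join(
                np.array(list("acgtACGT"))[rng.integers(0, 8, int(rng.integers(10, 200)))]
            )
            for i in range(50)
        }
        path = tmp_path / "x.fa"
        io_mod.write_fasta(records, path)
        back = io_mod.read_fasta(path)
        assert back == {k: v.upper() for k, v in records.items()}

    def test_lowercase_input_uppercased(self, tmp_path):
        p = tmp_path / "lc.fa"
        p.write_text(">s\nacgt\n")
        assert io_mod.read_fasta(p) == {"s": "ACGT"}

    def test_duplicate_ids_rejected_with_names(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ValidationError, match="a"):
            io_mod.read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text(">a\n\n>b\nACGT\n")
        with pytest.raises(ValidationError):
            io_mod.read_fasta(p)


class TestSplicedSequence:
    def test_plus_strand_single_exon(self):
        t = make_transcript("t", exons=[(0, 4)], strand="+")
        assert io_mod.spliced_sequence(t, {"chr1": "ACGTAA"}) == "ACGT"

    def test_minus_strand_reverse_complements(self):
        t = make_transcript("t", exons=[(0, 3)], strand="-")
        assert io_mod.spliced_sequence(t, {"chr1": "AACGGG"}) == "GTT"

    def test_multi_exon_concatenates_in_genomic_order(self):
        genome = {"chr1": "AAACCCGGGTTT"}
        t = make_transcript("t", exons=[(0, 3), (9, 12)], strand="+")
        assert io_mod.spliced_sequence(t, genome) == "AAATTT"
        tm = make_transcript("t", exons=[(0, 3), (9, 12)], strand="-")
        assert io_mod.spliced_sequence(tm, genome) == reverse_complement("AAATTT")

    def test_exon_beyond_chrom_bounds_errors(self):
        t = make_transcript("t", exons=[(0, 10)])
        with pytest.raises(ValidationError):
            io_mod.spliced_sequence(t, {"chr1": "ACGT"})


class TestHitTable:
    LINE = "q1\ts1\t98.50\t120\t2\t0\t1\t120\t5\t124\t1e-05\t222.0"

    def test_scientific_notation_evalue_parsed(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE + "\n")
        (hit,) = io_mod.read_hit_table(p)
        assert hit.evalue == pytest.approx(1e-5)
        assert hit.query_id == "q1" and hit.percent_identity == 98.5

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "none.tsv"
        p.write_text("")
        assert io_mod.read_hit_table(p) == []

    def test_wrong_column_count_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(io_mod.ParseError):
            io_mod.read_hit_table(p)

    def test_round_trip_on_random_hits(self, tmp_path, rng):
        hits = [
            HomologyHit(
                query_id=f"q{i}",
                subject_id=f"s{i % 7}",
                percent_identity=float(np.round(rng.uniform(50, 100), 2)),
                alignment_length=int(rng.integers(30, 500)),
                mismatches=int(rng.integers(0, 30)),
                gap_opens=int(rng.integers(0, 5)),
                query_start=1,
                query_end=int(rng.integers(30, 500)),
                subject_start=1,
                subject_end=int(rng.integers(30, 500)),
                evalue=float(10.0 ** -rng.uniform(0, 50)),
                bit_score=float(np.round(rng.uniform(40, 900), 1)),
            )
            for i in range(1000)
        ]
        p = tmp_path / "rt.tsv"
        io_mod.write_hit_table(hits, p)
        back = io_mod.read_hit_table(p)
        assert len(back) == 1000
        for h, b in zip(hits, back):
            assert b.query_id == h.query_id and b.subject_id == h.subject_id
            assert b.evalue == pytest.approx(h.evalue, rel=0.01)
            assert b.alignment_length == h.alignment_length
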