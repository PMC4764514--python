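"""Filtration cascade: boundary strictness, stage conservation, planted
recovery and regime dominance."""

from __future__ import annotations

import numpy as np
import pytest

from lncforge.filters import (
    CascadeInputs,
    FilterConfig,
    StageReport,
    annotate_known_lncrnas,
    filter_by_coding_score,
    filter_by_homology,
    filter_min_length,
    filter_orf,
    run_cascade,
)
from lncforge.model import CodingScoreTable, HomologyHit
from lncforge.orf import find_longest_orf
from lncforge.synthetic import _coding_mrna

from conftest import make_transcript


def _hit(query: str, evalue: float, subject: str = "db|x") -> HomologyHit:
    return HomologyHit(query, subject, 90.0, 100, 5, 0, 1, 100, 1, 100, evalue, 180.0)


def _orf_transcript(tid: str, length: int, aa: int, seed: int = 0):
    """Transcript whose longest ORF is exactly *aa* amino acids."""
    rng = np.random.default_rng(seed)
    seq = _coding_mrna(rng, length, aa)
    res = find_longest_orf(seq, frames=3)
    assert res.aa_length == aa, "fixture construction failed"
    return make_transcript(tid, exons=[(0, length)], strand="+", sequence=seq)


class TestMinLength:
    def test_shorter_than_cutoff_is_strictly_removed(self):
        short = make_transcript("short", exons=[(0, 199)])
        exact = make_transcript("exact", exons=[(0, 200)])
        kept, removed = filter_min_length([short, exact], 200)
        assert [t.id for t in kept] == ["exact"]
        assert [t.id for t in removed] == ["short"]

    def test_empty_input(self):
        assert filter_min_length([], 200) == ([], [])


class TestOrfFilter:
    def test_traditional_boundary_at_100_aa_is_strict(self):
        at = _orf_transcript("at100", 600, 100)
        over = _orf_transcript("over", 600, 101)
        kept, removed = filter_orf([at, over], FilterConfig.traditional())
        assert [t.id for t in kept] == ["at100"]
        assert [t.id for t in removed] == ["over"]

    def test_stringent_boundary_at_83_aa(self):
        # fraction stays below 0.35 for both so only the aa rule decides
        at = _orf_transcript("at83", 800, 83)
        over = _orf_transcript("over", 800, 84)
        trad_kept, _ = filter_orf([at, over], FilterConfig.traditional())
        assert {t.id for t in trad_kept} == {"at83", "over"}
        kept, removed = filter_orf([at, over], FilterConfig.stringent())
        assert [t.id for t in kept] == ["at83"]
        assert [t.id for t in removed] == ["over"]

    def test_fraction_rule_is_strict_at_035(self):
        # 34 aa -> 105 nt footprint; length 300 puts the fraction at exactly 0.35
        exact = _orf_transcript("exact", 300, 34)
        over = _orf_transcript("over", 297, 34)  # 105/297 > 0.35
        assert find_longest_orf(exact.sequence).fraction == pytest.approx(0.35)
        kept, removed = filter_orf([exact, over], FilterConfig.stringent())
        assert [t.id for t in kept] == ["exact"]
        assert [t.id for t in removed] == ["over"]

    def test_short_orf_with_high_coverage_removed_only_by_stringency(self):
        t = _orf_transcript("t", 380, 50)  # 153/380 = 0.40 coverage
        kept, _ = filter_orf([t], FilterConfig.traditional())
        assert kept, "traditional regime has no coverage rule"
        kept, removed = filter_orf([t], FilterConfig.stringent())
        assert not kept and removed

    def test_missing_sequence_names_transcript(self):
        t = make_transcript("noseq", exons=[(0, 300)])
        with pytest.raises(ValueError, match="noseq"):
            filter_orf([t], FilterConfig.traditional())


class TestHomologyFilter:
    def test_evalue_cutoff_is_inclusive(self):
        ts = [make_transcript(t, exons=[(0, 300)]) for t in ("a", "b", "c")]
        hits = [_hit("a", 1e-5), _hit("b", 1e-4), _hit("c", 1e-3)]
        kept, removed = filter_by_homology(ts, hits, 1e-4)
        assert {t.id for t in removed} == {"a", "b"}
        assert {t.id for t in kept} == {"c"}

    def test_unknown_query_ids_ignored(self):
        ts = [make_transcript("a", exons=[(0, 300)])]
        kept, removed = filter_by_homology(ts, [_hit("ghost", 1e-20)], 1e-4)
        assert kept and not removed


class TestCodingScoreFilter:
    @pytest.mark.parametrize(
        "score,cutoff,kept",
        [
            (-0.3, -0.5, False),
            (-0.7, -0.5, True),
            (-0.7, -1.0, False),
            (-1.2, -0.5, True),
            (-1.2, -1.0, True),
            (-0.5, -0.5, False),  # boundary: strictly below required
        ],
    )
    def test_kept_iff_strictly_below_cutoff(self, score, cutoff, kept):
        t = make_transcript("t", exons=[(0, 300)])
        table = CodingScoreTable({"t": score})
        k, r = filter_by_coding_score([t], table, cutoff)
        assert bool(k) == kept and bool(r) == (not kept)

    def test_missing_score_is_kept_conservatively(self):
        t = make_transcript("t", exons=[(0, 300)])
        k, r = filter_by_coding_score([t], CodingScoreTable(), -0.5)
        assert k and not r


class TestKnownLncrnaAnnotation:
    def test_flags_without_removing(self):
        ts = [make_transcript(t, exons=[(0, 300)]) for t in ("a", "b")]
        flags = annotate_known_lncrnas(ts, [_hit("a", 1e-6, "lncdb|k1")], 1e-4)
        assert flags == {"a": {"lncdb|k1"}}

    def test_flag_count_matches_distinct_queries_after_cutoff(self, rng):
        ts = [make_transcript(f"t{i}", exons=[(0, 300)]) for i in range(50)]
        hits = []
        expected = set()
        for i in range(50):
            ev = float(10.0 ** -rng.uniform(0, 10))
            hits.append(_hit(f"t{i}", ev, "lncdb|x"))
            if ev <= 1e-4:
                expected.add(f"t{i}")
        flags = annotate_known_lncrnas(ts, hits, 1e-4)
        assert set(flags) == expected


class TestStageReport:
    def test_conservation_enforced_per_stage_and_chained(self):
        rep = StageReport()
        rep.add("a", 100, 30)
        rep.add("b", 70, 70)
        rep.validate()
        assert rep.n_input == 100 and rep.n_output == 0
        assert rep.total_removed == 100
        with pytest.raises(ValueError):
            rep.add("c", 5, 0)  # n_in must chain from previous n_out


class TestCascade:
    def test_planted_recovery_per_dataset(self, tiny_data):
        truth = tiny_data.truth
        for ds, transcripts in tiny_data.datasets.items():
            kept, report = run_cascade(
                transcripts, tiny_data.cascade_inputs, FilterConfig.traditional()
            )
            expected = {
                f"{tid}|{ds}"
                for tid, rec in truth.records.items()
                if rec.role == "lncrna" and ds in rec.datasets
            }
            assert {t.id for t in kept} == expected
            assert report.n_input == len(transcripts)
            report.validate()

    def test_output_is_a_pure_function_of_the_input_set(self, tiny_data, rng):
        ds = sorted(tiny_data.datasets)[0]
        transcripts = list(tiny_data.datasets[ds])
        kept1, _ = run_cascade(transcripts, tiny_data.cascade_inputs)
        shuffled = list(transcripts)
        rng.shuffle(shuffled)
        kept2, _ = run_cascade(shuffled, tiny_data.cascade_inputs)
        assert [t.id for t in kept1] == [t.id for t in kept2]

    def test_stringent_output_subset_of_traditional(self, tiny_data):
        for ds, transcripts in tiny_data.datasets.items():
            trad, _ = run_cascade(
                transcripts, tiny_data.cascade_inputs, FilterConfig.traditional()
            )
            strict, _ = run_cascade(
                transcripts, tiny_data.cascade_inputs, FilterConfig.stringent()
            )
            assert {t.id for t in strict} <= {t.id for t in trad}

    def test_all_pass_input_reports_zero_removed(self):
        ts = [
            make_transcript(f"t{i}", exons=[(0, 400)], sequence="C" * 400)
            for i in range(5)
        ]
        kept, report = run_cascade(ts, CascadeInputs())
        assert len(kept) == 5
        assert all(row.n_removed == 0 for row in report.rows)
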