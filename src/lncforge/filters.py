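"""The filtration cascade that reduces assembled transcripts to putative
long non-coding RNAs, with per-stage count reporting.

Stage order: minimum length -> ORF size -> protein-database homology ->
coding-potential score -> small-ncRNA homology.  Two stringency regimes
are shipped: *traditional* (length >= 200 nt, ORF <= 100 aa, E <= 1e-4,
score < -0.5) and *stringent* (ORF <= 83 aa and <= 35% of the transcript,
score < -1.0).  Comparison strictness at every boundary is part of the
contract and unit-tested:

=====================  ==========  =========================
threshold              comparison  outcome at the boundary
=====================  ==========  =========================
length 200 nt          ``<`` 200   removed; exactly 200 kept
ORF 100 / 83 aa        ``>`` max   removed; exactly max kept
ORF fraction 0.35      ``>`` 0.35  removed; exactly 0.35 kept
homology E 1e-4        ``<=``      removed at exactly 1e-4
coding score -0.5/-1   ``<`` cut   kept only strictly below
=====================  ==========  =========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .model import UNKNOWN, CodingScoreTable, HomologyHit, TranscriptModel
from .orf import OrfResult, find_longest_orf

logger = logging.getLogger(__name__)

STAGE_MIN_LENGTH = "min_length"
STAGE_ORF = "orf"
STAGE_PROTEIN_HOMOLOGY = "protein_homology"
STAGE_CODING_SCORE = "coding_score"
STAGE_SMALL_NCRNA = "small_ncrna_homology"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one stringency regime."""

    min_length_nt: int = 200
    max_orf_aa: int = 100
    max_orf_fraction: float | None = None
    homology_evalue: float = 1e-4
    coding_score_cutoff: float = -0.5
    orf_frames: int | None = None  # None: 3 when strand known, 6 when unknown

    @classmethod
    def traditional(cls) -> "FilterConfig":
        return cls()

    @classmethod
    def stringent(cls) -> "FilterConfig":
        return cls(max_orf_aa=83, max_orf_fraction=0.35, coding_score_cutoff=-1.0)


@dataclass(frozen=True)
class StageRow:
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class StageReport:
    """Ordered per-stage counts; conservation (n_in = n_removed + n_out,
    chained across stages) is an enforced invariant."""

    rows: list[StageRow] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_removed: int) -> None:
        row = StageRow(stage, n_in, n_removed, n_in - n_removed)
        if self.rows and self.rows[-1].n_out != n_in:
            raise ValueError(
                f"stage {stage}: n_in {n_in} != previous n_out {self.rows[-1].n_out}"
            )
        self.rows.append(row)

    def validate(self) -> None:
        for row in self.rows:
            if row.n_in - row.n_removed != row.n_out:
                raise ValueError(f"conservation violated at stage {row.stage}")
        for a, b in zip(self.rows, self.rows[1:]):
            if a.n_out != b.n_in:
                raise ValueError(f"stage chaining broken at {b.stage}")

    @property
    def n_input(self) -> int:
        return self.rows[0].n_in if self.rows else 0

    @property
    def n_output(self) -> int:
        return self.rows[-1].n_out if self.rows else 0

    @property
    def total_removed(self) -> int:
        return sum(r.n_removed for r in self.rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_removed\tn_out\n")
            for r in self.rows:
                fh.write(f"{r.stage}\t{r.n_in}\t{r.n_removed}\t{r.n_out}\n")

    def to_dict(self) -> list[dict]:
        return [
            {"stage": r.stage, "n_in": r.n_in, "n_removed": r.n_removed, "n_out": r.n_out}
            for r in self.rows
        ]


def transcript_orf(t: TranscriptModel, config: FilterConfig) -> OrfResult:
    """ORF of a transcript: 3 forward frames when the strand is known,
    all 6 when unknown (the mRNA could lie on either strand)."""
    if t.sequence is None:
        raise ValueError(f"transcript {t.id} has no sequence; cannot scan ORFs")
    frames = config.orf_frames
    if frames is None:
        frames = 3 if t.strand != UNKNOWN else 6
    return find_longest_orf(t.sequence, frames=frames)


def filter_min_length(
    transcripts: Sequence[TranscriptModel], min_length_nt: int = 200
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts strictly shorter than *min_length_nt*."""
    kept = [t for t in transcripts if t.length >= min_length_nt]
    removed = [t for t in transcripts if t.length < min_length_nt]
    return kept, removed


def filter_orf(
    transcripts: Sequence[TranscriptModel], config: FilterConfig
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts whose longest complete ORF exceeds the aa cutoff,
    or (when configured) covers more than the fractional cutoff."""
    kept, removed = [], []
    for t in transcripts:
        orf = transcript_orf(t, config)
        too_long = orf.aa_length > config.max_orf_aa
        too_covering = (
            config.max_orf_fraction is not None
            and orf.fraction > config.max_orf_fraction
        )
        (removed if too_long or too_covering else kept).append(t)
    return kept, removed


def _hit_queries(hits: Iterable[HomologyHit], evalue_cutoff: float) -> set[str]:
    return {h.query_id for h in hits if h.evalue <= evalue_cutoff}


def filter_by_homology(
    transcripts: Sequence[TranscriptModel],
    hits: Iterable[HomologyHit],
    evalue_cutoff: float = 1e-4,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove any transcript with a hit at E <= cutoff (inclusive)."""
    hits = list(hits)
    flagged = _hit_queries(hits, evalue_cutoff)
    known = {t.id for t in transcripts}
    unknown = {h.query_id for h in hits} - known
    if unknown:
        logger.warning(
            "%d hit-table query ids not among the %d transcripts; ignored",
            len(unknown),
            len(known),
        )
    kept = [t for t in transcripts if t.id not in flagged]
    removed = [t for t in transcripts if t.id in flagged]
    return kept, removed


def filter_by_coding_score(
    transcripts: Sequence[TranscriptModel],
    score_table: CodingScoreTable,
    cutoff: float = -0.5,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep transcripts scoring strictly below *cutoff* (non-coding
    leaning); transcripts absent from the table are kept and counted."""
    kept, removed, missing = [], [], 0
    for t in transcripts:
        score = score_table.get(t.id)
        if score is None:
            missing += 1
            kept.append(t)
        elif score < cutoff:
            kept.append(t)
        else:
            removed.append(t)
    if missing:
        logger.warning(
            "%d transcripts had no coding score; kept conservatively", missing
        )
    return kept, removed


def annotate_known_lncrnas(
    transcripts: Sequence[TranscriptModel],
    lncrna_hits: Iterable[HomologyHit],
    evalue_cutoff: float = 1e-4,
) -> dict[str, set[str]]:
    """Flag transcripts with significant similarity to previously
    characterized lncRNAs.  Annotation only — nothing is removed."""
    subjects: dict[str, set[str]] = {}
    for h in lncrna_hits:
        if h.evalue <= evalue_cutoff:
            subjects.setdefault(h.query_id, set()).add(h.subject_id)
    present = {t.id for t in transcripts}
    return {tid: subs for tid, subs in subjects.items() if tid in present}


@dataclass
class CascadeInputs:
    """Evidence tables the cascade consumes (precomputed search outputs)."""

    protein_hits: list[HomologyHit] = field(default_factory=list)
    ncrna_hits: list[HomologyHit] = field(default_factory=list)
    scores: CodingScoreTable = field(default_factory=CodingScoreTable)
    lncrna_db_hits: list[HomologyHit] = field(default_factory=list)


def run_cascade(
    transcripts: Sequence[TranscriptModel],
    inputs: CascadeInputs,
    config: FilterConfig | None = None,
) -> tuple[list[TranscriptModel], StageReport]:
    """Apply the full filtration cascade and report per-stage counts.

    The output is a pure function of the input *set*: transcripts are
    ordered canonically before filtering so input order never matters.
    """
    if config is None:
        config = FilterConfig.traditional()
    current = sorted(transcripts, key=lambda t: t.id)
    report = StageReport()

    current, removed = filter_min_length(current, config.min_length_nt)
    report.add(STAGE_MIN_LENGTH, len(removed) + len(current), len(removed))

    current, removed = filter_orf(current, config)
    report.add(STAGE_ORF, len(removed) + len(current), len(removed))

    current, removed = filter_by_homology(
        current, inputs.protein_hits, config.homology_evalue
    )
    report.add(STAGE_PROTEIN_HOMOLOGY, len(removed) + len(current), len(removed))

    current, removed = filter_by_coding_score(
        current, inputs.scores, config.coding_score_cutoff
    )
    report.add(STAGE_CODING_SCORE, len(removed) + len(current), len(removed))

    current, removed = filter_by_homology(
        current, inputs.ncrna_hits, config.homology_evalue
    )
    report.add(STAGE_SMALL_NCRNA, len(removed) + len(current), len(removed))

    report.validate()
    return current, report
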