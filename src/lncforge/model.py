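"""Core genomic data model.

Coordinates are 0-based, half-open throughout the library; file formats
that use other conventions (GTF: 1-based inclusive) convert at the I/O
boundary.  Strand is one of ``"+"``, ``"-"`` or ``"."`` (unknown);
unknown-strand transcripts are first-class citizens because three of the
four source datasets the pipeline was designed around carry no strand
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

PLUS = "+"
MINUS = "-"
UNKNOWN = "."
STRANDS = (PLUS, MINUS, UNKNOWN)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Shared nucleotides with *other*; 0 when on different chroms."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A (possibly multi-exon) transcript anchored on the genome.

    ``sequence``, when present, is the spliced sequence read 5'->3' for
    stranded transcripts, or in genomic (plus) orientation when the strand
    is unknown.
    """

    id: str
    exons: list[GenomicInterval]
    source_dataset: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        if not self.exons:
            raise ValidationError(f"transcript {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.id} has exons on multiple chroms: {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise ValidationError(f"transcript {self.id} mixes exon strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"transcript {self.id}: sequence length {len(self.sequence)} "
                f"!= exonic length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def with_strand(self, strand: str) -> "TranscriptModel":
        """Copy with the strand replaced (used by strand rescue).

        A stored sequence is kept in 5'->3' orientation: assigning minus
        to a previously unknown-strand transcript reverse-complements it.
        """
        if strand not in STRANDS:
            raise ValidationError(f"invalid strand {strand!r}")
        seq = self.sequence
        if seq is not None and self.strand == UNKNOWN and strand == MINUS:
            seq = reverse_complement(seq)
        exons = [replace(e, strand=strand) for e in self.exons]
        return TranscriptModel(self.id, exons, self.source_dataset, seq)


def exonic_overlap_nt(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total exon-level overlap between two transcripts in nt."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        ea, eb = a.exons[i], b.exons[j]
        total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
        if ea.end <= eb.end:
            i += 1
        else:
            j += 1
    return total


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a locus and strand."""

    id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValidationError(f"gene {self.id} spans multiple chroms")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts} - {UNKNOWN}
        return strands.pop() if len(strands) == 1 else UNKNOWN

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exons(self) -> list[GenomicInterval]:
        """Merged union of all transcript exons, sorted."""
        ivals = sorted(
            (e.start, e.end) for t in self.transcripts for e in t.exons
        )
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged]

    @property
    def introns(self) -> list[GenomicInterval]:
        exons = self.exons
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
            if b.start > a.end
        ]


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular similarity-search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int  # 1-based inclusive, as in the file dialect
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}: negative E-value")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}: identity {self.percent_identity} out of range"
            )


class CodingScoreTable:
    """transcript_id -> coding-potential score (CPC-style index).

    Negative scores lean non-coding; the filter keeps transcripts scoring
    strictly below the configured cutoff.
    """

    def __init__(self, scores: Mapping[str, float] | Iterable[tuple[str, float]] = ()):
        self._scores: dict[str, float] = {}
        items = scores.items() if isinstance(scores, Mapping) else scores
        for tid, score in items:
            if tid in self._scores:
                raise ValidationError(f"duplicate score entry for {tid}")
            self._scores[tid] = float(score)

    def __contains__(self, tid: str) -> bool:
        return tid in self._scores

    def __getitem__(self, tid: str) -> float:
        return self._scores[tid]

    def get(self, tid: str, default: float | None = None) -> float | None:
        return self._scores.get(tid, default)

    def __len__(self) -> int:
        return len(self._scores)

    def __iter__(self) -> Iterator[str]:
        return iter(self._scores)

    def items(self):
        return self._scores.items()
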