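"""Readers and writers for the formats the pipeline touches.

GTF is read and written in its native 1-based inclusive convention and
converted to the library's 0-based half-open coordinates; FASTA goes
through Biopython; homology hit tables use the common 12-column
tab-separated layout (query, subject, %identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, E-value, bit score).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    UNKNOWN,
    CodingScoreTable,
    GeneModel,
    GenomicInterval,
    HomologyHit,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    """Raised on malformed input files; names the offending line."""


def _parse_gtf_exons(path: str | Path):
    """Yield (chrom, start0, end, strand, attrs) for each exon feature."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"{path}:{lineno}: invalid 1-based interval {start1}..{end1}"
                )
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = dict(_ATTR_RE.findall(attr))
            if "transcript_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            # GTF 1-based inclusive -> 0-based half-open
            yield chrom, start1 - 1, end1, strand, attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features and assemble transcripts, grouped by transcript_id."""
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    for chrom, start, end, strand, attrs in _parse_gtf_exons(path):
        tid = attrs["transcript_id"]
        exons_by_tid.setdefault(tid, []).append(
            GenomicInterval(chrom, start, end, strand)
        )
    return [TranscriptModel(tid, exons) for tid, exons in exons_by_tid.items()]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a GTF into gene models using the gene_id attribute for grouping."""
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    for chrom, start, end, strand, attrs in _parse_gtf_exons(path):
        tid = attrs["transcript_id"]
        exons_by_tid.setdefault(tid, []).append(
            GenomicInterval(chrom, start, end, strand)
        )
        gene_of[tid] = attrs.get("gene_id", tid)
    transcripts = {tid: TranscriptModel(tid, ex) for tid, ex in exons_by_tid.items()}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, t in transcripts.items():
        by_gene.setdefault(gene_of[tid], []).append(t)
    return [
        GeneModel(gid, sorted(ts, key=lambda t: t.id)) for gid, ts in by_gene.items()
    ]


def write_gtf(
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    gene_ids: Mapping[str, str] | None = None,
    source: str = "lncforge",
) -> None:
    """Write one exon feature per exon, 1-based inclusive, sorted
    deterministically by (chrom, start, transcript id)."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id))
    with open(path, "w") as fh:
        for t in ordered:
            gid = gene_ids.get(t.id, t.id) if gene_ids else t.id
            for e in t.exons:
                attr = f'gene_id "{gid}"; transcript_id "{t.id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attr,
                        ]
                    )
                    + "\n"
                )


def write_gene_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    transcripts = [t for g in genes for t in g.transcripts]
    gene_ids = {t.id: g.id for g in genes for t in g.transcripts}
    write_gtf(transcripts, path, gene_ids=gene_ids)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping."""
    records: dict[str, str] = {}
    dupes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            dupes.append(rec.id)
            continue
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"FASTA record {rec.id} has an empty sequence")
        records[rec.id] = seq
    if dupes:
        raise ValidationError(f"duplicate FASTA ids: {sorted(set(dupes))}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def spliced_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenate exon sequences in genomic order; reverse-complement for
    minus-strand transcripts.  Unknown strand reads in plus orientation."""
    if transcript.chrom not in genome:
        raise ValidationError(
            f"transcript {transcript.id}: chrom {transcript.chrom} not in genome"
        )
    chrom_seq = genome[transcript.chrom]
    if transcript.end > len(chrom_seq):
        raise ValidationError(
            f"transcript {transcript.id}: exon end {transcript.end} beyond "
            f"chrom length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in transcript.exons)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tab-separated hit table (E-values in scientific
    notation allowed).  Extra trailing columns are preserved opaquely with
    a single logged warning."""
    hits: list[HomologyHit] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                logger.warning(
                    "%s: hit table has %d columns; columns beyond 12 kept opaquely",
                    path,
                    len(fields),
                )
                warned_extra = True
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                        extra=tuple(fields[12:]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.alignment_length),
                str(h.mismatches),
                str(h.gap_opens),
                str(h.query_start),
                str(h.query_end),
                str(h.subject_start),
                str(h.subject_end),
                f"{h.evalue:.2e}",
                f"{h.bit_score:.1f}",
                *h.extra,
            ]
            fh.write("\t".join(fields) + "\n")


def read_score_table(path: str | Path) -> CodingScoreTable:
    """Read a two-column (transcript_id, score) TSV."""
    entries: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                entries.append((parts[0], float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
    return CodingScoreTable(entries)


def write_score_table(table: CodingScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, score in table.items():
            fh.write(f"{tid}\t{score:.4f}\n")


def write_bed6(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """BED6 export of transcript spans (name = id, score = 0)."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id))
    with open(path, "w") as fh:
        for t in ordered:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t0\t{t.strand}\n"
            )
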