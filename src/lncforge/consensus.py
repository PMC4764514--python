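"""Cross-dataset consensus: co-detection matching, support filtering,
redundancy removal, overlap deduplication and strand rescue.

Putative lncRNAs predicted independently from several transcriptome
datasets (all mapped to the same genome) are matched by genomic overlap;
a transcript is retained only when its co-detection component spans at
least ``min_support`` distinct datasets.  Each component is then
collapsed to a single non-redundant representative.  A further, stricter
rule removes the shorter member of any remaining cross-dataset pair
overlapping by more than 100 nt.  Finally, strand-unknown transcripts
adopt the strand of a counterpart from a stranded (Ribo-Zero style)
dataset when sequence identity over the shared region exceeds 95% and
the genomic spans coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import (
    MINUS,
    PLUS,
    UNKNOWN,
    TranscriptModel,
    exonic_overlap_nt,
)

logger = logging.getLogger(__name__)

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class DatasetCollection:
    """Named transcript sets with per-dataset strandedness flags."""

    datasets: dict[str, list[TranscriptModel]]
    stranded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.stranded - set(self.datasets)
        if unknown:
            raise ValueError(f"stranded flag for unknown datasets: {sorted(unknown)}")
        for name, ts in self.datasets.items():
            for t in ts:
                if not t.source_dataset:
                    t.source_dataset = name
                elif t.source_dataset != name:
                    raise ValueError(
                        f"transcript {t.id} tagged {t.source_dataset!r} "
                        f"but listed under dataset {name!r}"
                    )

    def all_transcripts(self) -> list[TranscriptModel]:
        return [t for name in sorted(self.datasets) for t in self.datasets[name]]


@dataclass(frozen=True)
class MatchEdge:
    """Co-detection of (putatively) the same transcript in two datasets."""

    transcript_a: str
    transcript_b: str
    overlap_nt: int
    identity_pct: float | None
    same_coordinates: bool


def _plus_base(t: TranscriptModel, plus_index: int) -> str:
    """Base at the given plus-orientation spliced index, regardless of how
    the sequence is stored (minus-strand sequences are stored 5'->3')."""
    assert t.sequence is not None
    if t.strand == MINUS:
        return _COMPL.get(t.sequence[len(t.sequence) - 1 - plus_index], "N")
    return t.sequence[plus_index]


def _genomic_index_map(t: TranscriptModel) -> dict[int, int]:
    """genomic position -> plus-orientation spliced index."""
    mapping: dict[int, int] = {}
    offset = 0
    for e in t.exons:
        for pos in range(e.start, e.end):
            mapping[pos] = offset
            offset += 1
    return mapping


def overlap_identity_pct(a: TranscriptModel, b: TranscriptModel) -> float | None:
    """Percent base identity over the exonic overlap, comparing genome-
    projected bases.  None when either sequence is absent or no overlap."""
    if a.sequence is None or b.sequence is None:
        return None
    map_a = _genomic_index_map(a)
    map_b = _genomic_index_map(b)
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        return None
    matches = sum(
        1 for pos in shared if _plus_base(a, map_a[pos]) == _plus_base(b, map_b[pos])
    )
    return 100.0 * matches / len(shared)


def build_match_graph(
    collection: DatasetCollection,
    min_identity: float = 95.0,
    min_overlap_nt: int = 1,
) -> list[MatchEdge]:
    """Emit an edge for every cross-dataset transcript pair overlapping
    genomically by at least *min_overlap_nt* on the same chrom.  When both
    sequences are present, identity over the overlap must also reach
    *min_identity* (secondary confirmation); coordinate overlap is the
    primary criterion since all datasets share one genome."""
    transcripts = collection.all_transcripts()
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    edges: list[MatchEdge] = []
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.start, t.id))
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if b.start >= a.end:
                    break
                if a.source_dataset == b.source_dataset:
                    continue
                ov = exonic_overlap_nt(a, b)
                if ov < min_overlap_nt:
                    continue
                ident = overlap_identity_pct(a, b)
                if ident is not None and ident < min_identity:
                    continue
                x, y = sorted((a, b), key=lambda t: t.id)
                edges.append(
                    MatchEdge(
                        transcript_a=x.id,
                        transcript_b=y.id,
                        overlap_nt=ov,
                        identity_pct=ident,
                        same_coordinates=(
                            a.span.overlap_nt(b.span) > 0
                        ),
                    )
                )
    return edges


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _components(
    transcripts: Sequence[TranscriptModel], edges: Sequence[MatchEdge]
) -> list[list[TranscriptModel]]:
    by_id = {t.id: t for t in transcripts}
    uf = _UnionFind(by_id)
    for e in edges:
        if e.transcript_a in by_id and e.transcript_b in by_id:
            uf.union(e.transcript_a, e.transcript_b)
    groups: dict[str, list[TranscriptModel]] = {}
    for tid in sorted(by_id):
        groups.setdefault(uf.find(tid), []).append(by_id[tid])
    return [groups[k] for k in sorted(groups)]


def consensus_filter(
    collection: DatasetCollection,
    edges: Sequence[MatchEdge],
    min_support: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts whose co-detection component spans at least
    *min_support* distinct datasets."""
    transcripts = collection.all_transcripts()
    kept: list[TranscriptModel] = []
    for comp in _components(transcripts, edges):
        if len({t.source_dataset for t in comp}) >= min_support:
            kept.extend(comp)
    return sorted(kept, key=lambda t: t.id)


def merge_redundant(
    kept: Sequence[TranscriptModel], edges: Sequence[MatchEdge]
) -> list[TranscriptModel]:
    """Collapse each co-detection component to one representative —
    the redundancy removal applied after consensus support in both
    regimes.  Representative: strand-known over unknown, then longest
    spliced length, then smallest id."""
    reps = []
    for comp in _components(kept, edges):
        rep = min(
            comp, key=lambda t: (t.strand == UNKNOWN, -t.length, t.id)
        )
        reps.append(rep)
    return sorted(reps, key=lambda t: t.id)


def deduplicate(
    kept: Sequence[TranscriptModel], max_overlap_nt: int = 100
) -> list[TranscriptModel]:
    """Stricter positional redundancy rule: while any cross-dataset pair
    overlaps by more than *max_overlap_nt*, remove the shorter member
    (spliced length; ties remove the lexicographically later id).

    Deterministic fixpoint: each step resolves the conflicting pair with
    the largest overlap (ties by id pair)."""
    current = sorted(kept, key=lambda t: t.id)
    while True:
        conflicts = []
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in current:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom in sorted(by_chrom):
            ts = sorted(by_chrom[chrom], key=lambda t: (t.start, t.id))
            for i, a in enumerate(ts):
                for b in ts[i + 1 :]:
                    if b.start >= a.end:
                        break
                    if a.source_dataset == b.source_dataset:
                        continue
                    ov = exonic_overlap_nt(a, b)
                    if ov > max_overlap_nt:
                        x, y = sorted((a, b), key=lambda t: t.id)
                        conflicts.append((ov, x.id, y.id, x, y))
        if not conflicts:
            return current
        conflicts.sort(key=lambda c: (-c[0], c[1], c[2]))
        _, _, _, x, y = conflicts[0]
        if x.length != y.length:
            loser = x if x.length < y.length else y
        else:
            loser = max(x, y, key=lambda t: t.id)
        current = [t for t in current if t.id != loser.id]


def assign_strand(
    unstranded: Sequence[TranscriptModel],
    stranded_set: Sequence[TranscriptModel],
    min_identity: float = 95.0,
) -> list[TranscriptModel]:
    """Strand rescue: a strand-unknown transcript adopts the strand of a
    stranded counterpart when identity over the shared region exceeds
    *min_identity* (strict >) and the genomic spans overlap.  Conflicting
    counterparts leave the strand unknown, with a logged warning."""
    stranded_by_chrom: dict[str, list[TranscriptModel]] = {}
    for s in stranded_set:
        if s.strand == UNKNOWN:
            raise ValueError(f"stranded counterpart {s.id} has unknown strand")
        stranded_by_chrom.setdefault(s.chrom, []).append(s)
    out: list[TranscriptModel] = []
    for t in unstranded:
        if t.strand != UNKNOWN:
            out.append(t)
            continue
        strands = set()
        for s in stranded_by_chrom.get(t.chrom, []):
            if t.span.overlap_nt(s.span) <= 0:
                continue
            ident = overlap_identity_pct(t, s)
            if ident is not None and ident > min_identity:
                strands.add(s.strand)
        if len(strands) == 1:
            out.append(t.with_strand(strands.pop()))
        else:
            if len(strands) > 1:
                logger.warning(
                    "transcript %s matches stranded counterparts on both "
                    "strands; strand left unknown",
                    t.id,
                )
            out.append(t)
    return out
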