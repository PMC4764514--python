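"""Independent brute-force oracles used to validate the optimized
implementations.  These deliberately use naive exhaustive scans and share
no code path with the library functions they check."""

from __future__ import annotations

from lncforge.model import (
    GeneModel,
    TranscriptModel,
    UNKNOWN,
    reverse_complement,
)

_STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq: str, frames: int = 3):
    """Enumerate every ATG and its first in-frame stop; return
    (aa_length, start, on_reverse) of the best ORF, or (0, None, None)."""
    seq = seq.upper()
    candidates = []
    strands = [(seq, False)]
    if frames == 6:
        strands.append((reverse_complement(seq), True))
    for s, rev in strands:
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(s):
                if s[j : j + 3] in _STOPS:
                    candidates.append(((j - i) // 3, i, rev))
                    break
                j += 3
    if not candidates:
        return 0, None, None
    return min(candidates, key=lambda c: (-c[0], c[1], c[2]))


def _exon_overlap(a: TranscriptModel, b_exons) -> int:
    total = 0
    for ea in a.exons:
        for s, e in b_exons:
            total += max(0, min(ea.end, e) - max(ea.start, s))
    return total


def classify_oracle(lnc: TranscriptModel, genes: list[GeneModel], window: int = 15_000):
    """Exhaustive O(N*M) genomic-context classifier following the same
    category taxonomy and precedence, with plain nested loops."""
    on_chrom = sorted(
        (g for g in genes if g.chrom == lnc.chrom), key=lambda g: g.id
    )

    def orient(gs: str) -> str:
        if lnc.strand == UNKNOWN or gs == UNKNOWN:
            return "unknown"
        return "same" if lnc.strand == gs else "opposite"

    # 1. containing
    for intron in lnc.introns:
        for g in on_chrom:
            span = g.span
            if intron.start <= span.start and span.end <= intron.end:
                return "containing", g.id
    # 2. exonic
    exonic = [
        g
        for g in on_chrom
        if _exon_overlap(lnc, [(e.start, e.end) for e in g.exons]) > 0
    ]
    if exonic:
        g = exonic[0]
        cat = {
            "same": "exonic_sense",
            "opposite": "exonic_antisense",
            "unknown": "exonic_unknown",
        }[orient(g.strand)]
        return cat, g.id
    # 3. intronic (span overlap, no exon contact)
    spanning = [
        g
        for g in on_chrom
        if max(0, min(lnc.end, g.span.end) - max(lnc.start, g.span.start)) > 0
    ]
    if spanning:
        return "intronic", spanning[0].id
    # 4./5. intergenic by nearest distance
    best, best_d = None, None
    for g in on_chrom:
        span = g.span
        if span.end <= lnc.start:
            d = lnc.start - span.end
        else:
            d = span.start - lnc.end
        if best_d is None or d < best_d or (d == best_d and g.id < best.id):
            best, best_d = g, d
    if best is None or best_d > window:
        return "intergenic_distal", best.id if best else None
    cat = {
        "same": "intergenic_convergent",
        "opposite": "intergenic_divergent",
        "unknown": "intergenic_unoriented",
    }[orient(best.strand)]
    return cat, best.id


def match_edges_oracle(transcripts: list[TranscriptModel], min_overlap_nt: int = 1):
    """All-pairs cross-dataset exonic-overlap scan; returns the set of
    (id_a, id_b, overlap) triples with id_a < id_b."""
    out = set()
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1 :]:
            if a.source_dataset == b.source_dataset or a.chrom != b.chrom:
                continue
            ov = _exon_overlap(a, [(e.start, e.end) for e in b.exons])
            if ov >= min_overlap_nt:
                x, y = sorted((a.id, b.id))
                out.add((x, y, ov))
    return out


def has_dedup_conflict(
    transcripts: list[TranscriptModel], max_overlap_nt: int = 100
) -> bool:
    """Brute-force check for any remaining cross-dataset pair overlapping
    by more than the threshold."""
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1 :]:
            if a.source_dataset == b.source_dataset or a.chrom != b.chrom:
                continue
            if _exon_overlap(a, [(e.start, e.end) for e in b.exons]) > max_overlap_nt:
                return True
    return False
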