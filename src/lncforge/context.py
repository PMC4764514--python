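"""Genomic-context classification of lncRNAs relative to protein-coding
genes, and the position-based stringent filters.

Categories (decided in this fixed precedence):

1. ``containing``       — a coding gene lies entirely within an intron of
                          the lncRNA;
2. ``exonic_{sense,antisense,unknown}``
                        — an lncRNA exon shares sequence with a coding
                          exon, subdivided by relative strand;
3. ``intronic``         — the lncRNA overlaps a gene's span but touches no
                          coding exon (it lives in intronic sequence);
4. ``intergenic_{convergent,divergent,unoriented}``
                        — no overlap, nearest gene within a window
                          (default 15 kb); convergent = same strand as the
                          nearest gene, divergent = opposite (this
                          taxonomy's own usage), unoriented when either
                          strand is unknown;
5. ``intergenic_distal`` — nearest gene beyond the window (or none).

Distances between half-open intervals use gap = start2 - end1, so abutting
features are at distance 0; "within" windows are inclusive.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import UNKNOWN, GeneModel, TranscriptModel

INTRONIC = "intronic"
EXONIC_SENSE = "exonic_sense"
EXONIC_ANTISENSE = "exonic_antisense"
EXONIC_UNKNOWN = "exonic_unknown"
CONTAINING = "containing"
INTERGENIC_CONVERGENT = "intergenic_convergent"
INTERGENIC_DIVERGENT = "intergenic_divergent"
INTERGENIC_UNORIENTED = "intergenic_unoriented"
INTERGENIC_DISTAL = "intergenic_distal"

CATEGORIES = (
    INTRONIC,
    EXONIC_SENSE,
    EXONIC_ANTISENSE,
    EXONIC_UNKNOWN,
    CONTAINING,
    INTERGENIC_CONVERGENT,
    INTERGENIC_DIVERGENT,
    INTERGENIC_UNORIENTED,
    INTERGENIC_DISTAL,
)
GENIC_CATEGORIES = frozenset(
    {INTRONIC, EXONIC_SENSE, EXONIC_ANTISENSE, EXONIC_UNKNOWN, CONTAINING}
)


@dataclass(frozen=True)
class ClassificationResult:
    lnc_id: str
    category: str
    nearest_gene_id: str | None
    distance_nt: float  # 0 when overlapping; math.inf when no gene on chrom
    relative_orientation: str  # "same" | "opposite" | "unknown"

    @property
    def genic(self) -> bool:
        return self.category in GENIC_CATEGORIES


class GeneIndex:
    """Interval index over gene spans and exons, keyed by chrom."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.span.start, g.id))
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._starts: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in self.genes:
            span = g.span
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(
                span.start, span.end, g
            )
            for e in g.exons:
                self._exon_trees.setdefault(g.chrom, IntervalTree()).addi(
                    e.start, e.end, g
                )
            self._starts.setdefault(g.chrom, []).append((span.start, span.end, g))
        for chrom in self._starts:
            self._starts[chrom].sort(key=lambda x: (x[0], x[1], x[2].id))

    @staticmethod
    def _unique(genes) -> list[GeneModel]:
        by_id = {g.id: g for g in genes}
        return [by_id[k] for k in sorted(by_id)]

    def overlapping_spans(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        return self._unique(iv.data for iv in tree.overlap(start, end))

    def overlapping_exons(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        return self._unique(iv.data for iv in tree.overlap(start, end))


def nearest_gene_distance(
    lncrna: TranscriptModel, index: GeneIndex
) -> tuple[str | None, float]:
    """Nearest gene on the lncRNA's chrom and the gap to it (0 when the
    spans overlap or abut; inf when the chrom carries no gene)."""
    entries = index._starts.get(lncrna.chrom)
    if not entries:
        return None, math.inf
    best_id, best_d = None, math.inf
    for start, end, g in entries:
        if end <= lncrna.start:
            d = lncrna.start - end
        elif start >= lncrna.end:
            d = start - lncrna.end
        else:
            d = 0
        if d < best_d or (d == best_d and (best_id is None or g.id < best_id)):
            best_id, best_d = g.id, d
    return best_id, float(best_d)


def _orientation(lnc_strand: str, gene_strand: str) -> str:
    if lnc_strand == UNKNOWN or gene_strand == UNKNOWN:
        return "unknown"
    return "same" if lnc_strand == gene_strand else "opposite"


def classify(
    lncrna: TranscriptModel, index: GeneIndex, window: int = 15_000
) -> ClassificationResult:
    """Assign exactly one genomic-context category (precedence in the
    module docstring)."""
    # 1. containing: a gene entirely inside one of the lncRNA's introns
    for intron in lncrna.introns:
        for g in index.overlapping_spans(lncrna.chrom, intron.start, intron.end):
            span = g.span
            if intron.start <= span.start and span.end <= intron.end:
                return ClassificationResult(
                    lncrna.id,
                    CONTAINING,
                    g.id,
                    0.0,
                    _orientation(lncrna.strand, g.strand),
                )
    # 2. exonic: exon-level overlap with a coding exon
    exonic_genes = []
    for e in lncrna.exons:
        exonic_genes.extend(index.overlapping_exons(lncrna.chrom, e.start, e.end))
    if exonic_genes:
        g = min(exonic_genes, key=lambda g: g.id)
        orient = _orientation(lncrna.strand, g.strand)
        category = {
            "same": EXONIC_SENSE,
            "opposite": EXONIC_ANTISENSE,
            "unknown": EXONIC_UNKNOWN,
        }[orient]
        return ClassificationResult(lncrna.id, category, g.id, 0.0, orient)
    # 3. intronic: overlaps a gene span without touching its exons
    span_genes = index.overlapping_spans(lncrna.chrom, lncrna.start, lncrna.end)
    if span_genes:
        g = min(span_genes, key=lambda g: g.id)
        return ClassificationResult(
            lncrna.id, INTRONIC, g.id, 0.0, _orientation(lncrna.strand, g.strand)
        )
    # 4./5. intergenic, by distance to the nearest gene
    gene_id, dist = nearest_gene_distance(lncrna, index)
    if gene_id is None or dist > window:
        orient = "unknown"
        if gene_id is not None:
            gene = next(g for g in index.genes if g.id == gene_id)
            orient = _orientation(lncrna.strand, gene.strand)
        return ClassificationResult(lncrna.id, INTERGENIC_DISTAL, gene_id, dist, orient)
    gene = next(g for g in index.genes if g.id == gene_id)
    orient = _orientation(lncrna.strand, gene.strand)
    category = {
        "same": INTERGENIC_CONVERGENT,
        "opposite": INTERGENIC_DIVERGENT,
        "unknown": INTERGENIC_UNORIENTED,
    }[orient]
    return ClassificationResult(lncrna.id, category, gene_id, dist, orient)


def classify_all(
    lncrnas: Sequence[TranscriptModel], index: GeneIndex, window: int = 15_000
) -> list[ClassificationResult]:
    return [classify(t, index, window) for t in lncrnas]


def filter_sense_overlap(
    lncrnas: Sequence[TranscriptModel], index: GeneIndex
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove lncRNAs whose exons overlap a coding gene's exons on the
    same (known) strand.  Unknown strands cannot establish sense and are
    kept."""
    kept, removed = [], []
    for t in lncrnas:
        sense = False
        if t.strand != UNKNOWN:
            for e in t.exons:
                for g in index.overlapping_exons(t.chrom, e.start, e.end):
                    if g.strand == t.strand:
                        sense = True
        (removed if sense else kept).append(t)
    return kept, removed


def filter_single_exon_proximity(
    lncrnas: Sequence[TranscriptModel],
    index: GeneIndex,
    max_gap: int = 500,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove single-exon lncRNAs adjacent to (not overlapping) a coding
    gene within *max_gap* nt (inclusive)."""
    kept, removed = [], []
    for t in lncrnas:
        if t.n_exons == 1:
            _gene, dist = nearest_gene_distance(t, index)
            if 0 < dist <= max_gap:
                removed.append(t)
                continue
        kept.append(t)
    return kept, removed


def summarize_classes(results: Sequence[ClassificationResult]) -> dict[str, int]:
    """Per-category counts plus genic / intergenic / total aggregates."""
    counts = Counter(r.category for r in results)
    table = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    table["genic"] = sum(table[c] for c in GENIC_CATEGORIES)
    table["intergenic"] = sum(
        table[c]
        for c in (
            INTERGENIC_CONVERGENT,
            INTERGENIC_DIVERGENT,
            INTERGENIC_UNORIENTED,
            INTERGENIC_DISTAL,
        )
    )
    table["total"] = len(results)
    return table
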