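# Methods

## Problem and model

lncRNAs are transcripts longer than 200 nt with little or no
protein-coding capacity. They are hard to identify computationally
because they are weakly conserved and lowly expressed, so discovery is a
*filtration* problem: start from all assembled transcripts and remove
everything with positive evidence of being something else (an mRNA, a
pseudogene transcript, a structural RNA). lncforge implements that
cascade, a multi-dataset consensus step that suppresses assembly noise,
a positional taxonomy relative to the coding annotation, and a tissue
expression atlas.

All coordinates are 0-based half-open internally; GTF I/O converts to
the format's 1-based inclusive convention. Strand may be unknown
throughout: in the study design the package targets, only one of four
datasets (a Ribo-Zero library) preserves orientation, and orientation
for the rest is *rescued* rather than assumed.

## Filter cascade

Stage order: minimum length → ORF → protein homology → coding score →
small-ncRNA homology. Thresholds and their strictness:

| parameter            | traditional | stringent | comparison |
|----------------------|-------------|-----------|------------|
| min length           | 200 nt      | 200 nt    | `< 200` removed (exactly 200 kept) |
| max ORF              | 100 aa      | 83 aa     | `>` removed (boundary kept) |
| max ORF coverage     | —           | 0.35      | `>` removed (exactly 0.35 kept) |
| homology E-value     | 10⁻⁴        | 10⁻⁴      | `≤` removed (inclusive) |
| coding score cutoff  | −0.5        | −1.0      | kept iff strictly below |

An ORF is a *complete* ATG→stop span; the amino-acid length counts the
initial Met and excludes the stop; the coverage fraction is
3·(aa + 1)/length, i.e. the ORF footprint including its stop codon.
Incomplete ORFs (no in-frame stop) do not count, and codons containing N
never act as start or stop. Strand-known transcripts are scanned in the
3 forward frames of their 5'→3' sequence; strand-unknown transcripts in
all 6 (the mRNA could sit on either strand). Both choices are
configurable (`FilterConfig.orf_frames`) since reasonable tools differ
here.

Transcripts absent from the coding-score table are kept and counted in
the log: an absent score is no evidence of coding ability, and dropping
them silently would bias against poorly characterized transcripts.

The known-lncRNA database search is *annotation only* — matches flag a
transcript as evolutionarily conserved but never remove it, reflecting
that conservation with characterized lncRNAs is corroborating, not
disqualifying, evidence.

Every stage reports (n_in, n_removed, n_out) and the report object
enforces n_in = n_removed + n_out per stage plus chaining across stages,
so count bookkeeping errors cannot pass silently.

## Consensus across datasets

Datasets share one genome, so co-detection is decided primarily by
genomic (exon-level) overlap; when spliced sequences are available,
identity over the shared region must also reach 95% as confirmation.
Any overlap (≥ 1 nt) counts as co-detection by default. A transcript
survives iff its co-detection component spans ≥ 2 distinct datasets;
each component then collapses to one representative (strand-known
preferred, then longest spliced length, then smallest id) — this is the
redundancy-removal step, applied in both regimes.

The stringent regime additionally applies the positional dedup rule:
while any cross-dataset pair overlaps by more than 100 nt, the shorter
member is removed. "Shorter" is spliced length (a documented choice —
genomic span is the defensible alternative). To make the fixpoint
deterministic, each iteration resolves the single conflicting pair with
the largest overlap (ties by id pair), removing the shorter member (tie:
the lexicographically later id).

Strand rescue copies the strand from a stranded counterpart when
identity over the shared bases is strictly above 95% and the genomic
spans overlap. Counterparts on conflicting strands leave the transcript
unknown, with a warning. A rescued minus-strand transcript has its
stored sequence reverse-complemented so sequences stay 5'→3'.

## Genomic-context classification

Exactly one category per lncRNA, by fixed precedence (the taxonomy
itself does not define precedence for transcripts meeting several
definitions, so the package fixes one): `containing` (a coding gene
entirely inside an lncRNA intron) > `exonic_*` (exon–exon overlap,
subdivided sense/antisense/unknown by strand pair) > `intronic` (gene
span overlap without exon contact) > `intergenic_*`. Intergenic
transcripts within 15 kb (inclusive) of the nearest gene are
`convergent` when on the same strand as that gene and `divergent` when
opposite — this taxonomy's own usage of those words, kept deliberately
even though head-to-head/tail-to-tail is the commoner meaning —
`unoriented` when either strand is unknown, and `distal` beyond the
window. Distance between half-open intervals is start₂ − end₁, so
abutting features are 0 nt apart.

The interval index is backed by interval trees plus sorted span lists;
its answers are property-tested against an exhaustive O(N·M) classifier
on randomized gene/lncRNA configurations.

Positional stringent filters: sense-overlap removal requires both
strands known and equal at exon level (unknown strand cannot establish
"sense" and is kept, logged); the single-exon proximity rule removes
single-exon lncRNAs at 0 < distance ≤ 500 nt, leaving overlapping cases
to the other filters.

## Expression atlas

RPKM uses the library totals supplied with the counts (mapping policy
for multi-mapped reads is upstream of this package). Mean-scaling
normalization multiplies each tissue column by (mean of column means) /
(column mean), so all column means become equal; all-zero columns are
left untouched with a warning.

Tissue specificity: x_t ≥ 8·max_{j≠t} x_j (inclusive ≥, so exactly
8-fold qualifies) with the 0.5-RPKM floor applied to the candidate
tissue's own value — the natural reading, documented because the rule's
prose admits others. For fold > 1 at most one tissue can qualify, and
the specific and ubiquitous sets are provably disjoint at the default
thresholds.

Entropy uses tissue shares and log base 2 (configurable), so a uniform
13-tissue profile scores log₂13 ≈ 3.7004 bits and a one-tissue profile
scores 0.

Clustering is average-linkage agglomerative on Pearson correlation
distance (1 − r), cut at distance 1 − 0.97; for average linkage every
within-cluster mean pairwise distance is a convex combination of merge
heights, so each reported cluster's mean pairwise correlation is ≥ 0.97
by construction (and re-verified by direct recomputation in the tests).
The 0.97 threshold is the contract; the linkage choice is this package's
(the original analysis used an interactive tool whose exact routine is
not specified). Zero-variance profiles are excluded (correlation is
undefined) with a logged count; singleton "clusters" are not reported.
Within each cluster, members are ranked by entropy and the top
⌈0.20·size⌉ retained, so small clusters keep at least one member.

## Synthetic fixture: what it emulates and what it does not

The generator lays the genome out in per-transcript blocks (50 kb per
lncRNA block, 12 kb per coding block, 3 kb per small-RNA block) so every
planted genomic-context class is realized exactly by construction and
placement cannot fail. Defaults mirror the targeted study conditions:
four datasets with one stranded; 13 tissues; 300 lncRNAs spread over all
nine context classes; 200 coding and 100 small-RNA decoys; lncRNA
lengths ~0.82 kb versus ~1.64 kb for coding transcripts; ~90% of
lncRNAs single-exon.

Sequence design makes ORF properties certain rather than probable:
coding ORFs are stop-free codon runs flanked by stop-dense UTRs, and all
non-coding sequence carries a stop cassette (`TTAATTAATTAA`, stops in
all three frames on both strands) every ~45 nt, so a spurious ORF longer
than ~60 aa cannot arise even where an lncRNA overlaps a coding exon
(overlaps are capped at 90 nt). Planted evidence clears each threshold
with roughly a 2× margin (coding scores ≤ −2 vs the −1.0 cutoff, decoy
protein hits at E ≥ 10⁻³ vs the 10⁻⁴ cutoff, specific-tissue RPKM 32 vs
the 8 × 0.25 + 0.5 requirement), so noise-free recovery is exact and
recovery under noise is a sharp recall measurement.

Counts are negative-binomial around the expected RPKM (dispersion
size = 20 by default; `nb_dispersion=None` gives rounded noise-free
means). Planted co-expression blocks use a tighter dispersion
(size = 300): a Pearson-0.97 cut can only ever recover genes that
co-vary within ~10% noise, so "co-expressed" is *defined* as tightly
co-varying; with the global dispersion the attainable correlation
(~0.93–0.95) sits below the threshold for every pair, planted or not.

The subsets of the coding role (short-ORF with a protein hit,
pseudogene-like; short-ORF caught only by the coding score) exist so
that *every* cascade stage removes a planted subset, as does the
rRNA-like long small-RNA subset for the final stage.

What the fixture does **not** emulate: read-level sequencing error,
genome duplication and paralogy, alternative isoforms, partial overlap
between genuinely distinct lncRNAs across datasets, multi-mapping
ambiguity, or realistic inter-gene spacing. Passing the planted-truth
tests therefore demonstrates that the *decision logic* is exact under
the stated definitions — not that the thresholds themselves are optimal
for any real genome.

## Problem sizes and numerics

The reference fixture (~600 planted transcripts, ~1,200 emitted copies,
~17.6 Mb genome) generates in a few seconds and the full two-regime run
plus atlas completes in under ten; tests use a smaller 36-transcript
variant where per-case speed matters. All randomness flows from a
single `numpy` `default_rng(seed)`; identical (config, seed) reproduce
byte-identical artifacts. Floating-point comparisons in the atlas use
exact arithmetic where the contract is exact (conservation counts,
curve terminus pinned to 1.0) and machine-precision tolerances
elsewhere.

## Known limitations

- The cascade consumes precomputed homology and coding-score tables; it
  does not validate that those searches were sensibly parameterized.
- Consensus matching is coordinate-anchored; it would under-merge
  transcripts assembled against different genome builds.
- The convergent/divergent naming follows the implemented taxonomy's
  parentheticals, not the commoner promoter-geometry meaning.
- TSS/promoter-anchored categories (e.g. bidirectional promoters) and
  cis-target prediction are out of scope.
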