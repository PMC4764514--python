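"""Deterministic synthetic genome / transcriptome generator with planted
ground truth.

The generator emulates the study conditions the pipeline was designed
for: four transcriptome datasets (one stranded, Ribo-Zero style) mapped
to one genome, 13 tissues, and three transcript roles —

* protein-coding mRNAs (long ORFs, protein-database hits, positive
  coding-potential scores; a pseudogene-like subset carries only a short
  ORF plus a protein hit, and a further subset is caught only by the
  coding-score filter, so every cascade stage removes a planted subset);
* small / structural non-coding RNAs (mostly < 200 nt; an rRNA-like
  subset is longer but carries ncRNA-database hits);
* lncRNAs planted to realize each genomic-context category exactly, with
  lengths centred near 0.82 kb versus 1.64 kb for coding transcripts and
  a strong single-exon bias, mirroring what is reported for real lncRNA
  catalogues.

Sequence design guarantees ORF properties by construction: coding ORFs
are written as stop-free codon runs, and non-coding sequence is seeded
with a stop cassette ("TTAATTAATTAA", stop codons in all three frames on
both strands) every ~45 nt, so no spurious long ORF can arise.  Planted
signals clear their filter thresholds with about a 2x margin so that
noise-free recovery is exact.

Everything is a pure function of (config, seed): the same inputs yield
byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import CountMatrix
from .filters import CascadeInputs
from .model import (
    MINUS,
    PLUS,
    UNKNOWN,
    CodingScoreTable,
    GeneModel,
    GenomicInterval,
    HomologyHit,
    TranscriptModel,
)
from .orf import find_longest_orf

STOP_CASSETTE = "TTAATTAATTAA"  # stops in all 3 frames, both strands
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

DEFAULT_TISSUES = (
    "brain",
    "white_muscle",
    "red_muscle",
    "fat",
    "gill",
    "head_kidney",
    "kidney",
    "intestine",
    "skin",
    "spleen",
    "stomach",
    "liver",
    "testis",
)

DEFAULT_CLASS_COUNTS = {
    "intronic": 60,
    "exonic_sense": 20,
    "exonic_antisense": 30,
    "exonic_unknown": 20,
    "containing": 10,
    "intergenic_convergent": 50,
    "intergenic_divergent": 50,
    "intergenic_unoriented": 40,
    "intergenic_distal": 20,
}

ROLE_CODING = "coding"
ROLE_SMALL = "small_rna"
ROLE_LNCRNA = "lncrna"


@dataclass
class SynthConfig:
    seed: int = 42
    # planted population
    n_coding: int = 200
    n_coding_short_orf_with_hit: int = 40  # pseudogene-like, caught by homology
    n_coding_score_only: int = 20  # caught only by the coding-score filter
    n_small_rna: int = 100
    n_rrna_like: int = 20  # subset of n_small_rna, > 200 nt with ncRNA hits
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    # datasets: two poly-A selected sets (paired/single read), one small
    # assembly, and one stranded rRNA-depleted (Ribo-Zero style) set
    dataset_names: tuple[str, ...] = ("polya_pe", "polya_se", "assembly_sm", "ribozero")
    stranded_dataset: str = "ribozero"
    lnc_single_dataset_fraction: float = 0.0  # planted consensus failures
    # genome layout
    lnc_block_nt: int = 50_000
    lnc_blocks_per_chrom: int = 75
    coding_block_nt: int = 12_000
    small_block_nt: int = 3_000
    # lengths
    lnc_length_mean: float = 820.0
    lnc_length_sd: float = 250.0
    coding_length_mean: float = 1_640.0
    coding_length_sd: float = 400.0
    lnc_two_exon_fraction: float = 0.10  # intergenic classes only
    # annotation tables
    n_conserved: int = 30  # lncRNAs with known-lncRNA database hits
    n_missing_score: int = 10  # lncRNAs absent from the score table
    n_decoy_protein_hits: int = 20  # lncRNAs with sub-threshold protein hits
    # expression
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    library_size: int = 2_000_000
    n_tissue_specific: int = 60
    n_ubiquitous: int = 60
    n_cluster_blocks: int = 5
    cluster_block_lnc: int = 3
    cluster_block_coding: int = 3
    specific_rpkm: float = 32.0  # 8-fold rule cleared with ~2x margin
    background_rpkm: float = 0.25
    ubiquitous_rpkm_range: tuple[float, float] = (6.0, 10.0)
    cluster_amplitude_range: tuple[float, float] = (60.0, 120.0)
    cluster_peak_tissues: int = 3
    nb_dispersion: float | None = 20.0  # None -> noise-free (rounded means)
    # planted co-expression blocks co-vary within tight measurement noise:
    # a correlation-0.97 cut can only ever recover such genes
    cluster_nb_dispersion: float = 300.0

    @property
    def n_lncrna(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class TruthRecord:
    id: str
    role: str
    lnc_class: str | None
    strand: str
    datasets: tuple[str, ...]
    orf_aa: int
    coding_score: float | None
    has_protein_hit: bool
    has_ncrna_hit: bool
    conserved: bool
    expression_pattern: str | None
    chrom: str
    start: int
    end: int
    n_exons: int
    length: int
    consensus_expected: bool
    stringent_kept: bool


@dataclass
class SyntheticTruth:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.id in self.records:
            raise ValueError(f"duplicate truth id {rec.id}")
        self.records[rec.id] = rec

    def ids_with_role(self, role: str) -> set[str]:
        return {r.id for r in self.records.values() if r.role == role}

    def lncrna_ids(self) -> set[str]:
        return self.ids_with_role(ROLE_LNCRNA)

    def expected_traditional_ids(self) -> set[str]:
        """Base ids the traditional end-to-end pipeline should recover."""
        return {
            r.id
            for r in self.records.values()
            if r.role == ROLE_LNCRNA and r.consensus_expected
        }

    def expected_stringent_ids(self) -> set[str]:
        return {
            r.id
            for r in self.records.values()
            if r.role == ROLE_LNCRNA and r.consensus_expected and r.stringent_kept
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(r) for r in self.records.values()]
        df = pd.DataFrame(rows).set_index("id").sort_index()
        df["datasets"] = df["datasets"].map(lambda d: ",".join(d))
        return df


@dataclass
class SyntheticData:
    config: SynthConfig
    genome: dict[str, str]
    coding_genes: list[GeneModel]
    datasets: dict[str, list[TranscriptModel]]
    stranded_datasets: set[str]
    cascade_inputs: CascadeInputs
    counts: CountMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------- helpers


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _noncoding_filler(rng: np.random.Generator, n: int) -> str:
    """Random sequence with the all-frame stop cassette every ~45 nt,
    starting with a cassette, so no ORF longer than ~17 aa can form."""
    parts = []
    total = 0
    while total < n:
        parts.append(STOP_CASSETTE)
        total += len(STOP_CASSETTE)
        chunk = min(33, max(0, n - total))
        if chunk:
            parts.append(_random_bases(rng, chunk))
            total += chunk
    return "".join(parts)[:n]


def _coding_mrna(rng: np.random.Generator, length: int, orf_aa: int) -> str:
    """mRNA of *length* nt whose longest ORF is exactly the designed one:
    18 nt random + stop cassette + ATG + (aa-1) sense codons + stop +
    stop-dense 3' filler."""
    orf_nt = 3 * (orf_aa + 1)
    utr5 = _random_bases(rng, 18) + STOP_CASSETTE
    if len(utr5) + orf_nt > length:
        raise ValueError(f"length {length} too short for {orf_aa} aa ORF")
    orf = (
        "ATG"
        + "".join(rng.choice(SENSE_CODONS) for _ in range(orf_aa - 1))
        + str(rng.choice(["TAA", "TAG", "TGA"]))
    )
    utr3 = _noncoding_filler(rng, length - len(utr5) - len(orf))
    return utr5 + orf + utr3


def _sample_length(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


class _Stamper:
    """Writes designed transcript sequences into the genome, tracking
    which positions are already fixed by an earlier (coding) feature."""

    def __init__(self, rng: np.random.Generator, chrom_lengths: dict[str, int]):
        self.rng = rng
        bases = np.frombuffer(b"ACGT", dtype="S1")
        self.arrays = {
            c: bases[rng.integers(0, 4, n)].copy() for c, n in chrom_lengths.items()
        }
        self.stamped = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}

    def stamp_transcript(self, t: TranscriptModel, designed: str) -> None:
        """Write *designed* (5'->3') along the transcript's exons."""
        if len(designed) != t.length:
            raise ValueError("designed sequence length mismatch")
        genomic = designed
        if t.strand == MINUS:
            from .model import reverse_complement

            genomic = reverse_complement(designed)
        offset = 0
        arr = self.arrays[t.chrom]
        mask = self.stamped[t.chrom]
        for e in t.exons:
            piece = genomic[offset : offset + e.length]
            arr[e.start : e.end] = np.frombuffer(piece.encode(), dtype="S1")
            mask[e.start : e.end] = True
            offset += e.length

    def fill_noncoding(self, t: TranscriptModel) -> None:
        """Fill the not-yet-stamped portions of a transcript's exons with
        stop-dense non-coding filler (already-stamped overlaps with coding
        exons are left untouched)."""
        arr = self.arrays[t.chrom]
        mask = self.stamped[t.chrom]
        for e in t.exons:
            pos = e.start
            while pos < e.end:
                if mask[pos]:
                    pos += 1
                    continue
                run_end = pos
                while run_end < e.end and not mask[run_end]:
                    run_end += 1
                filler = _noncoding_filler(self.rng, run_end - pos)
                arr[pos:run_end] = np.frombuffer(filler.encode(), dtype="S1")
                pos = run_end
        # non-coding regions stay unmasked so a retry can re-randomize them

    def sequence_of(self, t: TranscriptModel) -> str:
        arr = self.arrays[t.chrom]
        seq = "".join(
            arr[e.start : e.end].tobytes().decode() for e in t.exons
        )
        if t.strand == MINUS:
            from .model import reverse_complement

            seq = reverse_complement(seq)
        return seq

    def genome(self) -> dict[str, str]:
        return {c: a.tobytes().decode() for c, a in self.arrays.items()}


def _host_gene(gid: str, chrom: str, block: int, strand: str) -> GeneModel:
    """Three-exon host gene near the start of an lncRNA block; intron 1
    spans [b+1600, b+5600) and offers room for intronic planting."""
    b = block
    exons = [
        GenomicInterval(chrom, b + 1000, b + 1600, strand),
        GenomicInterval(chrom, b + 5600, b + 6400, strand),
        GenomicInterval(chrom, b + 9400, b + 10_000, strand),
    ]
    return GeneModel(gid, [TranscriptModel(f"{gid}.t1", exons)])


def _lnc_exons(
    chrom: str, start: int, length: int, strand: str, n_exons: int
) -> list[GenomicInterval]:
    if n_exons == 1:
        return [GenomicInterval(chrom, start, start + length, strand)]
    a = length // 2
    return [
        GenomicInterval(chrom, start, start + a, strand),
        GenomicInterval(chrom, start + a + 300, start + length + 300, strand),
    ]


# ---------------------------------------------------------------- generate


def generate(config: SynthConfig | None = None) -> SyntheticData:
    """Build the full fixture: genome, reference annotation, per-dataset
    candidate transcripts, homology/score tables, counts and truth."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_rrna_like > cfg.n_small_rna:
        raise ValueError("n_rrna_like cannot exceed n_small_rna")
    if cfg.n_coding_short_orf_with_hit + cfg.n_coding_score_only > cfg.n_coding:
        raise ValueError("coding subsets exceed n_coding")

    truth = SyntheticTruth()
    genes: list[GeneModel] = []
    planted: list[tuple[TranscriptModel, TruthRecord]] = []
    coding_designed: dict[str, str] = {}  # base id -> designed mRNA

    # ---- genome layout -------------------------------------------------
    n_lnc = cfg.n_lncrna
    n_lnc_chroms = max(1, math.ceil(n_lnc / cfg.lnc_blocks_per_chrom))
    chrom_lengths: dict[str, int] = {}
    for i in range(n_lnc_chroms):
        per = min(cfg.lnc_blocks_per_chrom, n_lnc - i * cfg.lnc_blocks_per_chrom)
        chrom_lengths[f"chr{i + 1}"] = per * cfg.lnc_block_nt + 1000
    coding_chrom = f"chr{n_lnc_chroms + 1}"
    chrom_lengths[coding_chrom] = cfg.n_coding * cfg.coding_block_nt + 1000
    small_chrom = f"chr{n_lnc_chroms + 2}"
    chrom_lengths[small_chrom] = cfg.n_small_rna * cfg.small_block_nt + 1000

    # ---- plant lncRNAs block by block ---------------------------------
    class_order = [c for c in DEFAULT_CLASS_COUNTS if cfg.class_counts.get(c, 0)]
    lnc_specs = [c for c in class_order for _ in range(cfg.class_counts[c])]
    host_idx = 0
    lnc_entries: list[tuple[TranscriptModel, str, str]] = []  # (t, class, strand)
    for k, lnc_class in enumerate(lnc_specs):
        chrom = f"chr{k // cfg.lnc_blocks_per_chrom + 1}"
        b = (k % cfg.lnc_blocks_per_chrom) * cfg.lnc_block_nt
        base = f"lnc{k:04d}"
        gene_strand = PLUS if rng.random() < 0.5 else MINUS
        need_gene = lnc_class != "intergenic_distal"
        if need_gene:
            gene = _host_gene(f"gene_h{host_idx:04d}", chrom, b, gene_strand)
            host_idx += 1
            genes.append(gene)
        if lnc_class == "intronic":
            length = _sample_length(rng, cfg.lnc_length_mean, cfg.lnc_length_sd, 300, 1400)
            strand = (
                UNKNOWN
                if rng.random() < 0.5
                else (PLUS if rng.random() < 0.5 else MINUS)
            )
            exons = _lnc_exons(chrom, b + 2600, length, strand, 1)
        elif lnc_class in ("exonic_sense", "exonic_antisense", "exonic_unknown"):
            length = _sample_length(rng, 1000, 150, 800, 1400)
            overlap = int(rng.integers(60, 91))
            start = b + 5600 + overlap - length
            if lnc_class == "exonic_sense":
                strand = gene_strand
            elif lnc_class == "exonic_antisense":
                strand = MINUS if gene_strand == PLUS else PLUS
            else:
                strand = UNKNOWN
            exons = _lnc_exons(chrom, start, length, strand, 1)
        elif lnc_class == "containing":
            strand = PLUS if rng.random() < 0.5 else MINUS
            exons = [
                GenomicInterval(chrom, b + 500, b + 900, strand),
                GenomicInterval(chrom, b + 10_600, b + 11_000, strand),
            ]
            length = 800
        else:  # intergenic classes
            length = _sample_length(rng, cfg.lnc_length_mean, cfg.lnc_length_sd, 300, 1400)
            n_ex = 2 if rng.random() < cfg.lnc_two_exon_fraction else 1
            if lnc_class == "intergenic_convergent":
                strand = gene_strand
            elif lnc_class == "intergenic_divergent":
                strand = MINUS if gene_strand == PLUS else PLUS
            elif lnc_class == "intergenic_unoriented":
                strand = UNKNOWN
            else:  # distal
                strand = PLUS if rng.random() < 0.5 else MINUS
            if lnc_class == "intergenic_distal":
                start = b + 24_000
            else:
                gap = int(rng.integers(1000, 3001))
                start = b + 10_000 + gap
            exons = _lnc_exons(chrom, start, length, strand, n_ex)
        t = TranscriptModel(base, exons)
        lnc_entries.append((t, lnc_class, strand))

    # ---- plant coding candidates --------------------------------------
    n_short_hit = cfg.n_coding_short_orf_with_hit
    n_score_only = cfg.n_coding_score_only
    coding_entries: list[tuple[TranscriptModel, str, int]] = []  # (t, group, aa)
    for i in range(cfg.n_coding):
        b = i * cfg.coding_block_nt
        base = f"cod{i:04d}"
        strand = PLUS if rng.random() < 0.5 else MINUS
        length = _sample_length(
            rng, cfg.coding_length_mean, cfg.coding_length_sd, 600, 3000
        )
        n_ex = int(rng.integers(2, 7))
        # exons laid left to right from b+1000 with 300-800 nt introns
        sizes = np.full(n_ex, length // n_ex)
        sizes[: length % n_ex] += 1
        exons = []
        pos = b + 1000
        for s in sizes:
            exons.append(GenomicInterval(coding_chrom, pos, pos + int(s), strand))
            pos += int(s) + int(rng.integers(300, 801))
        t = TranscriptModel(base, exons)
        if i < cfg.n_coding - n_short_hit - n_score_only:
            group = "long_orf"
            aa = int(rng.integers(120, min(301, (length - 33) // 3 - 1)))
        elif i < cfg.n_coding - n_score_only:
            group = "short_orf_hit"
            aa = int(rng.integers(40, 71))
        else:
            group = "score_only"
            aa = int(rng.integers(40, 71))
        coding_entries.append((t, group, aa))
        gene = GeneModel(f"gene_{base}", [TranscriptModel(f"gene_{base}.t1", t.exons)])
        genes.append(gene)

    # ---- plant small / structural RNAs --------------------------------
    small_entries: list[tuple[TranscriptModel, bool]] = []  # (t, is_rrna_like)
    for i in range(cfg.n_small_rna):
        b = i * cfg.small_block_nt
        base = f"sml{i:04d}"
        strand = PLUS if rng.random() < 0.5 else MINUS
        rrna_like = i >= cfg.n_small_rna - cfg.n_rrna_like
        length = (
            int(rng.integers(400, 1201)) if rrna_like else int(rng.integers(70, 181))
        )
        exons = [GenomicInterval(small_chrom, b + 500, b + 500 + length, strand)]
        small_entries.append((TranscriptModel(base, exons), rrna_like))

    # ---- write sequences into the genome ------------------------------
    stamper = _Stamper(rng, chrom_lengths)
    for t, _group, aa in coding_entries:
        designed = _coding_mrna(rng, t.length, aa)
        coding_designed[t.id] = designed
        stamper.stamp_transcript(t, designed)
    for gene in genes:
        if gene.id.startswith("gene_h"):
            gt = gene.transcripts[0]
            stamper.stamp_transcript(gt, _coding_mrna(rng, gt.length, 300))
    for t, _cls, _strand in lnc_entries:
        stamper.fill_noncoding(t)
    for t, _rrna in small_entries:
        stamper.fill_noncoding(t)

    # validate planted lncRNA ORFs; retry filler on the rare violation
    for t, lnc_class, _strand in lnc_entries:
        for attempt in range(10):
            seq = stamper.sequence_of(t)
            orf = find_longest_orf(seq, frames=6)
            if orf.aa_length <= 60 and orf.fraction <= 0.25:
                break
            stamper.fill_noncoding(t)
        else:
            raise RuntimeError(
                f"could not plant ORF-free sequence for {t.id} ({lnc_class})"
            )

    genome = stamper.genome()

    # ---- dataset emission ---------------------------------------------
    unstranded = [d for d in cfg.dataset_names if d != cfg.stranded_dataset]
    datasets: dict[str, list[TranscriptModel]] = {d: [] for d in cfg.dataset_names}

    def emit(t: TranscriptModel, ds_names: Sequence[str]) -> list[str]:
        out = []
        for ds in ds_names:
            strand = t.strand if ds == cfg.stranded_dataset else UNKNOWN
            exons = [
                GenomicInterval(e.chrom, e.start, e.end, strand) for e in t.exons
            ]
            copy = TranscriptModel(f"{t.id}|{ds}", exons, source_dataset=ds)
            copy.sequence = stamper.sequence_of(copy)
            datasets[ds].append(copy)
            out.append(copy.id)
        return out

    n_single = int(round(cfg.lnc_single_dataset_fraction * len(lnc_entries)))
    single_ids = {t.id for t, _c, _s in lnc_entries[:n_single]}

    protein_hits: list[HomologyHit] = []
    ncrna_hits: list[HomologyHit] = []
    lncdb_hits: list[HomologyHit] = []
    scores: list[tuple[str, float]] = []

    def _hit(q: str, s: str, ev: float, qlen: int) -> HomologyHit:
        alen = max(30, qlen // 3)
        return HomologyHit(
            query_id=q,
            subject_id=s,
            percent_identity=float(np.round(rng.uniform(70, 99), 2)),
            alignment_length=alen,
            mismatches=int(rng.integers(0, 20)),
            gap_opens=int(rng.integers(0, 4)),
            query_start=1,
            query_end=alen,
            subject_start=1,
            subject_end=alen,
            evalue=ev,
            bit_score=float(np.round(rng.uniform(50, 500), 1)),
        )

    lnc_ids_sorted = [t.id for t, _c, _s in lnc_entries]
    conserved_ids = set(lnc_ids_sorted[-cfg.n_conserved :]) if cfg.n_conserved else set()
    missing_score_ids = (
        set(lnc_ids_sorted[: cfg.n_missing_score]) if cfg.n_missing_score else set()
    )
    decoy_ids = (
        set(lnc_ids_sorted[cfg.n_missing_score : cfg.n_missing_score + cfg.n_decoy_protein_hits])
        if cfg.n_decoy_protein_hits
        else set()
    )

    for t, lnc_class, strand in lnc_entries:
        must_strand = lnc_class in (
            "exonic_sense",
            "exonic_antisense",
            "intergenic_convergent",
            "intergenic_divergent",
        ) or (strand != UNKNOWN and rng.random() < 0.5)
        never_strand = strand == UNKNOWN
        if t.id in single_ids:
            pool = unstranded if never_strand else list(cfg.dataset_names)
            ds_names = [pool[int(rng.integers(0, len(pool)))]]
        elif never_strand:
            n_ds = int(rng.integers(2, len(unstranded) + 1))
            ds_names = sorted(
                rng.choice(unstranded, size=n_ds, replace=False).tolist()
            )
        elif must_strand:
            n_extra = int(rng.integers(1, 3))
            extras = sorted(rng.choice(unstranded, size=n_extra, replace=False).tolist())
            ds_names = extras + [cfg.stranded_dataset]
        else:
            n_ds = int(rng.integers(2, 4))
            ds_names = sorted(rng.choice(unstranded, size=n_ds, replace=False).tolist())
        copy_ids = emit(t, ds_names)
        score = None
        if t.id not in missing_score_ids:
            score = float(np.round(rng.uniform(-4.0, -2.0), 3))
            for cid in copy_ids:
                scores.append((cid, score))
        if t.id in decoy_ids:
            for cid in copy_ids:
                protein_hits.append(
                    _hit(cid, f"nr|weak{t.id}", 10.0 ** -rng.uniform(2.0, 2.9), t.length)
                )
        if t.id in conserved_ids:
            for cid in copy_ids:
                lncdb_hits.append(
                    _hit(cid, f"lncdb|known_{t.id}", 10.0 ** -rng.uniform(5, 20), t.length)
                )
        truth.add(
            TruthRecord(
                id=t.id,
                role=ROLE_LNCRNA,
                lnc_class=lnc_class,
                strand=strand,
                datasets=tuple(ds_names),
                orf_aa=0,
                coding_score=score,
                has_protein_hit=t.id in decoy_ids,
                has_ncrna_hit=False,
                conserved=t.id in conserved_ids,
                expression_pattern=None,  # assigned below
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                n_exons=t.n_exons,
                length=t.length,
                consensus_expected=len(ds_names) >= 2,
                stringent_kept=lnc_class != "exonic_sense",
            )
        )

    for t, group, aa in coding_entries:
        n_ds = int(rng.integers(1, 3))
        ds_names = sorted(rng.choice(cfg.dataset_names, size=n_ds, replace=False).tolist())
        copy_ids = emit(t, ds_names)
        if group == "score_only":
            score = float(np.round(rng.uniform(-0.45, -0.15), 3))
        else:
            score = float(np.round(rng.uniform(0.2, 2.5), 3))
        for cid in copy_ids:
            scores.append((cid, score))
        has_hit = group in ("long_orf", "short_orf_hit")
        if has_hit:
            for cid in copy_ids:
                protein_hits.append(
                    _hit(cid, f"nr|prot_{t.id}", 10.0 ** -rng.uniform(10, 50), t.length)
                )
        truth.add(
            TruthRecord(
                id=t.id,
                role=ROLE_CODING,
                lnc_class=None,
                strand=t.strand,
                datasets=tuple(ds_names),
                orf_aa=aa,
                coding_score=score,
                has_protein_hit=has_hit,
                has_ncrna_hit=False,
                conserved=False,
                expression_pattern=None,
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                n_exons=t.n_exons,
                length=t.length,
                consensus_expected=False,
                stringent_kept=False,
            )
        )

    ncrna_dbs = ("tRNA", "miRNA", "LSU", "SSU")
    for j, (t, rrna_like) in enumerate(small_entries):
        n_ds = int(rng.integers(1, 3))
        ds_names = sorted(rng.choice(cfg.dataset_names, size=n_ds, replace=False).tolist())
        copy_ids = emit(t, ds_names)
        db = "LSU" if rrna_like else ncrna_dbs[j % len(ncrna_dbs)]
        for cid in copy_ids:
            ncrna_hits.append(
                _hit(cid, f"{db}|ref_{t.id}", 10.0 ** -rng.uniform(6, 30), t.length)
            )
            scores.append((cid, float(np.round(rng.uniform(-3.0, -1.5), 3))))
        truth.add(
            TruthRecord(
                id=t.id,
                role=ROLE_SMALL,
                lnc_class=None,
                strand=t.strand,
                datasets=tuple(ds_names),
                orf_aa=0,
                coding_score=None,
                has_protein_hit=False,
                has_ncrna_hit=True,
                conserved=False,
                expression_pattern=None,
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                n_exons=t.n_exons,
                length=t.length,
                consensus_expected=False,
                stringent_kept=False,
            )
        )

    # ---- expression counts --------------------------------------------
    consensus_lnc = [
        t.id for t, _c, _s in lnc_entries if truth.records[t.id].consensus_expected
    ]
    coding_ids = [t.id for t, _g, _a in coding_entries]
    lengths = {}
    for t, _c, _s in lnc_entries:
        lengths[t.id] = t.length
    for t, _g, _a in coding_entries:
        lengths[t.id] = t.length

    n_spec = min(cfg.n_tissue_specific, len(consensus_lnc))
    n_ubiq = min(cfg.n_ubiquitous, max(0, len(consensus_lnc) - n_spec))
    spec_ids = consensus_lnc[:n_spec]
    ubiq_ids = consensus_lnc[n_spec : n_spec + n_ubiq]
    cluster_lnc = consensus_lnc[
        n_spec + n_ubiq : n_spec + n_ubiq + cfg.n_cluster_blocks * cfg.cluster_block_lnc
    ]
    cluster_cod = coding_ids[: cfg.n_cluster_blocks * cfg.cluster_block_coding]

    patterns: dict[str, str] = {}
    for i, tid in enumerate(spec_ids):
        patterns[tid] = f"specific:{cfg.tissues[i % len(cfg.tissues)]}"
    for tid in ubiq_ids:
        patterns[tid] = "ubiquitous"
    for k in range(cfg.n_cluster_blocks):
        for tid in cluster_lnc[k * cfg.cluster_block_lnc : (k + 1) * cfg.cluster_block_lnc]:
            patterns[tid] = f"cluster:{k}"
        for tid in cluster_cod[
            k * cfg.cluster_block_coding : (k + 1) * cfg.cluster_block_coding
        ]:
            patterns[tid] = f"cluster:{k}"

    cluster_shapes = {}
    tissue_arr = np.array(cfg.tissues)
    for k in range(cfg.n_cluster_blocks):
        peaks = rng.choice(len(tissue_arr), size=cfg.cluster_peak_tissues, replace=False)
        shape = np.full(len(tissue_arr), 0.05)
        shape[peaks] = 1.0
        cluster_shapes[k] = shape

    row_ids = list(consensus_lnc) + coding_ids
    count_rows = {}
    for tid in row_ids:
        pattern = patterns.get(tid, "background")
        rec = truth.records[tid]
        target = plant_expression_pattern(
            pattern,
            length=lengths[tid],
            config=cfg,
            rng=rng,
            cluster_shapes=cluster_shapes,
            is_coding=rec.role == ROLE_CODING,
        )
        count_rows[tid] = target
        rec.expression_pattern = pattern

    counts_df = pd.DataFrame.from_dict(
        count_rows, orient="index", columns=list(cfg.tissues)
    ).astype(int)
    counts_df = counts_df.sort_index()
    counts = CountMatrix(
        counts=counts_df,
        lengths=pd.Series({t: lengths[t] for t in counts_df.index}, name="length"),
        totals=pd.Series(
            {t: cfg.library_size for t in cfg.tissues}, name="total", dtype=float
        ),
    )

    return SyntheticData(
        config=cfg,
        genome=genome,
        coding_genes=sorted(genes, key=lambda g: g.id),
        datasets={d: sorted(ts, key=lambda t: t.id) for d, ts in datasets.items()},
        stranded_datasets={cfg.stranded_dataset},
        cascade_inputs=CascadeInputs(
            protein_hits=protein_hits,
            ncrna_hits=ncrna_hits,
            scores=CodingScoreTable(scores),
            lncrna_db_hits=lncdb_hits,
        ),
        counts=counts,
        truth=truth,
    )


def plant_expression_pattern(
    pattern: str,
    length: int,
    config: SynthConfig,
    rng: np.random.Generator,
    cluster_shapes: dict[int, np.ndarray] | None = None,
    is_coding: bool = False,
) -> np.ndarray:
    """Counts for one transcript under a planted expression pattern.

    Expected RPKM profiles: ``specific:<tissue>`` puts ``specific_rpkm``
    in the target tissue and ``background_rpkm`` elsewhere (clearing the
    8-fold rule with ~2x margin); ``ubiquitous`` draws every tissue from
    ``ubiquitous_rpkm_range`` (well above the 1.0 floor); ``cluster:<k>``
    scales a shared per-block shape; ``background`` is a low lognormal.
    Counts are negative-binomial around the expected values, or exact
    rounded means when ``nb_dispersion`` is None.
    """
    tissues = config.tissues
    n = len(tissues)
    if pattern.startswith("specific:"):
        target = pattern.split(":", 1)[1]
        rpkm = np.full(n, config.background_rpkm)
        rpkm[list(tissues).index(target)] = config.specific_rpkm
    elif pattern == "ubiquitous":
        lo, hi = config.ubiquitous_rpkm_range
        rpkm = rng.uniform(lo, hi, n)
    elif pattern.startswith("cluster:"):
        k = int(pattern.split(":", 1)[1])
        if cluster_shapes is None:
            raise ValueError("cluster pattern needs cluster_shapes")
        amp = rng.uniform(*config.cluster_amplitude_range)
        rpkm = amp * cluster_shapes[k]
    else:  # background
        scale = 12.0 if is_coding else 1.5
        rpkm = np.minimum(rng.lognormal(math.log(scale), 1.0, n), 200.0)
    mu = rpkm * (length / 1e3) * (config.library_size / 1e6)
    if config.nb_dispersion is None:
        return np.round(mu).astype(int)
    size = config.nb_dispersion
    if pattern.startswith("cluster:"):
        size = config.cluster_nb_dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(int)
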