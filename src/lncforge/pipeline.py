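"""End-to-end orchestration: per-dataset filter cascade, cross-dataset
consensus, strand rescue, redundancy removal, stringent positional
filters, genomic-context classification and the expression atlas, with a
machine-readable run report whose per-stage counts always satisfy
conservation (n_in = n_removed + n_out)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import atlas as atlas_mod
from .atlas import CountMatrix, ClusterSet, ExpressionMatrix
from .consensus import (
    DatasetCollection,
    MatchEdge,
    assign_strand,
    build_match_graph,
    consensus_filter,
    deduplicate,
    merge_redundant,
)
from .context import (
    ClassificationResult,
    GeneIndex,
    classify_all,
    filter_sense_overlap,
    filter_single_exon_proximity,
    summarize_classes,
)
from .filters import (
    CascadeInputs,
    FilterConfig,
    StageReport,
    annotate_known_lncrnas,
    run_cascade,
)
from .model import GeneModel, TranscriptModel, UNKNOWN

logger = logging.getLogger(__name__)

MODES = ("traditional", "stringent")


def base_id(transcript_id: str) -> str:
    """Strip the dataset suffix a copy id carries (``lnc0001|polya_pe`` ->
    ``lnc0001``)."""
    return transcript_id.split("|", 1)[0]


@dataclass
class PipelineConfig:
    mode: str = "traditional"
    min_support: int = 2
    match_min_identity: float = 95.0
    match_min_overlap_nt: int = 1
    dedup_max_overlap_nt: int = 100
    strand_min_identity: float = 95.0
    classification_window: int = 15_000
    single_exon_max_gap: int = 500
    specific_fold: float = 8.0
    specific_min_rpkm: float = 0.5
    ubiquitous_min_rpkm: float = 1.0
    cluster_min_corr: float = 0.97
    cluster_retain_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def filter_config(self) -> FilterConfig:
        return (
            FilterConfig.stringent()
            if self.mode == "stringent"
            else FilterConfig.traditional()
        )


@dataclass
class PipelineInputs:
    """Everything one run consumes."""

    datasets: Mapping[str, Sequence[TranscriptModel]]
    stranded_datasets: set[str]
    cascade_inputs: CascadeInputs
    coding_genes: Sequence[GeneModel] = ()
    counts: CountMatrix | None = None


@dataclass
class AtlasResult:
    rpkm: ExpressionMatrix
    normalized: ExpressionMatrix
    tissue_specific: pd.Series
    ubiquitous: pd.Series
    clusters: ClusterSet


@dataclass
class PipelineResult:
    config: PipelineConfig
    lncrnas: list[TranscriptModel]
    per_dataset_reports: dict[str, StageReport]
    conserved: dict[str, set[str]]
    edges: list[MatchEdge]
    classifications: list[ClassificationResult]
    class_summary: dict[str, int]
    atlas: AtlasResult | None
    report: dict = field(default_factory=dict)

    @property
    def recovered_base_ids(self) -> set[str]:
        return {base_id(t.id) for t in self.lncrnas}

    def write_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)


def run_all(inputs: PipelineInputs, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole discovery pipeline and audit count conservation."""
    config = config or PipelineConfig()
    fcfg = config.filter_config

    # 1. per-dataset filtration cascade
    kept_by_ds: dict[str, list[TranscriptModel]] = {}
    reports: dict[str, StageReport] = {}
    for ds in sorted(inputs.datasets):
        kept, report = run_cascade(
            inputs.datasets[ds], inputs.cascade_inputs, fcfg
        )
        kept_by_ds[ds] = kept
        reports[ds] = report

    # annotation only: similarity to previously characterized lncRNAs
    all_kept = [t for ds in sorted(kept_by_ds) for t in kept_by_ds[ds]]
    conserved = annotate_known_lncrnas(
        all_kept, inputs.cascade_inputs.lncrna_db_hits, fcfg.homology_evalue
    )

    # 2. cross-dataset consensus (>= min_support datasets)
    collection = DatasetCollection(
        datasets=kept_by_ds,
        stranded=set(inputs.stranded_datasets) & set(kept_by_ds),
    )
    edges = build_match_graph(
        collection,
        min_identity=config.match_min_identity,
        min_overlap_nt=config.match_min_overlap_nt,
    )
    supported = consensus_filter(collection, edges, min_support=config.min_support)
    n_union = len(all_kept)

    # 3. strand rescue from the stranded dataset(s)
    stranded_pool = [
        t
        for t in supported
        if t.source_dataset in inputs.stranded_datasets and t.strand != UNKNOWN
    ]
    supported = assign_strand(
        supported, stranded_pool, min_identity=config.strand_min_identity
    )

    # 4. redundancy removal: one representative per co-detection component
    merged = merge_redundant(supported, edges)
    counts_flow = {
        "union_after_cascade": n_union,
        "consensus_supported": len(supported),
        "non_redundant": len(merged),
    }

    # 5. stringent positional extras
    gene_index = GeneIndex(inputs.coding_genes)
    current = merged
    if config.mode == "stringent":
        current = deduplicate(current, max_overlap_nt=config.dedup_max_overlap_nt)
        counts_flow["after_overlap_dedup"] = len(current)
        current, removed_sense = filter_sense_overlap(current, gene_index)
        counts_flow["sense_overlap_removed"] = len(removed_sense)
        current, removed_prox = filter_single_exon_proximity(
            current, gene_index, max_gap=config.single_exon_max_gap
        )
        counts_flow["single_exon_proximity_removed"] = len(removed_prox)
    final = sorted(current, key=lambda t: (t.chrom, t.start, t.id))
    counts_flow["final_lncrnas"] = len(final)

    # 6. genomic-context classification
    classifications = classify_all(final, gene_index, config.classification_window)
    class_summary = summarize_classes(classifications)

    # 7. expression atlas over the surviving lncRNAs (+ coding genes for
    #    co-expression clustering)
    atlas_result = None
    if inputs.counts is not None:
        final_bases = sorted({base_id(t.id) for t in final})
        coding_rows = [
            i for i in inputs.counts.counts.index if i not in set(final_bases)
        ]
        cm = inputs.counts.subset(final_bases + coding_rows)
        em = atlas_mod.rpkm(cm)
        norm = atlas_mod.normalize_mean_scaling(em)
        lnc_em = ExpressionMatrix(
            em.values.loc[[i for i in em.values.index if i in set(final_bases)]],
            source=cm,
        )
        specific = atlas_mod.call_tissue_specific(
            lnc_em, fold=config.specific_fold, min_rpkm=config.specific_min_rpkm
        )
        ubiquitous = atlas_mod.call_ubiquitous(
            lnc_em, min_rpkm=config.ubiquitous_min_rpkm
        )
        clusters = atlas_mod.cluster_correlated(
            norm,
            min_corr=config.cluster_min_corr,
            retain_fraction=config.cluster_retain_fraction,
            coding_ids=set(coding_rows),
        )
        atlas_result = AtlasResult(
            rpkm=em,
            normalized=norm,
            tissue_specific=specific,
            ubiquitous=ubiquitous,
            clusters=clusters,
        )

    report = {
        "mode": config.mode,
        "per_dataset_stages": {ds: reports[ds].to_dict() for ds in sorted(reports)},
        "consensus": counts_flow,
        "conserved_lncrnas": len({base_id(i) for i in conserved}),
        "class_summary": class_summary,
    }
    if atlas_result is not None:
        report["atlas"] = {
            "tissue_specific": int(atlas_result.tissue_specific.notna().sum()),
            "ubiquitous": int(atlas_result.ubiquitous.sum()),
            "clusters": len(atlas_result.clusters.clusters),
            "coexpression_clusters": sum(
                c.is_coexpression for c in atlas_result.clusters.clusters
            ),
        }

    result = PipelineResult(
        config=config,
        lncrnas=final,
        per_dataset_reports=reports,
        conserved=conserved,
        edges=edges,
        classifications=classifications,
        class_summary=class_summary,
        atlas=atlas_result,
        report=report,
    )
    _audit_conservation(result)
    return result


def _audit_conservation(result: PipelineResult) -> None:
    for ds, report in result.per_dataset_reports.items():
        report.validate()
        if report.n_input - report.total_removed != report.n_output:
            raise AssertionError(f"end-to-end conservation broken for {ds}")
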