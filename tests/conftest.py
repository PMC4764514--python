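from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lncforge.model import GenomicInterval, TranscriptModel
from lncforge.pipeline import PipelineConfig, PipelineInputs, run_all
from lncforge.synthetic import SynthConfig, SyntheticData, generate

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_transcript(
    tid: str,
    chrom: str = "chr1",
    exons: list[tuple[int, int]] | None = None,
    strand: str = ".",
    sequence: str | None = None,
    dataset: str = "",
) -> TranscriptModel:
    exons = exons or [(0, 300)]
    ivals = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return TranscriptModel(tid, ivals, source_dataset=dataset, sequence=sequence)


def tiny_synth_config(seed: int = 42, **overrides) -> SynthConfig:
    """A small, fast fixture with every role and class represented."""
    params = dict(
        seed=seed,
        n_coding=12,
        n_coding_short_orf_with_hit=4,
        n_coding_score_only=2,
        n_small_rna=6,
        n_rrna_like=2,
        class_counts={
            "intronic": 2,
            "exonic_sense": 2,
            "exonic_antisense": 2,
            "exonic_unknown": 2,
            "containing": 2,
            "intergenic_convergent": 2,
            "intergenic_divergent": 2,
            "intergenic_unoriented": 2,
            "intergenic_distal": 2,
        },
        n_conserved=4,
        n_missing_score=2,
        n_decoy_protein_hits=2,
        n_tissue_specific=4,
        n_ubiquitous=4,
        n_cluster_blocks=1,
    )
    params.update(overrides)
    return SynthConfig(**params)


def pipeline_inputs(data: SyntheticData) -> PipelineInputs:
    return PipelineInputs(
        datasets=data.datasets,
        stranded_datasets=data.stranded_datasets,
        cascade_inputs=data.cascade_inputs,
        coding_genes=data.coding_genes,
        counts=data.counts,
    )


@pytest.fixture(scope="session")
def default_data() -> SyntheticData:
    """The reference fixture: ~600 planted transcripts (200 coding,
    100 small-RNA, 300 lncRNAs across every genomic-context class)."""
    return generate(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def traditional_run(default_data):
    return run_all(pipeline_inputs(default_data), PipelineConfig(mode="traditional"))


@pytest.fixture(scope="session")
def stringent_run(default_data):
    return run_all(pipeline_inputs(default_data), PipelineConfig(mode="stringent"))


@pytest.fixture(scope="session")
def tiny_data() -> SyntheticData:
    return generate(tiny_synth_config(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
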