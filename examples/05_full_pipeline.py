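"""End-to-end run on the reference synthetic fixture with planted truth.

Generates ~600 transcripts (200 coding, 100 small-RNA, 300 lncRNA across
all genomic-context classes), runs the whole pipeline in both stringency
regimes and scores recovery against the planted truth.
"""

from lncforge.pipeline import PipelineConfig, PipelineInputs, run_all
from lncforge.synthetic import SynthConfig, generate

data = generate(SynthConfig(seed=42))
inputs = PipelineInputs(
    datasets=data.datasets,
    stranded_datasets=data.stranded_datasets,
    cascade_inputs=data.cascade_inputs,
    coding_genes=data.coding_genes,
    counts=data.counts,
)

for mode in ("traditional", "stringent"):
    result = run_all(inputs, PipelineConfig(mode=mode))
    expected = (
        data.truth.expected_traditional_ids()
        if mode == "traditional"
        else data.truth.expected_stringent_ids()
    )
    got = result.recovered_base_ids
    tp = len(expected & got)
    print(f"{mode}: {len(got)} lncRNAs recovered; "
          f"precision={tp / len(got):.3f} recall={tp / len(expected):.3f}")
print("At zero planting noise the cascade + consensus + positional filters")
print("recover exactly the planted lncRNAs; the stringent list is a subset.")
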