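"""Tissue expression atlas over 13 tissues.

Computes RPKM from raw counts, calls tissue-specific (>= 8-fold over all
other tissues, >= 0.5 RPKM) and ubiquitous (>= 1.0 RPKM everywhere)
lncRNAs, ranks profiles by Shannon entropy and clusters co-expressed
lncRNA/mRNA profiles at Pearson r >= 0.97.
"""

import math

from lncforge.atlas import (
    ExpressionMatrix,
    call_tissue_specific,
    call_ubiquitous,
    cluster_correlated,
    complexity_curve,
    expression_entropy,
    normalize_mean_scaling,
    rpkm,
)
from lncforge.synthetic import SynthConfig, generate

data = generate(SynthConfig(seed=42))
em = rpkm(data.counts)

lnc_rows = [i for i in em.values.index if data.truth.records[i].role == "lncrna"]
lnc_em = ExpressionMatrix(em.values.loc[lnc_rows])
specific = call_tissue_specific(lnc_em)
ubiquitous = call_ubiquitous(lnc_em)

print(f"lncRNAs quantified:    {len(lnc_rows)} x {len(em.tissues)} tissues")
print(f"tissue-specific calls: {int(specific.notna().sum())}")
print(f"ubiquitous calls:      {int(ubiquitous.sum())}")
print(f"uniform-profile entropy bound: {expression_entropy([1.0] * 13):.4f} bits "
      f"(= log2 13 = {math.log2(13):.4f})")

curve = complexity_curve(lnc_em, "brain")
print(f"brain complexity: top 10 lncRNAs contribute {curve[9]:.1%} of expression")

coding = {t for t, r in data.truth.records.items() if r.role == "coding"}
clusters = cluster_correlated(normalize_mean_scaling(em), coding_ids=coding)
co = [c for c in clusters.clusters if c.is_coexpression]
print(f"clusters at r>=0.97:   {len(clusters.clusters)} ({len(co)} mixing lncRNA+mRNA)")
print("Tissue-restricted lncRNAs are candidate tissue regulators; clusters")
print("with mRNAs suggest shared regulation worth following up.")
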