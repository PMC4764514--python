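"""Tissue expression atlas: RPKM quantification, tissue-specificity and
housekeeping calls, transcriptome-complexity curves, and entropy-ranked
correlation clustering.

RPKM = count / ((length/1e3) * (total mapped reads/1e6)).  A transcript
is *tissue-specific* when its expression in one tissue is at least
``fold`` (default 8) times the maximum over all other tissues and at
least ``min_rpkm`` (default 0.5); it is *ubiquitous* (housekeeping-like)
when every tissue reaches ``min_rpkm`` (default 1.0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import entropy as _scipy_entropy

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw read counts (transcripts x tissues) with library sizes and
    transcript lengths."""

    counts: pd.DataFrame  # integer counts, index=transcripts, columns=tissues
    lengths: pd.Series  # nt per transcript
    totals: pd.Series  # total mapped reads per tissue

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ValueError(f"lengths missing for {len(missing)} transcripts")
        missing_t = set(self.counts.columns) - set(self.totals.index)
        if missing_t:
            raise ValueError(f"totals missing for tissues {sorted(missing_t)}")
        self.lengths = self.lengths.reindex(self.counts.index)
        self.totals = self.totals.reindex(self.counts.columns)
        colsums = self.counts.sum(axis=0)
        if (self.totals < colsums).any():
            raise ValueError("library totals smaller than column sums")

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, transcript_ids: Sequence[str]) -> "CountMatrix":
        ids = [t for t in transcript_ids if t in self.counts.index]
        return CountMatrix(
            self.counts.loc[ids].copy(), self.lengths.loc[ids].copy(), self.totals
        )

    @classmethod
    def from_tsv(cls, counts_path, lengths_path, totals_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        totals = pd.read_csv(totals_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, lengths, totals)


@dataclass
class ExpressionMatrix:
    """RPKM values with provenance to the source counts."""

    values: pd.DataFrame
    source: CountMatrix | None = None
    normalized: bool = False

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads Per Kilobase of transcript per Million mapped reads."""
    if (cm.totals <= 0).any():
        raise ValueError("zero or negative library total")
    if (cm.lengths <= 0).any():
        raise ValueError("zero or negative transcript length")
    kb = cm.lengths / 1e3
    millions = cm.totals / 1e6
    values = cm.counts.div(kb, axis=0).div(millions, axis=1)
    return ExpressionMatrix(values, source=cm, normalized=False)


def normalize_mean_scaling(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scaling normalization with the mean as normalization value: each
    tissue column is scaled so all column means equal the global mean of
    column means.  All-zero columns are left unscaled with a warning."""
    col_means = em.values.mean(axis=0)
    usable = col_means[col_means > 0]
    if usable.empty:
        logger.warning("all columns have zero mean; normalization is a no-op")
        return ExpressionMatrix(em.values.copy(), em.source, normalized=True)
    target = usable.mean()
    factors = pd.Series(1.0, index=em.values.columns)
    factors[usable.index] = target / usable
    zero_cols = col_means.index[col_means == 0]
    if len(zero_cols):
        logger.warning("columns %s have zero mean; left unscaled", list(zero_cols))
    return ExpressionMatrix(em.values * factors, em.source, normalized=True)


def call_tissue_specific(
    em: ExpressionMatrix, fold: float = 8.0, min_rpkm: float = 0.5
) -> pd.Series:
    """Per-transcript tissue-specificity call.

    Returns a Series mapping transcript -> tissue name, or None when not
    specific.  Specific to tissue t iff x_t >= fold * max over the other
    tissues (inclusive) and x_t >= min_rpkm.  For fold > 1 at most one
    tissue can qualify.
    """
    if em.values.shape[1] < 2:
        raise ValueError("need at least two tissues")
    vals = em.values.to_numpy(dtype=float)
    tissues = np.asarray(em.values.columns)
    order = np.argsort(-vals, axis=1, kind="stable")
    top = vals[np.arange(len(vals)), order[:, 0]]
    second = vals[np.arange(len(vals)), order[:, 1]]
    ok = (top >= fold * second) & (top >= min_rpkm)
    out = pd.Series([None] * len(vals), index=em.values.index, dtype=object)
    out[ok] = tissues[order[:, 0]][ok]
    # all-equal nonzero profiles: top == second fails fold>1 automatically
    return out


def call_ubiquitous(em: ExpressionMatrix, min_rpkm: float = 1.0) -> pd.Series:
    """Boolean Series: expressed at >= min_rpkm in every tissue."""
    return em.values.min(axis=1) >= min_rpkm


def complexity_curve(em: ExpressionMatrix, tissue: str) -> np.ndarray:
    """Cumulative fraction of a tissue's expression contributed by its
    most abundant transcripts (descending), ending exactly at 1.0."""
    col = em.values[tissue].to_numpy(dtype=float)
    total = col.sum()
    if total <= 0:
        raise ValueError(f"tissue {tissue} has no expression")
    ordered = np.sort(col)[::-1]
    curve = np.cumsum(ordered) / total
    curve[-1] = 1.0  # guard against float drift at the terminus
    return curve


def expression_entropy(profile: Sequence[float], base: float = 2.0) -> float:
    """Shannon entropy of the tissue-share distribution p_i = x_i / sum x;
    0 * log 0 = 0.  Uniform profiles reach log_base(n_tissues)."""
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression values")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero profile")
    return float(_scipy_entropy(x / total, base=base))


@dataclass
class Cluster:
    members: list[str]
    entropies: dict[str, float]
    retained: list[str]
    mean_pairwise_correlation: float
    is_coexpression: bool = False


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    n_zero_variance_excluded: int = 0


def cluster_correlated(
    em: ExpressionMatrix,
    min_corr: float = 0.97,
    retain_fraction: float = 0.20,
    coding_ids: set[str] | None = None,
) -> ClusterSet:
    """Average-linkage agglomerative clustering on Pearson correlation
    distance (1 - r), cut at distance 1 - min_corr so each cluster's mean
    pairwise correlation is at least *min_corr*.

    Zero-variance profiles are excluded (correlation undefined) with a
    logged count.  Within each cluster members are ranked by expression
    entropy (descending) and the top ceil(retain_fraction * size) are
    retained.  Clusters mixing *coding_ids* with other ids are flagged as
    co-expression clusters.
    """
    if em.values.shape[1] < 2:
        raise ValueError("need at least two tissues")
    vals = em.values.to_numpy(dtype=float)
    variances = vals.var(axis=1)
    usable = variances > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluding %d zero-variance profiles from clustering", n_excluded)
    ids = list(em.values.index[usable])
    if len(ids) < 2:
        return ClusterSet(clusters=[], n_zero_variance_excluded=n_excluded)
    sub = vals[usable]
    corr = np.corrcoef(sub)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=1.0 - min_corr, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    clusters: list[Cluster] = []
    for lab in sorted(groups):
        idxs = groups[lab]
        if len(idxs) < 2:
            continue
        members = sorted(ids[i] for i in idxs)
        ent = {m: expression_entropy(em.values.loc[m]) for m in members}
        n_keep = math.ceil(retain_fraction * len(members))
        retained = sorted(ent, key=lambda m: (-ent[m], m))[:n_keep]
        block = corr[np.ix_(idxs, idxs)]
        iu = np.triu_indices(len(idxs), k=1)
        mean_r = float(block[iu].mean())
        is_co = False
        if coding_ids is not None:
            member_set = set(members)
            is_co = bool(member_set & coding_ids) and bool(member_set - coding_ids)
        clusters.append(
            Cluster(
                members=members,
                entropies=ent,
                retained=sorted(retained),
                mean_pairwise_correlation=mean_r,
                is_coexpression=is_co,
            )
        )
    clusters.sort(key=lambda c: c.members[0])
    return ClusterSet(clusters=clusters, n_zero_variance_excluded=n_excluded)
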