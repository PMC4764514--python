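"""Expression atlas: RPKM, normalization, specificity calls, complexity
curves, entropy and correlation clustering."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncforge.atlas import (
    CountMatrix,
    ExpressionMatrix,
    call_tissue_specific,
    call_ubiquitous,
    cluster_correlated,
    complexity_curve,
    expression_entropy,
    normalize_mean_scaling,
    rpkm,
)


def _cm(counts: dict, lengths: dict, totals: dict) -> CountMatrix:
    return CountMatrix(
        counts=pd.DataFrame(counts).T,
        lengths=pd.Series(lengths),
        totals=pd.Series(totals, dtype=float),
    )


def _em(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows).T.astype(float))


class TestRpkm:
    def test_unit_case(self):
        cm = _cm({"t": {"a": 1000}}, {"t": 1000}, {"a": 1_000_000})
        assert rpkm(cm).values.loc["t", "a"] == pytest.approx(1000.0)

    def test_zero_count_gives_zero(self):
        cm = _cm({"t": {"a": 0}}, {"t": 500}, {"a": 1_000_000})
        assert rpkm(cm).values.loc["t", "a"] == 0.0

    def test_direct_evaluation(self):
        cm = _cm({"t": {"a": 250}}, {"t": 500}, {"a": 50_000_000})
        assert rpkm(cm).values.loc["t", "a"] == pytest.approx(10.0)

    def test_linearity_and_joint_scaling_invariance(self, rng):
        counts = rng.integers(0, 500, size=(20, 4))
        lengths = rng.integers(200, 3000, 20)
        totals = rng.integers(10**6, 10**7, 4)
        ids = [f"t{i}" for i in range(20)]
        tissues = [f"ts{j}" for j in range(4)]
        cm = CountMatrix(
            pd.DataFrame(counts, index=ids, columns=tissues),
            pd.Series(lengths, index=ids),
            pd.Series(totals, index=tissues, dtype=float),
        )
        base = rpkm(cm).values
        doubled = CountMatrix(
            pd.DataFrame(counts * 2, index=ids, columns=tissues),
            pd.Series(lengths, index=ids),
            pd.Series(totals, index=tissues, dtype=float),
        )
        assert np.allclose(rpkm(doubled).values, base * 2)
        scaled = CountMatrix(
            pd.DataFrame(counts * 3, index=ids, columns=tissues),
            pd.Series(lengths, index=ids),
            pd.Series(totals * 3, index=tissues, dtype=float),
        )
        assert np.allclose(rpkm(scaled).values, base)

    def test_zero_library_total_errors(self):
        with pytest.raises(ValueError):
            rpkm(_cm({"t": {"a": 0}}, {"t": 500}, {"a": 0}))


class TestMeanScaling:
    def test_equal_column_means_unchanged(self):
        em = _em({"x": {"a": 2.0, "b": 2.0}, "y": {"a": 4.0, "b": 4.0}})
        out = normalize_mean_scaling(em)
        assert np.allclose(out.values, em.values)

    def test_two_column_means_equalized_at_their_mean(self):
        em = _em({"x": {"a": 1.0, "b": 3.0}, "y": {"a": 3.0, "b": 5.0}})
        # column means: a -> 2, b -> 4; target 3
        out = normalize_mean_scaling(em)
        assert out.values.mean(axis=0).tolist() == pytest.approx([3.0, 3.0])

    def test_column_means_equal_on_random_matrices(self, rng):
        vals = rng.uniform(0.1, 50, size=(30, 6))
        em = ExpressionMatrix(pd.DataFrame(vals))
        out = normalize_mean_scaling(em)
        means = out.values.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0])

    def test_all_zero_column_left_unscaled(self):
        em = _em({"x": {"a": 2.0, "b": 0.0}, "y": {"a": 4.0, "b": 0.0}})
        out = normalize_mean_scaling(em)
        assert (out.values["b"] == 0).all()


class TestSpecificityCalls:
    def test_eightfold_rule_is_inclusive(self):
        em = _em({"t": {"a": 4.0, "b": 0.5, "c": 0.5}})
        assert call_tissue_specific(em).loc["t"] == "a"

    def test_just_under_eightfold_is_not_specific(self):
        em = _em({"t": {"a": 4.0, "b": 0.6, "c": 0.1}})
        assert call_tissue_specific(em).loc["t"] is None

    def test_minimum_rpkm_floor_applies_to_the_candidate_tissue(self):
        em = _em({"t": {"a": 0.4, "b": 0.04, "c": 0.01}})
        assert call_tissue_specific(em).loc["t"] is None

    def test_flat_profile_is_not_specific(self):
        em = _em({"t": {"a": 5.0, "b": 5.0, "c": 5.0}})
        assert call_tissue_specific(em).loc["t"] is None

    def test_ubiquitous_requires_every_tissue_at_floor(self):
        em = _em({"t": {c: 1.0 for c in "abcdefghijklm"}})
        assert call_ubiquitous(em).loc["t"]
        em2 = _em({"t": {**{c: 2.0 for c in "abcdefghijkl"}, "m": 0.99}})
        assert not call_ubiquitous(em2).loc["t"]

    def test_specific_and_ubiquitous_are_mutually_exclusive(self, rng):
        vals = rng.uniform(0, 20, size=(200, 13))
        em = ExpressionMatrix(pd.DataFrame(vals))
        spec = call_tissue_specific(em, fold=8.0, min_rpkm=0.5)
        ubiq = call_ubiquitous(em, min_rpkm=1.0)
        both = spec.notna() & ubiq
        assert not both.any()


class TestComplexityCurve:
    def test_single_expressed_transcript_jumps_to_one(self):
        em = _em({"t1": {"a": 7.0}, "t2": {"a": 0.0}, "t3": {"a": 0.0}})
        curve = complexity_curve(em, "a")
        assert curve[0] == pytest.approx(1.0)
        assert curve[-1] == 1.0

    def test_uniform_profile_is_linear(self):
        em = _em({f"t{i}": {"a": 2.0} for i in range(10)})
        curve = complexity_curve(em, "a")
        assert np.allclose(curve, np.arange(1, 11) / 10)

    def test_matches_bruteforce_and_is_monotone(self, rng):
        col = rng.uniform(0, 30, 50)
        em = ExpressionMatrix(pd.DataFrame({"a": col}))
        curve = complexity_curve(em, "a")
        brute = np.cumsum(sorted(col, reverse=True)) / col.sum()
        assert np.allclose(curve[:-1], brute[:-1])
        assert (np.diff(curve) >= -1e-12).all()
        assert curve[-1] == 1.0

    def test_all_zero_tissue_errors(self):
        em = _em({"t": {"a": 0.0}})
        with pytest.raises(ValueError):
            complexity_curve(em, "a")


class TestEntropy:
    def test_uniform_13_tissue_profile(self):
        assert expression_entropy([1.0] * 13) == pytest.approx(math.log2(13))

    def test_one_hot_profile_is_zero(self):
        assert expression_entropy([0, 0, 5.0, 0]) == 0.0

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=13),
        st.floats(min_value=0.001, max_value=1000),
    )
    def test_scale_invariance(self, profile, c):
        h = expression_entropy(profile)
        assert expression_entropy([c * x for x in profile]) == pytest.approx(h, abs=1e-9)
        assert 0 <= h <= math.log2(len(profile)) + 1e-9

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValueError):
            expression_entropy([0.0, 0.0])


class TestClustering:
    def test_identical_profiles_form_one_cluster(self):
        em = _em(
            {
                "a": {"x": 1.0, "y": 5.0, "z": 2.0},
                "b": {"x": 2.0, "y": 10.0, "z": 4.0},
            }
        )
        cs = cluster_correlated(em)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].members == ["a", "b"]

    def test_weakly_correlated_profiles_stay_apart(self):
        em = _em(
            {
                "a": {"x": 1.0, "y": 5.0, "z": 2.0, "w": 1.0},
                "b": {"x": 5.0, "y": 1.0, "z": 1.0, "w": 4.0},
            }
        )
        cs = cluster_correlated(em)
        assert cs.clusters == []

    def test_retain_fraction_keeps_top_fifth_by_entropy(self, rng):
        base = np.array([10.0, 1.0, 0.5, 8.0, 2.0])
        rows = {f"t{i}": base * (1 + 0.001 * i) for i in range(10)}
        em = ExpressionMatrix(pd.DataFrame(rows).T)
        cs = cluster_correlated(em)
        (cluster,) = cs.clusters
        assert len(cluster.members) == 10
        assert len(cluster.retained) == 2  # ceil(0.2 * 10)

    def test_small_cluster_retains_at_least_one_member(self):
        em = _em(
            {
                "a": {"x": 1.0, "y": 5.0, "z": 2.0},
                "b": {"x": 2.0, "y": 10.0, "z": 4.0},
            }
        )
        (cluster,) = cluster_correlated(em).clusters
        assert len(cluster.retained) == 1

    def test_zero_variance_rows_excluded(self):
        em = _em(
            {
                "flat": {"x": 3.0, "y": 3.0, "z": 3.0},
                "a": {"x": 1.0, "y": 5.0, "z": 2.0},
                "b": {"x": 2.0, "y": 10.0, "z": 4.0},
            }
        )
        cs = cluster_correlated(em)
        assert cs.n_zero_variance_excluded == 1
        assert all("flat" not in c.members for c in cs.clusters)

    def test_fewer_than_two_usable_rows_gives_empty_set(self):
        em = _em({"flat": {"x": 1.0, "y": 1.0}})
        assert cluster_correlated(em).clusters == []

    def test_reported_clusters_meet_correlation_threshold_by_recomputation(
        self, default_data
    ):
        em = normalize_mean_scaling(rpkm(default_data.counts))
        cs = cluster_correlated(em, min_corr=0.97)
        assert cs.clusters, "expected clusters on the reference fixture"
        for c in cs.clusters:
            sub = em.values.loc[c.members].to_numpy()
            corr = np.corrcoef(sub)
            iu = np.triu_indices(len(c.members), k=1)
            assert corr[iu].mean() >= 0.97 - 1e-9

    def test_planted_coexpression_blocks_recovered(self, default_data):
        em = normalize_mean_scaling(rpkm(default_data.counts))
        coding = {
            tid
            for tid, r in default_data.truth.records.items()
            if r.role == "coding"
        }
        cs = cluster_correlated(em, coding_ids=coding)
        blocks: dict[str, set] = {}
        for tid, rec in default_data.truth.records.items():
            if rec.expression_pattern and rec.expression_pattern.startswith("cluster:"):
                blocks.setdefault(rec.expression_pattern, set()).add(tid)
        assert blocks
        for name, members in blocks.items():
            hosts = [c for c in cs.clusters if members <= set(c.members)]
            assert hosts, f"planted block {name} not recovered"
            assert hosts[0].is_coexpression
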