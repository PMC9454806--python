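"""Signature scoring and rank-sum marker detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from veinoise import (
    CountMatrix,
    DEParams,
    GeneSet,
    NormalizedMatrix,
    PROINFLAMMATORY,
    deg_lists,
    lognormalize,
    rank_markers,
    score_gene_set,
)
from veinoise.reference import exact_ranksum_p, naive_ranksum_p
from veinoise.synthetic import DonorSpec, SimulationConfig, SubsetSpec, generate_counts


def _norm(dense, genes=None):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    return NormalizedMatrix(
        genes, [f"c{i}" for i in range(dense.shape[1])], sparse.csc_matrix(dense)
    )


# ---------------------------------------------------------------------------
# Gene-set scores
# ---------------------------------------------------------------------------

class TestScoreGeneSet:
    def test_proinflammatory_score_is_mean_over_adhesion_genes(self, rng):
        genes = list(PROINFLAMMATORY.genes) + ["OTHER1", "OTHER2"]
        dense = rng.uniform(0, 3, size=(9, 5))
        scores, _ = score_gene_set(_norm(dense, genes), PROINFLAMMATORY)
        assert np.allclose(scores.to_numpy(), dense[:7].mean(axis=0))

    def test_all_zero_expression_scores_zero(self):
        norm = _norm(np.zeros((3, 4)), ["SELE", "IL6", "X"])
        with pytest.warns(UserWarning):
            scores, _ = score_gene_set(norm, PROINFLAMMATORY)
        assert (scores == 0).all()

    def test_singleton_set_equals_gene_value(self, rng):
        dense = rng.uniform(0, 2, (4, 6))
        scores, _ = score_gene_set(_norm(dense), GeneSet("solo", ["g2"]))
        assert np.allclose(scores.to_numpy(), dense[2])

    def test_no_present_genes_is_error_listing_symbols(self):
        with pytest.raises(ValueError, match="SELE"):
            score_gene_set(_norm(np.ones((2, 2))), PROINFLAMMATORY)

    def test_linearity_over_disjoint_sets(self, rng):
        dense = rng.uniform(0, 2, (10, 5))
        norm = _norm(dense)
        a = GeneSet("a", ["g0", "g1", "g2"])
        b = GeneSet("b", ["g5", "g6"])
        u = GeneSet("u", a.genes + b.genes)
        sa, _ = score_gene_set(norm, a)
        sb, _ = score_gene_set(norm, b)
        su, _ = score_gene_set(norm, u)
        assert np.allclose(su, (3 * sa + 2 * sb) / 5)

    def test_per_subset_means_aggregate_cells(self, rng):
        dense = rng.uniform(0, 2, (4, 6))
        labels = ["A", "A", "A", "B", "B", "B"]
        per_cell, per_subset = score_gene_set(
            _norm(dense), GeneSet("s", ["g0", "g3"]), labels
        )
        assert per_subset["A"] == pytest.approx(per_cell[:3].mean())


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def _two_group_norm(rng, n_genes=12, n_a=10, n_b=12):
    dense = rng.uniform(0, 2, size=(n_genes, n_a + n_b))
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    return _norm(dense), labels


class TestRankMarkers:
    def test_detection_filter_blocks_low_pct_genes(self):
        # gene detected in 29% of in-group, 10% of out-group -> not tested
        n_a, n_b = 100, 100
        col = np.zeros(n_a + n_b)
        col[:29] = 2.0          # 29% of A
        col[n_a : n_a + 10] = 2.0  # 10% of B
        dense = np.vstack([col, np.tile([1.0], n_a + n_b)])
        labels = np.array(["A"] * n_a + ["B"] * n_b)
        de = rank_markers(_norm(dense), labels)
        row = de[(de.gene == "g0") & (de.subset == "A")].iloc[0]
        assert not row.tested and not row.passes_filters
        assert row.detect_frac_in == pytest.approx(0.29)

    def test_identical_groups_have_zero_log2fc_and_filtered(self, rng):
        dense = np.tile(rng.uniform(0.5, 2, size=(5, 1)), (1, 8))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        de = rank_markers(_norm(dense), labels)
        assert np.allclose(de["log2fc"], 0.0)
        assert not de["tested"].any()

    def test_planted_marker_recovered_single_seed(self):
        cfg = SimulationConfig(
            n_genes=200,
            subsets=[
                SubsetSpec("A", 200, 0.3, markers={i: 4.0 for i in range(10, 14)}),
                SubsetSpec("B", 200, 0.3),
            ],
            donors=[DonorSpec("d1", 1.0)],
            baseline_overrides={i: 1.0 for i in range(10, 14)},
            seed=17,
        )
        cm, meta, truth = generate_counts(cfg)
        de = rank_markers(lognormalize(cm), meta["subset"].to_numpy())
        planted = list(truth.markers["A"])
        hits = de[(de.subset == "A") & (de.gene.isin(planted))]
        assert hits["passes_filters"].all()

    def test_pvalues_match_handwritten_normal_approximation(self, rng):
        norm, labels = _two_group_norm(rng, n_genes=20, n_a=14, n_b=16)
        params = DEParams(min_detect_frac=0.0, min_logfc=0.0)
        de = rank_markers(norm, labels, params)
        dense = norm.toarray()
        for _, row in de[(de.subset == "A") & de.tested].iterrows():
            g = norm.gene_index()[row.gene]
            p_ref = naive_ranksum_p(dense[g, labels == "A"], dense[g, labels == "B"])
            assert abs(row.pvalue - p_ref) < 1e-10

    def test_asymptotic_close_to_exact_enumeration_at_tiny_n(self, rng):
        for _ in range(5):
            x, y = rng.normal(0, 1, 7), rng.normal(0.8, 1, 7)
            p_asym = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_asym - exact_ranksum_p(x, y)) <= 0.05

    def test_label_permutation_null_is_controlled(self):
        cfg = SimulationConfig(
            n_genes=300,
            subsets=[SubsetSpec("A", 100, 0.3), SubsetSpec("B", 100, 0.3)],
            donors=[DonorSpec("d1", 1.0)],
            seed=23,
        )
        cm, meta, _ = generate_counts(cfg)
        norm = lognormalize(cm)
        rng = np.random.default_rng(23)
        labels = meta["subset"].to_numpy()
        fractions = []
        for _ in range(5):
            de = rank_markers(norm, rng.permutation(labels))
            fractions.append(de["passes_filters"].mean())
        assert np.mean(fractions) <= 0.05

    def test_tiny_subset_excluded_with_warning(self, rng):
        dense = rng.uniform(0, 2, (6, 9))
        labels = np.array(["A"] * 4 + ["B"] * 3 + ["C"] * 2)
        with pytest.warns(UserWarning, match="'C'"):
            de = rank_markers(_norm(dense), labels)
        assert set(de["subset"]) == {"A", "B"}


# ---------------------------------------------------------------------------
# DEG lists
# ---------------------------------------------------------------------------

class TestDegLists:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "subset", "detect_frac_in", "log2fc", "passes_filters"
            ],
        )

    def test_empty_input_gives_empty_lists(self):
        assert deg_lists(self._frame([])) == {}

    def test_fold_change_threshold_is_inclusive_at_0_4(self):
        de = self._frame([
            ("up", "A", 0.5, 0.40, True),
            ("just_below", "A", 0.5, 0.39, True),
            ("down", "A", 0.5, -1.0, True),
            ("low_pct", "A", 0.2, 1.0, True),
        ])
        assert deg_lists(de) == {"A": ["up"]}

    def test_output_contained_in_passing_genes(self, rng):
        norm, labels = _two_group_norm(rng, n_genes=30, n_a=15, n_b=15)
        de = rank_markers(norm, labels, DEParams(min_detect_frac=0.0, min_logfc=0.0))
        lists = deg_lists(de)
        for sub, genes in lists.items():
            passing = set(de[(de.subset == sub) & de.passes_filters]["gene"])
            assert set(genes) <= passing


def test_prefilter_monotone_in_thresholds(rng):
    norm, labels = _two_group_norm(rng, n_genes=40, n_a=20, n_b=20)
    loose = rank_markers(norm, labels, DEParams(min_detect_frac=0.1, min_logfc=0.1))
    tight = rank_markers(norm, labels, DEParams(min_detect_frac=0.4, min_logfc=0.5))
    for sub in ("A", "B"):
        t_loose = set(loose[(loose.subset == sub) & loose.tested]["gene"])
        t_tight = set(tight[(tight.subset == sub) & tight.tested]["gene"])
        assert t_tight <= t_loose
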