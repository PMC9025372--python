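"""Monte Carlo feature selection: projections, tree records, RI scores."""

import numpy as np
import pytest

from cellmark import MCFSConfig, MCFSRanker, run_mcfs
from cellmark.io import ExpressionMatrix, LabelVector
from cellmark.mcfs import TreeRecord, draw_projection, evaluate_tree, relative_importance


def ri_straight_line(records, d, u, v):
    """Independent re-computation of the RI sum, term by term."""
    ri = [0.0] * d
    for rec in records:
        for f, pairs in rec.node_contribs.items():
            for ig, frac in pairs:
                ri[f] += (rec.wacc ** u) * ig * (frac ** v)
    return np.array(ri)


class TestProjection:
    def test_m_equals_d_returns_all(self):
        rng = np.random.default_rng(0)
        assert list(draw_projection(5, 5, rng)) == [0, 1, 2, 3, 4]

    def test_fixed_rng_state_is_deterministic(self):
        a = draw_projection(20, 4, np.random.default_rng(3))
        b = draw_projection(20, 4, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_uniform_coverage_binomial_bound(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(3)
        n = 3000
        for _ in range(n):
            counts[draw_projection(3, 1, rng)[0]] += 1
        sigma = np.sqrt(n * (1 / 3) * (2 / 3))
        assert (np.abs(counts - n / 3) <= 3 * sigma).all()

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            draw_projection(3, 0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            draw_projection(3, 4, np.random.default_rng(0))


class TestEvaluateTree:
    def test_separable_single_feature_has_unit_wacc(self):
        X = np.r_[np.zeros((20, 1)), np.ones((20, 1)) * 9]
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        rec = evaluate_tree(X, y, np.array([0]), 0.66, np.random.default_rng(0))
        assert rec.wacc == 1.0

    def test_root_split_has_unit_node_fraction(self):
        X = np.r_[np.zeros((20, 1)), np.ones((20, 1)) * 9]
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        rec = evaluate_tree(X, y, np.array([0]), 0.66, np.random.default_rng(1))
        (pairs,) = rec.node_contribs.values()
        assert pairs[0][1] == 1.0  # the root reaches all training samples
        assert pairs[0][0] == pytest.approx(1.0)  # IG of a clean 50/50 split, in bits

    def test_unsplittable_training_data_gives_empty_contribs(self):
        # a constant feature cannot split: tree stays a single leaf
        X = np.ones((20, 1))
        y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        rec = evaluate_tree(X, y, np.array([0]), 0.66, np.random.default_rng(2))
        assert rec.node_contribs == {}


class TestRelativeImportance:
    def test_single_root_split_product(self):
        rec = TreeRecord(wacc=0.8, node_contribs={2: [(0.5, 1.0)]})
        ri = relative_importance([rec], d=4, u=1, v=1)
        assert ri[2] == pytest.approx(0.4)
        assert ri[[0, 1, 3]].sum() == 0.0

    def test_zero_exponents_reduce_to_ig_sum(self):
        rec = TreeRecord(wacc=0.5, node_contribs={0: [(0.3, 0.5), (0.2, 0.25)]})
        ri = relative_importance([rec], d=2, u=0, v=0)
        assert ri[0] == pytest.approx(0.5)

    def test_straight_line_oracle_small_runs(self, tiny_data):
        matrix, labels = tiny_data
        for s, t in [(1, 1), (2, 3), (3, 2)]:
            r = MCFSRanker(m=2, s=s, t=t, store_records=True, random_state=s + t)
            r.fit(matrix.values, labels.labels)
            expected = ri_straight_line(r.records_, matrix.n_genes, 1, 1)
            np.testing.assert_allclose(r.ri_scores_, expected, atol=1e-12)

    def test_increasing_u_downweights_imperfect_trees(self):
        rec = TreeRecord(wacc=0.6, node_contribs={0: [(1.0, 1.0)]})
        lo = relative_importance([rec], d=1, u=1, v=1)[0]
        hi = relative_importance([rec], d=1, u=3, v=1)[0]
        assert hi < lo


class TestRunMCFS:
    def test_single_projection_only_scores_projected_features(self, tiny_data):
        matrix, labels = tiny_data
        r = MCFSRanker(m=2, s=1, t=1, store_records=True, random_state=0)
        r.fit(matrix.values, labels.labels)
        touched = set()
        for rec in r.records_:
            touched |= set(rec.node_contribs)
        untouched = set(range(matrix.n_genes)) - touched
        assert all(r.ri_scores_[j] == 0 for j in untouched)

    def test_same_seed_identical_ranking(self, tiny_data):
        matrix, labels = tiny_data
        a = run_mcfs(matrix, labels, MCFSConfig(m=2, s=20, t=2, seed=7))
        b = run_mcfs(matrix, labels, MCFSConfig(m=2, s=20, t=2, seed=7))
        assert a.entries == b.entries

    def test_ri_non_negative_and_sorted(self, tiny_data):
        matrix, labels = tiny_data
        ranked = run_mcfs(matrix, labels, MCFSConfig(m=2, s=30, t=2, seed=1))
        scores = [s for _, s in ranked.entries]
        assert all(s >= 0 for s in scores)
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_keeps_input_gene_order(self):
        # two identical useless genes tie at RI 0; input order decides
        X = np.ones((10, 2))
        m = ExpressionMatrix(X, ["gB", "gA"], [f"c{i}" for i in range(10)])
        lab = LabelVector(np.array(["x"] * 5 + ["y"] * 5, dtype=object))
        ranked = run_mcfs(m, lab, MCFSConfig(m=2, s=5, t=1, seed=0))
        assert ranked.gene_ids == ["gB", "gA"]

    def test_markers_outrank_noise_mann_whitney(self, synth0):
        from scipy.stats import mannwhitneyu

        matrix, labels, truth = synth0
        noise = sorted(truth.noise_genes)[:120]
        sub = matrix.subset_genes(sorted(truth.all_markers) + noise)
        ranked = run_mcfs(sub, labels, MCFSConfig(m=8, s=400, t=2, seed=0))
        rank_of = {g: i for i, g in enumerate(ranked.gene_ids)}
        m_ranks = [rank_of[g] for g in truth.all_markers]
        n_ranks = [rank_of[g] for g in noise]
        assert mannwhitneyu(m_ranks, n_ranks, alternative="less").pvalue < 1e-6

    def test_marker_recovery_on_planted_data(self, chain0):
        truth = chain0["truth"]
        ranked = chain0["ranked"]
        rank_of = {g: i for i, g in enumerate(ranked.gene_ids)}
        marker_ranks = [rank_of[g] for g in truth.all_markers if g in rank_of]
        noise_ranks = [rank_of[g] for g in truth.noise_genes if g in rank_of]
        assert np.mean(marker_ranks) < np.mean(noise_ranks or [len(rank_of)])
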