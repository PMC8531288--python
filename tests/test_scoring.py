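"""Signature scoring, median split, stem-cluster ranking, proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stemscore as ss
from stemscore.io import ValidationError
from stemscore.scoring import _rank_es_one


def _norm(vals, genes, cells):
    return ss.NormalizedMatrix(np.asarray(vals, dtype=float),
                               tuple(genes), tuple(cells))


class TestMeanDifference:
    def test_arithmetic_identity(self):
        norm = _norm([[2], [4], [1]], ("u1", "u2", "d1"), ("c1",))
        sig = ss.GeneSignature("s", ("u1", "u2"), ("d1",))
        assert ss.mean_difference_score(norm, sig)["score"][0] == 2.0

    def test_all_zero_cell_scores_zero(self):
        norm = _norm([[0], [0]], ("u", "d"), ("c1",))
        sig = ss.GeneSignature("s", ("u",), ("d",))
        assert ss.mean_difference_score(norm, sig)["score"][0] == 0.0

    def test_empty_down_set_means_up_mean(self):
        norm = _norm([[3], [5]], ("u1", "u2"), ("c1",))
        sig = ss.GeneSignature("s", ("u1", "u2"))
        assert ss.mean_difference_score(norm, sig)["score"][0] == 4.0

    def test_missing_signature_rejected(self):
        norm = _norm([[1]], ("x",), ("c1",))
        with pytest.raises(ValidationError):
            ss.mean_difference_score(norm, ss.GeneSignature("s", ("nope",)))

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additivity_in_up_genes(self, k):
        """Adding k to every up-gene of a cell moves its score by exactly k."""
        base = np.array([[1.0], [2.0], [0.5]])
        sig = ss.GeneSignature("s", ("u1", "u2"), ("d",))
        s0 = ss.mean_difference_score(
            _norm(np.abs(base), ("u1", "u2", "d"), ("c",)), sig)["score"][0]
        shifted = np.abs(base).copy()
        shifted[:2] += abs(k)
        s1 = ss.mean_difference_score(
            _norm(shifted, ("u1", "u2", "d"), ("c",)), sig)["score"][0]
        assert s1 - s0 == pytest.approx(abs(k), abs=1e-12)

    def test_cancer_cells_score_higher_on_planted_signature(self, small_sim, small_norm):
        _, cells, truth = small_sim
        sig = ss.GeneSignature("planted", truth.up_genes, truth.down_genes)
        scores = ss.mean_difference_score(small_norm, sig).set_index("cell_id")
        t = truth.cells.set_index("cell_id")
        epi = t[t.compartment == "epithelial"]
        ca = scores.loc[epi.index[epi.is_cancer], "score"]
        no = scores.loc[epi.index[~epi.is_cancer], "score"]
        pooled_se = np.sqrt(ca.var() / len(ca) + no.var() / len(no))
        assert ca.mean() - no.mean() > 4 * pooled_se


class TestRankEnrichment:
    def test_top_block_set_reaches_walk_maximum(self):
        # gene set occupies exactly the top n ranks: the walk climbs to 1
        # before any out-of-set step, so the maxdiff score is exactly 1.
        x = np.arange(30, 0, -1).astype(float)
        in_set = np.zeros(30, dtype=bool)
        in_set[:6] = True
        assert _rank_es_one(x, in_set, tau=1.0) == pytest.approx(1.0, abs=1e-12)

    def test_uniformly_interleaved_set_near_zero_at_weight_zero(self):
        # brute-force walk oracle on an interleaved ranking
        n_genes, step = 40, 4
        x = np.arange(n_genes, 0, -1).astype(float)
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[::step] = True
        n_set = in_set.sum()
        walk, pos = [], 0.0
        for i in range(n_genes):  # descending order is index order here
            pos += (1.0 / n_set) if in_set[i] else (-1.0 / (n_genes - n_set))
            walk.append(pos)
        expected = max(max(walk), 0) + min(min(walk), 0)
        got = _rank_es_one(x, in_set, tau=0.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert abs(got) <= 2 * n_set / (n_genes - n_set)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(25).astype(float)
        in_set = np.zeros(25, dtype=bool)
        in_set[rng.choice(25, 7, replace=False)] = True
        assert _rank_es_one(x, in_set, 1.0) == pytest.approx(
            _rank_es_one(np.exp(0.3 * x), in_set, 1.0), abs=1e-12)

    def test_scores_bounded_and_set_equal_universe_rejected(self, small_norm):
        genes = list(small_norm.gene_ids)
        tab = ss.rank_enrichment_score(small_norm, genes[:40])
        assert tab["score"].between(-1, 1).all()
        with pytest.raises(ValidationError):
            ss.rank_enrichment_score(small_norm, genes)

    def test_concordant_with_mean_difference_on_planted_signal(self, small_sim, small_norm):
        """The two scoring routes rank cells concordantly (Spearman > 0.5)."""
        from scipy.stats import spearmanr
        _, cells, truth = small_sim
        sig = ss.GeneSignature("planted", truth.up_genes)
        md = ss.mean_difference_score(small_norm, sig)["score"]
        es = ss.rank_enrichment_score(small_norm, truth.up_genes)["score"]
        assert spearmanr(md, es).statistic > 0.5


class TestMedianSplit:
    def test_strictly_above_median_is_cancer(self):
        scores = pd.DataFrame({"cell_id": ["a", "b", "c"],
                               "score": [0.1, 0.5, 0.9]})
        out = ss.classify_by_median(scores).set_index("cell_id")["label"]
        assert out.to_dict() == {"a": "normal", "b": "normal", "c": "cancer"}

    def test_all_equal_scores_all_normal(self, caplog):
        scores = pd.DataFrame({"cell_id": list("abcd"), "score": [1.0] * 4})
        out = ss.classify_by_median(scores)
        assert (out["label"] == "normal").all()

    def test_even_n_distinct_scores_half_cancer(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"cell_id": [f"c{i}" for i in range(40)],
                               "score": rng.permutation(40).astype(float)})
        out = ss.classify_by_median(scores)
        assert (out["label"] == "cancer").sum() == 20

    def test_at_most_half_labelled_cancer(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = rng.integers(0, 4, size=rng.integers(3, 20)).astype(float)
            scores = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(s))],
                                   "score": s})
            out = ss.classify_by_median(scores)
            assert (out["label"] == "cancer").sum() <= len(s) // 2


class TestStemCluster:
    def test_ranking_and_margin(self):
        scores = pd.DataFrame({"cell_id": list("abcd"),
                               "score": [0.9, 0.9, 0.1, 0.1]})
        clusters = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        ranking, top, margin = ss.identify_stem_cluster(scores, clusters)
        assert top == "A" and margin == pytest.approx(0.8)

    def test_tie_breaks_by_label_order(self, caplog):
        scores = pd.DataFrame({"cell_id": list("ab"), "score": [0.5, 0.5]})
        clusters = pd.Series(["B", "A"], index=list("ab"))
        _, top, margin = ss.identify_stem_cluster(scores, clusters)
        assert top == "A" and margin == 0.0

    def test_planted_stem_cluster_top_ranked(self, small_sim, small_norm):
        """Rank-ES stemness scores on the true cell-type partition rank the
        stem type first."""
        _, cells, truth = small_sim
        epi = truth.cells[truth.cells.compartment == "epithelial"]
        sub = small_norm.subset_cells(list(epi.cell_id))
        stem_set = [g for g in truth.markers["Stem"] if g in sub.gene_ids]
        scores = ss.rank_enrichment_score(sub, stem_set)
        clusters = epi.set_index("cell_id")["cell_type"]
        _, top, _ = ss.identify_stem_cluster(scores, clusters)
        assert top == "Stem"


class TestProportions:
    def test_simple_fraction(self):
        labels = pd.Series({"a": "BCSC", "b": "BCSC", "c": "other", "d": "other"})
        stages = pd.Series({k: "W07" for k in "abcd"})
        out = ss.proportion_dynamics(labels, stages, list("abcd"))
        assert out.loc[out.label == "BCSC", "proportion"].iloc[0] == 0.5

    def test_empty_denominator_is_missing_not_zero(self):
        labels = pd.Series({"a": "x"})
        stages = pd.Series({"a": "W07"})
        out = ss.proportion_dynamics(labels, stages, [],
                                     stage_order=["W07"])
        assert out["proportion"].isna().all()

    def test_complementary_labels_sum_to_one(self):
        rng = np.random.default_rng(3)
        ids = [f"c{i}" for i in range(60)]
        labels = pd.Series(rng.choice(["x", "y"], 60), index=ids)
        stages = pd.Series(rng.choice(["W07", "W09"], 60), index=ids)
        out = ss.proportion_dynamics(labels, stages, ids)
        sums = out.groupby("stage")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)
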