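"""DE statistics, TMM factors, signature gates and ER-lineage calls."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stemscore as ss
from stemscore.io import ValidationError
from stemscore.signatures import DEGates, exact_ranksum_pvalue


def brute_force_ranksum_p(a, b):
    """Oracle: enumerate every assignment of the pooled values to group A."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = np.array([ranks[list(comb)].sum()
                     for comb in itertools.combinations(range(len(pooled)), n_a)])
    p_low = np.mean(sums <= w_obs + 1e-9)
    p_high = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_textbook_no_tie_case(self):
        # A={1,2}, B={3,4}: 6 assignments, extreme one observed -> p = 1/3
        assert exact_ranksum_pvalue([1, 2], [3, 4]) == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_p_one(self):
        assert exact_ranksum_pvalue([2, 2, 2], [2, 2, 2]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 8, size=2)
        a = rng.integers(0, 4, size=n_a).astype(float)
        b = rng.integers(0, 4, size=n_b).astype(float)
        assert exact_ranksum_pvalue(a, b) == pytest.approx(
            brute_force_ranksum_p(a, b), abs=1e-12)

    def test_de_table_contracts(self, small_norm, small_sim):
        _, cells, _ = small_sim
        epi = cells[cells["compartment"] == "epithelial"]["cell_id"]
        imm = cells[cells["compartment"] == "immune"]["cell_id"]
        de = ss.wilcoxon_de(small_norm, epi, imm)
        assert (de["fdr"] >= de["p_value"] - 1e-12).all()
        assert de["p_value"].between(0, 1).all()
        # fold-change sign agrees with group-mean ordering
        up = de["mean_a"] > de["mean_b"]
        assert ((de.loc[up, "fold_change"] > 1) | (de.loc[up, "mean_a"]
                == de.loc[up, "mean_b"])).all()

    def test_overlapping_groups_rejected(self, small_norm):
        ids = list(small_norm.cell_ids)
        with pytest.raises(ValidationError):
            ss.wilcoxon_de(small_norm, ids[:3], ids[2:5])

    def test_normal_approximation_close_to_scipy(self, small_norm):
        """Tie-corrected normal path agrees with scipy's asymptotic
        Mann-Whitney on genes without degenerate distributions."""
        ids = list(small_norm.cell_ids)
        a, b = ids[:30], ids[30:60]
        de = ss.wilcoxon_de(small_norm, a, b).set_index("gene")
        lookup = {c: i for i, c in enumerate(small_norm.cell_ids)}
        rng = np.random.default_rng(0)
        for g in rng.choice(small_norm.gene_ids, 10, replace=False):
            x = small_norm.values[small_norm.gene_index([g])[0]]
            va, vb = x[[lookup[c] for c in a]], x[[lookup[c] for c in b]]
            if np.ptp(np.concatenate([va, vb])) == 0:
                continue
            ref = stats.mannwhitneyu(va, vb, method="asymptotic",
                                     use_continuity=True).pvalue
            assert de.loc[g, "p_value"] == pytest.approx(ref, rel=1e-9)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        col = np.array([10, 5, 80, 3, 40])
        cm = ss.CountMatrix(np.stack([col, col], axis=1),
                            tuple("abcde"), ("s1", "s2"))
        np.testing.assert_allclose(ss.tmm_factors(cm), 1.0, atol=1e-9)

    def test_pure_depth_change_unit_factors(self):
        col = np.array([10, 5, 80, 3, 40])
        cm = ss.CountMatrix(np.stack([col, 2 * col], axis=1),
                            tuple("abcde"), ("s1", "s2"))
        np.testing.assert_allclose(ss.tmm_factors(cm), 1.0, atol=1e-9)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(8)
        cm = ss.CountMatrix(rng.poisson(20, size=(100, 5)),
                            tuple(f"g{i}" for i in range(100)),
                            tuple(f"s{i}" for i in range(5)))
        assert np.prod(ss.tmm_factors(cm)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_edger_oracle(self, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        rng = np.random.default_rng(7)
        X = rng.negative_binomial(5, 0.3, size=(300, 4)) * rng.integers(
            1, 4, size=(300, 1))
        X[:30, 0] *= 6
        cm = ss.CountMatrix(X, tuple(f"g{i}" for i in range(300)),
                            ("s1", "s2", "s3", "s4"))
        np.savetxt(tmp_path / "x.tsv", X, fmt="%d", delimiter="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR));'
             f'x<-as.matrix(read.table("{tmp_path}/x.tsv"));'
             f'cat(sprintf("%.10f ", calcNormFactors(x, method="TMM")))'],
            capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip(f"edgeR unavailable: {r.stderr[:200]}")
        ref = np.array([float(v) for v in r.stdout.split()])
        np.testing.assert_allclose(ss.tmm_factors(cm).to_numpy(), ref, atol=1e-6)

    def test_all_zero_sample_rejected(self):
        cm = ss.CountMatrix(np.array([[1, 0], [2, 0]]), ("a", "b"), ("s1", "s2"))
        with pytest.raises(ValidationError):
            ss.tmm_factors(cm)


class TestBulkDE:
    def test_label_swap_flips_fold_changes(self, small_cfg):
        bulk, samples, _ = ss.simulate_bulk(small_cfg, n_reps=3)
        grp = samples.set_index("sample_id")["group"]
        fwd = ss.bulk_de(bulk, grp, group_a="tumor", group_b="normal")
        rev = ss.bulk_de(bulk, grp, group_a="normal", group_b="tumor")
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"], atol=1e-9)

    def test_planted_recovery_at_paper_gates(self):
        """3v3, 200 genes, 20 planted up-genes at fold 4, dispersion 0.05:
        sensitivity >= 0.8 and FDP <= 0.2 at FDR<0.05, FC>1.5."""
        from conftest import lean_bulk_cfg
        cfg = lean_bulk_cfg(seed=13)
        bulk, samples, truth = ss.simulate_bulk(cfg, n_reps=3, fold=4,
                                                dispersion=0.05)
        de = ss.bulk_de(bulk, samples.set_index("sample_id")["group"])
        sig = ss.build_signature(de, DEGates())
        found, planted = set(sig.up_genes), set(truth.up_genes)
        assert len(found & planted) / len(planted) >= 0.8
        assert len(found - planted) / max(len(found), 1) <= 0.2

    def test_too_few_replicates_rejected(self, small_cfg):
        bulk, samples, _ = ss.simulate_bulk(small_cfg, n_reps=2)
        labels = samples.set_index("sample_id")["group"]
        ss.bulk_de(bulk, labels)  # 2 per group is the minimum
        with pytest.raises(ValidationError):
            ss.bulk_de(bulk, labels.iloc[1:])


class TestSignatureGates:
    @pytest.mark.parametrize("fdr,fc,where", [
        (0.04, 1.6, "up"),
        (0.04, 1.5, "none"),    # strict > 1.5
        (0.06, 3.0, "none"),    # strict FDR < 0.05
        (0.04, 0.5, "down"),
        (0.04, 0.67, "none"),   # strict < 0.67
        (0.05, 2.0, "none"),    # strict FDR < 0.05 at the boundary
    ])
    def test_strict_gate_boundaries(self, fdr, fc, where):
        de = pd.DataFrame({"gene": ["g"], "fdr": [fdr], "fold_change": [fc]})
        sig = ss.build_signature(de, DEGates())
        assert ("g" in sig.up_genes) == (where == "up")
        assert ("g" in sig.down_genes) == (where == "down")

    def test_gene_order_invariance_and_disjointness(self):
        rng = np.random.default_rng(0)
        de = pd.DataFrame({
            "gene": [f"g{i}" for i in range(50)],
            "fdr": rng.uniform(0, 0.1, 50),
            "fold_change": rng.uniform(0.3, 3.0, 50),
        })
        sig1 = ss.build_signature(de, DEGates())
        sig2 = ss.build_signature(de.sample(frac=1, random_state=1), DEGates())
        assert set(sig1.up_genes) == set(sig2.up_genes)
        assert set(sig1.down_genes) == set(sig2.down_genes)
        assert not set(sig1.up_genes) & set(sig1.down_genes)


class TestAugment:
    def test_curated_genes_added_once(self):
        sig = ss.GeneSignature("s", ("A",))
        out = ss.augment_signature(sig, ["Esr1"], universe=["A", "Esr1"])
        assert out.up_genes == ("A", "Esr1")
        assert ss.augment_signature(out, ["Esr1"],
                                    universe=["A", "Esr1"]).up_genes == out.up_genes

    def test_down_gene_moves_to_up(self, caplog):
        sig = ss.GeneSignature("s", ("A",), ("B",))
        out = ss.augment_signature(sig, ["B"])
        assert "B" in out.up_genes and "B" not in out.down_genes

    def test_unknown_curated_gene_dropped(self, caplog):
        sig = ss.GeneSignature("s", ("A",))
        out = ss.augment_signature(sig, ["Nope"], universe=["A"])
        assert out.up_genes == ("A",)


class TestERLineage:
    @staticmethod
    def _norm(vals, cells):
        return ss.NormalizedMatrix(vals, ("Esr1", "other"), cells)

    def test_all_zero_gene_everything_erlow(self):
        norm = self._norm(np.array([[0, 0], [1.0, 1.0]]), ("a", "b"))
        clusters = pd.Series(["c1", "c2"], index=["a", "b"])
        cl, cells = ss.classify_er_lineage(norm, clusters)
        assert set(cl.values()) == {"ERlow"}

    def test_positive_cluster_is_erhigh(self):
        vals = np.zeros((2, 10))
        vals[0, :9] = 2.0  # cluster hi: 9/9 positive; cluster lo: 0/1
        ids = tuple(f"c{i}" for i in range(10))
        norm = self._norm(vals, ids)
        clusters = pd.Series(["hi"] * 9 + ["lo"], index=ids)
        cl, cells = ss.classify_er_lineage(norm, clusters, expr_threshold=0.5)
        assert cl == {"hi": "ERhigh", "lo": "ERlow"}
        assert (cells[clusters == "hi"] == "ERhigh").all()

    def test_missing_gene_rejected(self):
        norm = ss.NormalizedMatrix(np.zeros((1, 2)), ("x",), ("a", "b"))
        with pytest.raises(ValidationError):
            ss.classify_er_lineage(norm, pd.Series(["c", "c"], index=["a", "b"]))
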