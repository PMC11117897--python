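import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

import endophen as ep
from endophen.de import CountMatrix


def toy_matrix(counts, samples, subjects, groups):
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        replicate_map=pd.Series(subjects, index=samples),
        subject_group=pd.Series(groups),
    )


class TestCollapseReplicates:
    def test_two_replicates_sum(self):
        cm = toy_matrix(
            np.array([[3, 4], [1, 2]]),
            ["s1", "s2"],
            ["A", "A"],
            {"A": "Phen1"},
        )
        out = ep.collapse_replicates(cm)
        assert out.counts.loc["g0", "A"] == 7
        assert out.counts.loc["g1", "A"] == 3

    def test_single_replicate_unchanged(self):
        cm = toy_matrix(
            np.array([[5], [0]]), ["s1"], ["A"], {"A": "Phen1"}
        )
        out = ep.collapse_replicates(cm)
        assert (out.counts["A"] == [5, 0]).all()

    def test_conserves_totals_on_random_matrix(self, rng):
        counts = rng.integers(0, 100, size=(50, 8))
        samples = [f"s{i}" for i in range(8)]
        subjects = [f"sub{i // 2}" for i in range(8)]
        groups = {f"sub{i}": ("Phen1" if i < 2 else "nonPhen1") for i in range(4)}
        cm = toy_matrix(counts, samples, subjects, groups)
        out = ep.collapse_replicates(cm)
        assert out.counts.to_numpy().sum() == counts.sum()
        # oracle: per-subject grouped sums
        for j, sub in enumerate(["sub0", "sub1", "sub2", "sub3"]):
            expected = counts[:, 2 * j] + counts[:, 2 * j + 1]
            assert (out.counts[sub].to_numpy() == expected).all()

    def test_subject_without_samples_raises(self):
        cm = toy_matrix(
            np.array([[1]]), ["s1"], ["A"], {"A": "Phen1", "B": "nonPhen1"}
        )
        with pytest.raises(ValueError, match="zero samples"):
            ep.collapse_replicates(cm)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 50, size=30)
        counts = pd.DataFrame(np.column_stack([col] * 4), columns=list("abcd"))
        sf = ep.size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_doubles_factor(self, rng):
        col = rng.integers(10, 100, size=50)
        counts = pd.DataFrame({"a": col, "b": col * 2})
        sf = ep.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-6)

    def test_single_subject_factor_is_one(self):
        counts = pd.DataFrame({"a": [5, 10, 20]})
        assert ep.size_factors(counts)["a"] == pytest.approx(1.0)

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="nonzero counts in every subject"):
            ep.size_factors(counts)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ep.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        out = ep.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ep.bh_adjust([0.5, 1.2])

    @staticmethod
    def brute_force(p):
        """Literal step-up: padj_(i) = min over j>=i of p_(j) * m / j, capped at 1."""
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        out = np.empty(m)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
            ]
            out[idx] = min(1.0, min(candidates))
        return out

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(ep.bh_adjust(p), self.brute_force(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_output_dominates_input(self, p):
        out = ep.bh_adjust(p)
        assert (out >= np.asarray(p) - 1e-15).all()
        assert (out <= 1.0).all()


class TestDifferentialExpression:
    def test_constant_gene_has_zero_lfc(self):
        counts = np.full((5, 8), 20)
        samples = [f"s{i}" for i in range(8)]
        subjects = samples
        groups = {s: ("Phen1" if i < 4 else "nonPhen1") for i, s in enumerate(samples)}
        cm = toy_matrix(counts, samples, subjects, groups)
        sig = ep.differential_expression(cm, reference="nonPhen1")
        assert np.allclose(sig["log2FoldChange"], 0.0, atol=1e-6)

    def test_small_group_rejected(self):
        counts = np.full((5, 3), 10)
        samples = ["a", "b", "c"]
        groups = {"a": "Phen1", "b": "nonPhen1", "c": "nonPhen1"}
        cm = toy_matrix(counts, samples, samples, groups)
        with pytest.raises(ValueError, match="fewer than 2"):
            ep.differential_expression(cm)

    def test_all_zero_gene_reported_as_nan(self, rng):
        counts = rng.integers(5, 50, size=(10, 8))
        counts[3] = 0
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("Phen1" if i < 4 else "nonPhen1") for i, s in enumerate(samples)}
        cm = toy_matrix(counts, samples, samples, groups)
        sig = ep.differential_expression(cm)
        assert np.isnan(sig.iloc[3]["pvalue"])
        assert sig["pvalue"].drop(sig.index[3]).notna().all()

    def test_planted_effect_recovered(self, small_expression):
        cm, truth = small_expression
        sig = ep.differential_expression(cm, reference="nonPhen1")
        targets = list(truth.target_set.members)
        assert sig.loc[targets, "log2FoldChange"].median() == pytest.approx(2.0, abs=0.4)
        assert (sig.loc[targets, "padj"] < 0.05).mean() >= 0.9

    def test_agrees_with_deseq2_style_reference(self):
        """Cross-check fold changes against pydeseq2 on a small dataset."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = ep.ExpressionSimConfig(
            n_genes=300, target_set_size=20, n_per_group=6, seed=21
        )
        cm, _ = ep.gen_expression(cfg)
        collapsed = ep.collapse_replicates(cm)
        sig = ep.differential_expression(cm, reference="nonPhen1")

        meta = pd.DataFrame(
            {"condition": collapsed.subject_group.loc[collapsed.counts.columns]}
        )
        dds = DeseqDataSet(
            counts=collapsed.counts.T,
            metadata=meta,
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        res = DeseqStats(
            dds, contrast=["condition", "Phen1", "nonPhen1"], quiet=True
        )
        res.summary()
        ref = res.results_df["log2FoldChange"]
        both = sig["log2FoldChange"].dropna().index.intersection(ref.dropna().index)
        r = np.corrcoef(sig.loc[both, "log2FoldChange"], ref.loc[both])[0, 1]
        assert r > 0.95


class TestRankedSignature:
    @staticmethod
    def sig_and_counts(lfcs, pvals, medians):
        genes = [f"g{i}" for i in range(len(lfcs))]
        sig = pd.DataFrame(
            {"log2FoldChange": lfcs, "pvalue": pvals, "padj": pvals}, index=genes
        )
        counts = pd.DataFrame(
            {f"s{j}": medians for j in range(3)}, index=genes
        )
        return sig, counts

    def test_median_exactly_ten_excluded(self):
        sig, counts = self.sig_and_counts(
            [3, 2, 1, -1, -2], [0.01] * 5, [10, 20, 20, 20, 20]
        )
        rs = ep.ranked_signature(sig, counts, k=2, min_median=10)
        assert "g0" not in rs.genes

    def test_k1_toy(self):
        sig, counts = self.sig_and_counts([2.0, 0.0, -1.0], [0.01] * 3, [50, 50, 50])
        rs = ep.ranked_signature(sig, counts, k=1)
        assert rs.up_set == ["g0"] and rs.down_set == ["g2"]

    def test_tie_break_by_pvalue_then_id(self):
        sig, counts = self.sig_and_counts(
            [1.0, 1.0, 1.0, -2.0], [0.5, 0.01, 0.01, 0.2], [50] * 4
        )
        rs = ep.ranked_signature(sig, counts, k=1)
        # order: ties in lfc resolved by smaller p, then lexicographic id
        assert rs.genes[:3] == ["g1", "g2", "g0"]

    def test_insufficient_genes_error_reports_count(self):
        sig, counts = self.sig_and_counts([1, -1, 0], [0.1] * 3, [50, 50, 5])
        with pytest.raises(ValueError, match="only 2 genes"):
            ep.ranked_signature(sig, counts, k=2)


class TestPCAClassify:
    def test_gene_order_invariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(12, 30)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"g{i}" for i in range(30)],
        )
        genes = [f"g{i}" for i in range(10)]
        a = ep.pca_classify(expr, genes)
        b = ep.pca_classify(expr, genes[::-1])
        for col in ["PC1", "PC2"]:
            assert np.allclose(a[col], b[col]) or np.allclose(a[col], -b[col])

    def test_two_subjects_flagged_degenerate(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 5)), columns=[f"g{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="degenerate"):
            coords = ep.pca_classify(expr, [f"g{i}" for i in range(5)])
        assert np.allclose(coords["PC2"], 0.0, atol=1e-8)

    def test_planted_groups_separate(self, rng):
        base = np.zeros((20, 50))
        base[:10, :25] += 3.0
        expr = pd.DataFrame(
            base + rng.normal(0, 0.2, size=(20, 50)),
            columns=[f"g{i}" for i in range(50)],
        )
        coords = ep.pca_classify(expr, list(expr.columns))
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[:10].min() > pc1[10:].max())


class TestLOOCV:
    def test_perfect_separation_scores_one(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (8, 2)), rng.normal(6, 0.2, (8, 2))])
        coords = pd.DataFrame(X, columns=["PC1", "PC2"])
        y = ["a"] * 8 + ["b"] * 8
        assert ep.loocv_logistic(coords, y) == 1.0

    def test_null_accuracy_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 2))
            y = np.array([0] * 10 + [1] * 10)
            accs.append(ep.loocv_logistic(pd.DataFrame(X), y))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_matches_sklearn_fold_by_fold(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        ours = ep.loocv_logistic(pd.DataFrame(X), y)
        correct = 0
        for i in range(10):
            mask = np.ones(10, bool)
            mask[i] = False
            clf = LogisticRegression(C=1e8, max_iter=5000).fit(X[mask], y[mask])
            correct += int(clf.predict(X[[i]])[0] == y[i])
        assert ours == pytest.approx(correct / 10)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="two classes"):
            ep.loocv_logistic(pd.DataFrame(X), ["a"] * 6)


class TestPermutationNull:
    def test_same_seed_reproduces_null_scores(self, rng):
        X = rng.normal(size=(12, 2))
        y = [0] * 6 + [1] * 6
        a = ep.permutation_null(pd.DataFrame(X), y, n_iter=50, seed=3)
        b = ep.permutation_null(pd.DataFrame(X), y, n_iter=50, seed=3)
        assert np.array_equal(a.null_scores, b.null_scores)

    def test_separated_data_has_small_p(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
        y = [0] * 10 + [1] * 10
        rep = ep.permutation_null(pd.DataFrame(X), y, n_iter=1000, seed=0)
        assert rep.loocv_accuracy == 1.0
        assert rep.permutation_p <= 0.02

    def test_invalid_iterations_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="n_iter"):
            ep.permutation_null(pd.DataFrame(X), [0, 0, 0, 1, 1, 1], n_iter=0)

    def test_add_one_estimator_never_zero(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(9, 0.1, (5, 2))])
        rep = ep.permutation_null(pd.DataFrame(X), [0] * 5 + [1] * 5, n_iter=20, seed=1)
        assert rep.permutation_p >= 1 / 21
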