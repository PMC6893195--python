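"""SVM ensemble training, cost tuning, ROC/AUC and FPR calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netprio import FunctionalNetwork
from netprio.geneset_modules import FunctionalModule
from netprio.network_io import GeneLookupError
from netprio.svm_ensemble import (
    FeatureMatrix,
    INITIAL_COST_GRID,
    build_feature_matrix,
    gene_fpr,
    roc_and_auc,
    sample_negatives,
    train_ensemble,
    tune_cost,
)


def mannwhitney_auc(scores, positives, negatives):
    """Rank-statistic oracle: U / (n+ * n-), ties counted half."""
    pos = np.array([scores[g] for g in sorted(positives)])
    neg = np.array([scores[g] for g in sorted(negatives)])
    u = 0.0
    for p in pos:
        u += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return u / (len(pos) * len(neg))


class TestFeatureMatrix:
    def test_complete_graph_all_ones_zero_diagonal(self):
        genes = ["a", "b", "c"]
        edges = {(x, y): 1.0 for i, x in enumerate(genes) for y in genes[i + 1 :]}
        net = FunctionalNetwork(edges)
        fm = build_feature_matrix(net, genes, genes)
        assert np.allclose(fm.values, 1 - np.eye(3))

    def test_matches_hand_table(self, toy_net):
        fm = build_feature_matrix(toy_net, ["g1", "g2", "g4", "g5"], ["g2", "g3"])
        expected = np.array([[0.8, 0.3], [0.0, 0.5], [0.0, 0.9], [0.0, 0.0]])
        assert np.allclose(fm.values, expected)

    def test_row_gene_absent_is_error(self, toy_net):
        with pytest.raises(GeneLookupError):
            build_feature_matrix(toy_net, ["gX"], ["g1"])

    def test_empty_positives_is_error(self, toy_net):
        with pytest.raises(ValueError):
            build_feature_matrix(toy_net, ["g1"], [])


class TestSampleNegatives:
    def test_excludes_positives(self, rng):
        universe = [f"g{i}" for i in range(10)]
        out = sample_negatives(universe, universe[:3], 3, rng)
        assert len(out) == 3 and not set(out) & set(universe[:3])

    def test_seed_reproducibility(self):
        universe = [f"g{i}" for i in range(50)]
        a = sample_negatives(universe, universe[:5], 10, np.random.default_rng(9))
        b = sample_negatives(universe, universe[:5], 10, np.random.default_rng(9))
        assert a == b

    def test_whole_complement(self, rng):
        universe = [f"g{i}" for i in range(8)]
        out = sample_negatives(universe, universe[:3], 5, rng)
        assert sorted(out) == sorted(universe[3:])

    def test_shortfall_error(self, rng):
        with pytest.raises(ValueError, match="short by"):
            sample_negatives(["a", "b"], ["a"], 2, rng)


class TestTuneCost:
    def test_initial_grid_is_decade_sequence(self):
        assert np.allclose(INITIAL_COST_GRID, [1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1, 10, 100])

    def test_separable_features_reach_accuracy_one(self, rng):
        n = 40
        X = np.zeros((n, 2))
        X[: n // 2, 0] = 1.0  # positives connect to positives
        X[n // 2 :, 1] = 1.0
        genes = [f"g{i}" for i in range(n)]
        labels = {g: (1 if i < n // 2 else -1) for i, g in enumerate(genes)}
        fm = FeatureMatrix(genes, ["p1", "p2"], X, labels)
        res = tune_cost(fm, folds=5, rng=rng)
        assert max(res.cv_accuracy.values()) == 1.0
        assert len(res.final_grid) == 8
        assert res.best_cost in res.final_grid

    def test_degenerate_labels_error(self, rng):
        fm = FeatureMatrix(["a", "b"], ["p"], np.zeros((2, 1)), {"a": 1, "b": 1})
        with pytest.raises(ValueError, match="single class"):
            tune_cost(fm, folds=2, rng=rng)


class TestTrainEnsemble:
    def test_planted_module_separation(self, small_planted):
        cfg, net, truth = small_planted
        members = sorted(g for g, m in truth.module_membership.items() if m == 0)
        mod = FunctionalModule("t", 1, frozenset(members))
        es = train_ensemble(
            net, mod, list(net.nodes), n_runs=3, rng=np.random.default_rng(7), folds=5
        )
        inside = np.mean([es.mean_score[g] for g in members])
        outside = np.mean(
            [es.mean_score[g] for g in net.nodes if g not in mod.genes]
        )
        assert inside > outside

    def test_single_run_counts(self, small_planted):
        cfg, net, truth = small_planted
        members = sorted(g for g, m in truth.module_membership.items() if m == 0)[:20]
        mod = FunctionalModule("t", 1, frozenset(members))
        es = train_ensemble(
            net, mod, list(net.nodes)[:100] + members, n_runs=1,
            rng=np.random.default_rng(3), folds=5,
        )
        assert es.n_runs == 1 and len(es.per_run_scores) == 1
        assert set(es.per_run_scores[0]) == set(es.mean_score)

    def test_uninformative_features_auc_half(self):
        # a network whose edges never touch the module: all-zero features
        mod_genes = [f"m{i}" for i in range(10)]
        others = [f"o{i}" for i in range(40)]
        edges = {(others[0], others[1]): 0.5}
        net = FunctionalNetwork(edges, extra_nodes=mod_genes + others)
        mod = FunctionalModule("t", 1, frozenset(mod_genes))
        es = train_ensemble(
            net, mod, mod_genes + others, n_runs=2, rng=np.random.default_rng(1), folds=2
        )
        roc = roc_and_auc(es.mean_score, set(mod_genes), set(others))
        assert roc.auc == pytest.approx(0.5, abs=0.1)

    def test_tiny_module_rejected(self, toy_net):
        mod = FunctionalModule("t", 1, frozenset(["g1"]))
        with pytest.raises(ValueError):
            train_ensemble(toy_net, mod, list(toy_net.nodes), n_runs=1)

    def test_fpr_monotone_in_score(self, small_planted):
        cfg, net, truth = small_planted
        members = sorted(g for g, m in truth.module_membership.items() if m == 0)
        mod = FunctionalModule("t", 1, frozenset(members))
        es = train_ensemble(
            net, mod, list(net.nodes), n_runs=2, rng=np.random.default_rng(5), folds=5
        )
        ranked = sorted(es.mean_score.items(), key=lambda kv: -kv[1])
        fprs = [es.fpr[g] for g, _ in ranked]
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"p1": 3.0, "p2": 2.0, "n1": 1.0, "n2": 0.0}
        roc = roc_and_auc(scores, {"p1", "p2"}, {"n1", "n2"})
        assert roc.auc == 1.0
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(1000)]
        scores = {g: float(rng.normal()) for g in genes}
        roc = roc_and_auc(scores, set(genes[:500]), set(genes[500:]))
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_overlapping_labels_error(self):
        with pytest.raises(ValueError, match="overlap"):
            roc_and_auc({"a": 1.0, "b": 0.0}, {"a"}, {"a", "b"})

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        scores = {g: float(rng.integers(0, 5)) for g in genes}  # heavy ties
        roc = roc_and_auc(scores, set(genes[:25]), set(genes[25:]))
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 25))
        n_neg = int(rng.integers(2, 25))
        genes = [f"g{i}" for i in range(n_pos + n_neg)]
        # discrete scores force ties, the hard case for trapezoid vs ranks
        scores = {g: float(rng.integers(0, 6)) for g in genes}
        pos, neg = set(genes[:n_pos]), set(genes[n_pos:])
        roc = roc_and_auc(scores, pos, neg)
        assert roc.auc == pytest.approx(mannwhitney_auc(scores, pos, neg), abs=1e-12)


class TestGeneFpr:
    def test_top_gene_hits_floor(self):
        scores = {f"n{i}": float(i) for i in range(10)}
        scores["top"] = 100.0
        fpr = gene_fpr(scores, {"top"}, {f"n{i}" for i in range(10)})
        assert fpr["top"] == pytest.approx(0.05)  # 0.5 / 10

    def test_bottom_gene_fpr_one(self):
        scores = {"lo": -5.0, "n1": 0.0, "n2": 1.0}
        fpr = gene_fpr(scores, {"lo"}, {"n1", "n2"})
        assert fpr["lo"] == 1.0

    def test_two_of_ten_negatives_above(self):
        neg = {f"n{i}": float(i) for i in range(10)}  # scores 0..9
        scores = dict(neg)
        scores["g"] = 7.5  # exceeded by n8, n9
        fpr = gene_fpr(scores, {"g"}, set(neg))
        assert fpr["g"] == pytest.approx(0.2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        genes = [f"g{i}" for i in range(n)]
        scores = {g: float(rng.integers(-3, 4)) for g in genes}
        pos = set(genes[: max(1, n // 4)])
        neg = set(genes[max(1, n // 4) :])
        fpr = gene_fpr(scores, pos, neg)
        floor = 0.5 / len(neg)
        for g, s in scores.items():
            fp = sum(1 for x in neg if scores[x] >= s)
            tn = len(neg) - fp
            assert fpr[g] == pytest.approx(max(fp / (fp + tn), floor), abs=0)
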