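"""Negative sampling, dynamic update, metrics, CV protocol, training loop."""

import numpy as np
import pytest

import dgcgrn.training as tr
from dgcgrn.config import RunConfig
from dgcgrn.dgcn import NodeFeatureMatrix
from dgcgrn.io_formats import EdgeList, ExpressionMatrix
from dgcgrn.proximity import DirectedGRN
from dgcgrn.training import (EdgeSplit, FeatureAssembly, auroc_rank,
                             cross_validate, draw_negatives, dynamic_update,
                             evaluate, sample_negatives, train)


def brute_force_auroc(pos, neg):
    """Pairwise-comparison oracle: P(score_pos > score_neg) + 0.5 ties."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestNegativeSampling:
    def test_count_and_disjointness(self):
        rng = np.random.default_rng(0)
        pos = np.array([[i, (i + 1) % 20] for i in range(20)])
        neg = sample_negatives(20, pos, ratio=1.0, seed=1)
        assert len(neg) == 20
        pos_set = {tuple(p) for p in pos}
        assert not pos_set & {tuple(q) for q in neg}
        assert np.all(neg[:, 0] != neg[:, 1])

    def test_deterministic_given_seed(self):
        pos = np.array([[0, 1], [1, 2]])
        a = sample_negatives(10, pos, seed=7)
        b = sample_negatives(10, pos, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_reverse_exclusion_flag(self):
        pos = np.array([[0, 1]])
        # 3 nodes: 6 ordered pairs, minus positive and its reverse leaves 4
        neg = sample_negatives(3, pos, ratio=4.0, seed=0, allow_reverse=False)
        assert (1, 0) not in {tuple(q) for q in neg}

    def test_insufficient_non_edges_raises(self):
        pos = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            sample_negatives(2, pos, ratio=1.0, seed=0)

    def test_known_negatives_used_when_enabled(self):
        pos = np.array([[i, (i + 1) % 10] for i in range(10)])
        known = np.array([[0, 5], [1, 6], [2, 7]])
        cfg_on = RunConfig(keep_known_negatives=True)
        cfg_off = RunConfig(keep_known_negatives=False)
        negs_on = draw_negatives(10, pos, known, cfg_on, seed=0)
        negs_off = draw_negatives(10, pos, known, cfg_off, seed=0)
        assert len(negs_on) == len(negs_off) == 10
        on_set = {tuple(q) for q in negs_on}
        assert {(0, 5), (1, 6), (2, 7)} <= on_set
        assert not {tuple(p) for p in pos} & on_set


class TestDynamicUpdate:
    def _graph(self):
        return DirectedGRN.from_edges(["a", "b", "c"],
                                      [("a", "b"), ("b", "c")])

    def test_weights_replaced_topology_preserved(self):
        g = self._graph()
        g2 = dynamic_update(g, {(0, 1): 0.9, (1, 2): 0.2})
        np.testing.assert_array_equal(g2.A > 0, g.A > 0)
        assert g2.A[0, 1] == 0.9 and g2.A[1, 2] == 0.2

    def test_score_out_of_range_rejected(self):
        g = self._graph()
        with pytest.raises(ValueError):
            dynamic_update(g, {(0, 1): 1.0, (1, 2): 0.5})

    def test_missing_edge_score_rejected(self):
        with pytest.raises(ValueError):
            dynamic_update(self._graph(), {(0, 1): 0.5})

    def test_uniform_scores_give_uniform_weights(self):
        g2 = dynamic_update(self._graph(), {(0, 1): 0.5, (1, 2): 0.5})
        assert set(g2.A[g2.A > 0]) == {0.5}


class TestAUROC:
    def test_perfect_and_inverted_separation(self):
        assert auroc_rank([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auroc_rank([0.1, 0.2], [0.9, 0.8]) == 0.0

    def test_all_ties_give_half(self):
        assert auroc_rank([0.5] * 5, [0.5] * 7) == 0.5

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 30))
            # quantised scores force ties
            pos = rng.integers(0, 10, n_pos) / 10
            neg = rng.integers(0, 10, n_neg) / 10
            assert auroc_rank(pos, neg) == brute_force_auroc(pos, neg)

    def test_random_scores_centre_at_half(self):
        rng = np.random.default_rng(1)
        vals = [auroc_rank(rng.random(40), rng.random(40))
                for _ in range(100)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.5) < 3 * se

    def test_one_class_undefined(self):
        with pytest.raises(ValueError):
            auroc_rank([], [0.1])


class TestEvaluate:
    def test_confusion_counts_and_accuracy(self):
        scores = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                  (1, 2): 0.6, (1, 3): 0.4, (2, 3): 0.3}
        r = evaluate(scores, test_pos=[(0, 1), (0, 2), (0, 3)],
                     test_neg=[(1, 2), (1, 3), (2, 3)])
        assert (r.TP, r.FP, r.TN, r.FN) == (3, 1, 2, 0)
        assert r.ACC == pytest.approx(5 / 6)
        assert r.TPR == 1.0 and r.FPR == pytest.approx(1 / 3)

    def test_perfect_separation_metrics(self):
        scores = {(0, 1): 0.9, (1, 2): 0.1}
        r = evaluate(scores, [(0, 1)], [(1, 2)])
        assert r.AUROC == 1.0 and r.AUPR == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate({(0, 1): 0.5}, [(0, 1)], [])


def toy_instance(n=20, n_edges=30, n_samples=40, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n)]
    pairs = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n, 2)
        if i != j:
            pairs.add((int(i), int(j)))
    pos = np.array(sorted(pairs))
    g = DirectedGRN.from_edges(ids, [(ids[i], ids[j]) for i, j in pos])
    expr = ExpressionMatrix(ids, rng.normal(size=(n, n_samples)))
    el = EdgeList([(ids[i], ids[j], 1.0) for i, j in pos])
    return g, expr, el, pos


class TestTrainLoop:
    def _fit(self, seed, use_dynamic=False, epochs=50):
        g, expr, el, pos = toy_instance(seed=3)
        neg = sample_negatives(g.n, pos, seed=1)
        split = EdgeSplit(pos, neg, pos, neg)
        X = tr._zscore_rows(expr.values)
        assembly = FeatureAssembly(NodeFeatureMatrix(X))
        cfg = RunConfig(epochs=epochs, use_cvae=False,
                        use_dynamic=use_dynamic, warmup=10, dropout=0.2)
        return train(g, assembly, split, cfg, seed=seed)

    def test_loss_decreases_in_moving_average(self):
        fit = self._fit(seed=0)
        losses = [e["loss"] for e in fit.log]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_same_seed_identical_parameters(self):
        f1 = self._fit(seed=4, epochs=15)
        f2 = self._fit(seed=4, epochs=15)
        for a, b in zip(f1.model.params(), f2.model.params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_dynamic_update_only_after_warmup(self):
        fit = self._fit(seed=5, use_dynamic=True, epochs=20)
        flags = [e.get("dynamic", False) for e in fit.log]
        assert not any(flags[:9]) and all(flags[9:])
        w = fit.graph.A[fit.graph.A > 0]
        assert np.all((w > 0) & (w < 1))

    def test_dynamic_disabled_keeps_unit_weights(self):
        fit = self._fit(seed=5, use_dynamic=False, epochs=20)
        assert set(fit.graph.A[fit.graph.A > 0]) == {1.0}


class TestCrossValidation:
    def _cfg(self, **kw):
        base = dict(epochs=8, repeats=2, folds=3, use_cvae=False,
                    use_dynamic=False, dropout=0.0)
        base.update(kw)
        return RunConfig(**base)

    def test_result_count_is_repeats_times_folds(self):
        _, expr, el, _ = toy_instance()
        res = cross_validate(expr, el, self._cfg(), seed=0)
        assert len(res) == 6
        assert {(r.repeat_id, r.fold_id) for r in res} == {
            (r, f) for r in range(2) for f in range(3)}

    def test_folds_partition_positives(self, monkeypatch):
        captured = []

        real_train = tr.train

        def spy(g, assembly, split, cfg, seed=0):
            captured.append(split)
            return real_train(g, assembly, split, cfg, seed=seed)

        monkeypatch.setattr(tr, "train", spy)
        _, expr, el, pos = toy_instance()
        cross_validate(expr, el, self._cfg(repeats=1, epochs=1), seed=0)
        all_test = np.vstack([s.test_pos for s in captured])
        assert {tuple(p) for p in all_test} == {tuple(p) for p in pos}
        sizes = [len(s.test_pos) for s in captured]
        assert sum(sizes) == len(pos)

    def test_no_leakage_into_message_graph(self, monkeypatch):
        """Test positives must never appear as edges of the training graph."""
        seen = []
        real_train = tr.train

        def spy(g, assembly, split, cfg, seed=0):
            g_edges = {tuple(e) for e in g.edge_index()}
            test_edges = {tuple(p) for p in split.test_pos}
            seen.append((g_edges, test_edges))
            return real_train(g, assembly, split, cfg, seed=seed)

        monkeypatch.setattr(tr, "train", spy)
        _, expr, el, _ = toy_instance()
        cross_validate(expr, el, self._cfg(repeats=1, epochs=1), seed=0)
        assert seen
        for g_edges, test_edges in seen:
            assert not g_edges & test_edges

    def test_repeats_use_different_fold_assignments(self, monkeypatch):
        captured = []
        real_train = tr.train

        def spy(g, assembly, split, cfg, seed=0):
            captured.append((split.repeat_id, frozenset(map(tuple,
                                                            split.test_pos))))
            return real_train(g, assembly, split, cfg, seed=seed)

        monkeypatch.setattr(tr, "train", spy)
        _, expr, el, _ = toy_instance()
        cross_validate(expr, el, self._cfg(epochs=1), seed=0)
        rep0 = {f for r, f in captured if r == 0}
        rep1 = {f for r, f in captured if r == 1}
        assert rep0 != rep1

    def test_too_few_positives_rejected(self):
        _, expr, _, _ = toy_instance()
        el = EdgeList([("g0", "g1", 1.0), ("g1", "g2", 1.0)])
        with pytest.raises(ValueError, match="folds"):
            cross_validate(expr, el, self._cfg(folds=5), seed=0)
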