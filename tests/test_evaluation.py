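import numpy as np
import pandas as pd
import pytest

from mtlgrn import evaluation as ev
from mtlgrn.io_formats import EdgeRecord, build_graph


def auroc_concordance_oracle(scores, labels):
    """O(n^2) pair-counting AUROC with midrank tie handling."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLinkMetrics:
    def test_perfect_separation_scores_one_everywhere(self):
        rep = ev.link_metrics(np.array([0.9, 0.8, 0.1, 0.2]),
                              np.array([1, 1, 0, 0]))
        assert (rep.accuracy, rep.auroc, rep.precision, rep.recall, rep.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_constant_half_scores_closed_form(self):
        """All scores 0.5 on balanced labels: predict-positive-at->=0.5 gives
        recall 1, precision 0.5, accuracy 0.5."""
        rep = ev.link_metrics(np.full(8, 0.5), np.array([1, 0] * 4))
        assert rep.recall == 1.0
        assert rep.precision == 0.5
        assert rep.accuracy == 0.5
        assert np.isclose(rep.auroc, 0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            ev.link_metrics(np.array([0.3, 0.4]), np.array([1, 1]))

    def test_auroc_matches_concordance_oracle_with_ties(self, rng):
        for _ in range(25):
            n = rng.integers(4, 31)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            rep = ev.link_metrics(scores, labels)
            assert np.isclose(rep.auroc,
                              auroc_concordance_oracle(scores, labels),
                              atol=1e-12)

    def test_f1_recomputable_from_precision_recall(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        rep = ev.link_metrics(scores, labels)
        if rep.precision + rep.recall > 0:
            assert np.isclose(rep.f1, 2 * rep.precision * rep.recall /
                              (rep.precision + rep.recall), atol=1e-12)

    def test_aggregate_runs_reports_means_and_per_run(self):
        reps = [ev.link_metrics(np.array([0.9, 0.1]), np.array([1, 0])),
                ev.link_metrics(np.array([0.1, 0.9]), np.array([1, 0]))]
        agg = ev.aggregate_runs(reps)
        assert agg.n_runs == 2
        assert np.isclose(agg.auroc, 0.5)
        assert agg.per_run["auroc"] == [1.0, 0.0]


class TestConsensusBinarize:
    def test_three_of_five_votes_keep_the_link(self):
        mats = [np.array([[v]]) for v in (1, 1, 1, 0, 0)]
        assert ev.consensus_binarize(mats)[0, 0] == 1

    def test_two_of_five_votes_drop_the_link(self):
        mats = [np.array([[v]]) for v in (1, 1, 0, 0, 0)]
        assert ev.consensus_binarize(mats)[0, 0] == 0

    def test_matches_sum_threshold_oracle(self, rng):
        stack = (rng.random((5, 10, 10)) < 0.5).astype(int)
        out = ev.consensus_binarize(list(stack), min_votes=3)
        assert np.array_equal(out, (stack.sum(axis=0) >= 3).astype(int))

    def test_consensus_bracketed_by_intersection_and_union(self, rng):
        stack = (rng.random((5, 6, 6)) < 0.4).astype(int)
        out = ev.consensus_binarize(list(stack))
        inter = stack.min(axis=0)
        union = stack.max(axis=0)
        assert (out >= inter).all() and (out <= union).all()

    def test_too_few_runs_raise(self):
        with pytest.raises(ValueError):
            ev.consensus_binarize([np.zeros((2, 2))] * 2, min_votes=3)


class TestKnockoutMetrics:
    def test_perfect_prediction(self, rng):
        pre = rng.standard_normal(10)
        true = pre + rng.standard_normal(10)
        rep = ev.knockout_metrics(true, true, pre)
        assert rep.corr == pytest.approx(1.0)
        assert rep.corr_delta == pytest.approx(1.0)
        assert rep.mse == 0.0
        assert rep.direction_accuracy == 1.0

    def test_copy_control_baseline_has_undefined_delta_correlation(self, rng):
        pre = rng.standard_normal(6)
        true = pre + rng.standard_normal(6)
        with pytest.warns(UserWarning, match="zero variance"):
            rep = ev.knockout_metrics(pre, true, pre)
        assert np.isnan(rep.corr_delta)

    def test_ten_gene_toy_matches_hand_computation(self):
        pre = np.arange(10.0)
        true = pre + np.array([1, -1, 2, 0.5, -0.5, 1, 1, -2, 0.25, 3.0])
        pred = pre + np.array([0.5, -2, 1, 1, -1, 2, -1, -1, 0.5, 2.0])
        rep = ev.knockout_metrics(pred, true, pre)
        assert np.isclose(rep.mse, np.mean((pred - true) ** 2), atol=1e-12)
        c = np.corrcoef(pred, true)[0, 1]
        assert np.isclose(rep.corr, c, atol=1e-12)
        cd = np.corrcoef(pred - pre, true - pre)[0, 1]
        assert np.isclose(rep.corr_delta, cd, atol=1e-12)
        signs_agree = np.sign(pred - pre) == np.sign(true - pre)
        assert np.isclose(rep.direction_accuracy, signs_agree.mean(), atol=1e-12)

    def test_de_subset_selects_largest_changes(self):
        pre = np.zeros(30)
        true = np.zeros(30)
        true[:25] = np.arange(25, 0, -1) * 1.0   # top changes in genes 0..19
        pred = true * 0.9
        rep = ev.knockout_metrics(pred, true, pre, subset="DE")
        manual = np.mean((pred[:20] - true[:20]) ** 2)
        assert np.isclose(rep.mse, manual, atol=1e-12)

    def test_zero_change_genes_excluded_from_direction(self):
        pre = np.zeros(4)
        true = np.array([0.0, 1.0, -1.0, 0.0])
        pred = np.array([5.0, 2.0, -0.5, -9.0])  # wild on zero-change genes
        rep = ev.knockout_metrics(pred, true, pre)
        assert rep.direction_accuracy == 1.0


class TestJaccard:
    def test_set_arithmetic(self):
        assert ev.jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert ev.jaccard(set(), set()) == 1.0
        assert ev.jaccard({"a"}, set()) == 0.0


class TestCentrality:
    def test_star_graph_closed_forms(self):
        edges = [EdgeRecord("hub", leaf) for leaf in ("l1", "l2", "l3", "l4")]
        table = ev.centrality_rank(build_graph(edges))
        hub = table[table.gene == "hub"].iloc[0]
        leaf = table[table.gene == "l1"].iloc[0]
        assert hub.degree == pytest.approx(1.0)
        assert leaf.degree == pytest.approx(0.25)
        assert table.iloc[0].gene == "hub"

    def test_path_middle_node_brokers_all_paths(self):
        g = build_graph([EdgeRecord("a", "b"), EdgeRecord("b", "c")])
        table = ev.centrality_rank(g).set_index("gene")
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)
        assert table.loc["a", "betweenness"] == pytest.approx(0.0)

    def test_matches_independent_igraph_oracle(self, rng):
        import igraph

        n = 12
        adj = (rng.random((n, n)) < 0.35).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        names = [f"g{i:02d}" for i in range(n)]
        recs = [EdgeRecord(names[i], names[j])
                for i, j in zip(*np.nonzero(np.triu(adj, 1)))]
        graph = build_graph(recs, node_universe=names)
        table = ev.centrality_rank(graph).set_index("gene")

        ig = igraph.Graph.Adjacency(graph.adjacency.tolist(), mode="undirected")
        deg = np.array(ig.degree()) / (n - 1)
        bet = np.array(ig.betweenness()) / ((n - 1) * (n - 2) / 2)
        for i, g in enumerate(graph.node_ids):
            assert np.isclose(table.loc[g, "degree"], deg[i], atol=1e-8)
            assert np.isclose(table.loc[g, "betweenness"], bet[i], atol=1e-8)
        comp = max(ig.connected_components(), key=len)
        sub = ig.subgraph(comp)
        ev_scores = np.array(sub.eigenvector_centrality(scale=True))
        for node, val in zip(comp, ev_scores):
            assert np.isclose(table.loc[graph.node_ids[node], "eigenvector"],
                              val, atol=1e-6)

    def test_empty_graph_rejected(self):
        from mtlgrn.io_formats import GeneGraph

        g = GeneGraph([], np.zeros((0, 0), dtype=np.int8), np.zeros(0, bool))
        with pytest.raises(ValueError):
            ev.centrality_rank(g)


class TestTopPredictions:
    def test_full_ranking_when_top_n_exceeds_universe(self, tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        table = ev.top_predictions(ckpt, ckpt.node_ids[0], exclude_known=False,
                                   top_n=10_000)
        assert len(table) == len(ckpt.node_ids) - 1

    def test_exclude_known_removes_training_partners(self, tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        tf = ckpt.node_ids[0]
        t = ckpt.index[tf]
        partners = {ckpt.node_ids[j] for i, j in ckpt.train_pos if i == t} | \
                   {ckpt.node_ids[i] for i, j in ckpt.train_pos if j == t}
        kept = set(ev.top_predictions(ckpt, tf, exclude_known=True,
                                      top_n=10_000).gene)
        dropped = set(ev.top_predictions(ckpt, tf, exclude_known=False,
                                         top_n=10_000).gene) - kept
        assert dropped == partners

    def test_unknown_tf_raises(self, tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        with pytest.raises(KeyError):
            ev.top_predictions(ckpt, "not-a-gene")

    def test_planted_partners_rank_above_non_partners(self, tiny_world,
                                                      tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        A = tiny_world.graph.adjacency
        degrees = A.sum(axis=1)
        tf_idx = int(np.argmax(degrees))
        tf = ckpt.node_ids[tf_idx]
        table = ev.top_predictions(ckpt, tf, exclude_known=False, top_n=10_000)
        rank = {g: r for r, g in enumerate(table.gene)}
        partners = [ckpt.node_ids[j] for j in np.nonzero(A[tf_idx])[0]]
        others = [g for g in ckpt.node_ids if g != tf and g not in partners]
        assert np.median([rank[g] for g in partners]) < \
            np.median([rank[g] for g in others])
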