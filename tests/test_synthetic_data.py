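import numpy as np
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from mtlgrn import synthetic_data as sd


def world_kwargs(**over):
    base = dict(n_genes=40, n_samples=15, d_latent=4, edge_density=0.08,
                noise_sd=0.1, motif_len=6, n_knockouts=5, seed=11,
                promoter_len=120)
    base.update(over)
    return base


class TestMakeWorld:
    def test_same_seed_is_bit_identical(self):
        a = sd.make_world(**world_kwargs())
        b = sd.make_world(**world_kwargs())
        assert np.array_equal(a.latent, b.latent)
        assert np.array_equal(a.graph.adjacency, b.graph.adjacency)
        assert np.array_equal(a.expression.values, b.expression.values)
        assert a.promoters == b.promoters
        assert a.attributes.equals(b.attributes)
        for ka, kb in zip(a.knockouts, b.knockouts):
            assert np.array_equal(ka.pre, kb.pre)
            assert np.array_equal(ka.post, kb.post)

    def test_zero_noise_knockout_follows_propagation_formula(self):
        w = sd.make_world(**world_kwargs(noise_sd=0.0, n_knockouts=3))
        A = w.graph.adjacency
        idx = w.graph.index
        for ko in w.knockouts:
            t = idx[ko.target_gene]
            expected = ko.pre - w.params["knockout_strength"] * A[t] * ko.pre
            expected[t] = 0.0
            assert np.allclose(ko.post, expected, atol=1e-12)
            assert ko.post[t] == 0.0

    def test_calibrated_probabilities_hit_requested_density(self):
        w = sd.make_world(**world_kwargs(n_genes=80))
        iu, ju = np.triu_indices(80, 1)
        logits = (w.latent @ w.latent.T)[iu, ju]
        # recompute the bias the generator must have used
        from mtlgrn.synthetic_data import _calibrate_bias
        b = _calibrate_bias(logits, 0.08)
        assert abs(expit(logits + b).mean() - 0.08) < 1e-8

    def test_realized_density_within_20pct_band(self):
        for seed in range(4):
            w = sd.make_world(**world_kwargs(n_genes=100, edge_density=0.05,
                                             seed=seed))
            n_pairs = 100 * 99 / 2
            density = w.graph.adjacency.sum() / 2 / n_pairs
            assert 0.04 <= density <= 0.06

    def test_latent_scores_dominate_nonedges(self):
        """Dot-product scores of planted edges should nearly separate from
        non-edges (AUROC >= 0.95) under the default latent margin."""
        for seed in range(3):
            w = sd.make_world(**world_kwargs(n_genes=100, edge_density=0.05,
                                             seed=seed))
            iu, ju = np.triu_indices(100, 1)
            scores = expit((w.latent @ w.latent.T)[iu, ju])
            labels = w.graph.adjacency[iu, ju]
            assert roc_auc_score(labels, scores) >= 0.95

    def test_edge_pairs_share_a_promoter_motif(self):
        w = sd.make_world(**world_kwargs(promoter_len=400))
        k = w.params["motif_len"]
        ids = w.graph.node_ids
        for i, j in w.graph.edge_array()[:10]:
            a, b = w.promoters[ids[i]], w.promoters[ids[j]]
            shared = {a[s:s + k] for s in range(len(a) - k + 1)} & \
                     {b[s:s + k] for s in range(len(b) - k + 1)}
            assert shared, f"edge ({ids[i]},{ids[j]}) shares no {k}-mer"

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.make_world(**world_kwargs(edge_density=0.7))
        with pytest.raises(ValueError):
            sd.make_world(**world_kwargs(n_knockouts=0))


class TestSplitEdges:
    def test_sizes_follow_fractions(self, tiny_world):
        split = sd.split_edges(tiny_world.graph, 0.8, 0.1, 0.1, seed=0)
        m = len(tiny_world.graph.edge_array())
        assert len(split.val_pos) == int(round(0.1 * m))
        assert len(split.test_pos) == int(round(0.1 * m))
        assert len(split.train_pos) + len(split.val_pos) + len(split.test_pos) == m

    def test_positive_partition_disjoint_by_pairwise_scan(self, tiny_world):
        split = sd.split_edges(tiny_world.graph, seed=1)
        sets = [set(map(tuple, s)) for s in
                (split.train_pos, split.val_pos, split.test_pos)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])

    def test_negatives_avoid_true_edges_and_are_disjoint(self, tiny_world):
        split = sd.split_edges(tiny_world.graph, seed=2)
        A = tiny_world.graph.adjacency
        negs = np.vstack([split.train_neg, split.val_neg, split.test_neg])
        assert (A[negs[:, 0], negs[:, 1]] == 0).all()
        assert (negs[:, 0] != negs[:, 1]).all()
        assert len({tuple(p) for p in negs.tolist()}) == len(negs)

    def test_dense_graph_exhausts_negatives(self):
        from mtlgrn.io_formats import EdgeRecord, build_graph
        names = list("abcd")
        edges = [EdgeRecord(a, b) for i, a in enumerate(names)
                 for b in names[i + 1:]]
        g = build_graph(edges[:-1])  # complete graph minus one pair
        with pytest.raises(ValueError, match="too dense"):
            sd.split_edges(g, 0.8, 0.1, 0.1, seed=0)

    def test_bad_fractions_rejected(self, tiny_world):
        with pytest.raises(ValueError):
            sd.split_edges(tiny_world.graph, 0.7, 0.1, 0.1, seed=0)


class TestMaskPositives:
    def test_fraction_zero_keeps_everything(self, tiny_world):
        train = sd.split_edges(tiny_world.graph, seed=0).train_pos
        perturbed, masked = sd.mask_positives(train, 0.0, seed=1)
        assert len(masked) == 0
        assert np.array_equal(perturbed.positives, train)

    def test_fraction_counts_floor(self):
        edges = np.array([(i, i + 1) for i in range(200)])
        _, masked = sd.mask_positives(edges, 0.10, seed=0)
        assert len(masked) == 20

    def test_masked_subset_disjoint_from_kept(self, tiny_world):
        train = sd.split_edges(tiny_world.graph, seed=0).train_pos
        perturbed, masked = sd.mask_positives(train, 0.3, seed=5)
        all_set = set(map(tuple, train))
        masked_set = set(map(tuple, masked))
        kept_set = set(map(tuple, perturbed.positives))
        assert masked_set <= all_set
        assert not (masked_set & kept_set)
        assert masked_set | kept_set == all_set

    def test_masks_are_nested_across_fractions(self):
        edges = np.array([(i, i + 1) for i in range(100)])
        _, small = sd.mask_positives(edges, 0.05, seed=9)
        _, large = sd.mask_positives(edges, 0.15, seed=9)
        assert set(map(tuple, small)) <= set(map(tuple, large))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sd.mask_positives(np.zeros((3, 2), dtype=int), 1.0, seed=0)


def test_write_world_round_trips_through_loaders(tmp_path, tiny_world):
    from mtlgrn.training import load_bundle

    sd.write_world(tiny_world, tmp_path)
    bundle = load_bundle(tmp_path)
    assert bundle.graph.node_ids == tiny_world.graph.node_ids
    assert np.array_equal(bundle.graph.adjacency, tiny_world.graph.adjacency)
    assert np.allclose(bundle.expression.values, tiny_world.expression.values,
                       atol=1e-10)
    assert len(bundle.knockouts) == len(tiny_world.knockouts)
    assert bundle.promoters == tiny_world.promoters
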