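"""Word-adjacency networks, topological features, coding classification."""

import numpy as np
import pytest

from ribocirc import netclassify as nc
from ribocirc import simdata
from ribocirc.junctionmap import RMRJ


class TestSequenceToNetwork:
    def test_alternating_sequence_single_heavy_edge(self):
        g = nc.sequence_to_network("ATATAT", w=3)
        assert set(g.nodes) == {"ATA", "TAT"}
        assert g.number_of_edges() == 1
        assert g["ATA"]["TAT"]["weight"] == 3  # three adjacent word pairs

    def test_homopolymer_has_no_self_loop(self):
        g = nc.sequence_to_network("AAAA", w=3)
        assert set(g.nodes) == {"AAA"}
        assert g.number_of_edges() == 0

    def test_sequence_of_word_length_is_single_node(self):
        g = nc.sequence_to_network("ACG", w=3)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_too_short_sequence_gives_empty_network(self):
        assert nc.sequence_to_network("AC", w=3).number_of_nodes() == 0

    def test_words_containing_n_skipped(self):
        g = nc.sequence_to_network("ACGNACG", w=3)
        assert all("N" not in n for n in g.nodes)

    def test_total_edge_weight_counts_distinct_adjacent_pairs(self, rng):
        # conservation law, checked against direct enumeration
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 80))))
            g = nc.sequence_to_network(seq, w=3)
            total = sum(d["weight"] for _, _, d in g.edges(data=True))
            words = [seq[i:i + 3] for i in range(len(seq) - 2)]
            expected = sum(1 for a, b in zip(words, words[1:]) if a != b)
            assert total == expected


class TestNetworkMeasures:
    def test_single_node_all_zero(self):
        g = nc.sequence_to_network("AAAA", w=3)
        assert nc.network_measures(g) == pytest.approx(np.zeros(6))

    def test_path_graph_hand_derived_values(self):
        import networkx as nx
        g = nx.Graph([("A", "B"), ("B", "C")])
        got = nc.network_measures(g)
        # degrees 1,2,1; clustering 0; assortativity -1 (endpoint degrees
        # perfectly anti-correlated); betweenness (0,1,0)/3; ordered-pair
        # mean shortest path (1+1+2)*2/6; edges/nodes 2/3
        expected = [4 / 3, 0.0, -1.0, 1 / 3, 4 / 3, 2 / 3]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_triangle_hand_derived_values(self):
        import networkx as nx
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A")])
        got = nc.network_measures(g)
        # zero degree variance -> assortativity undefined, mapped to 0
        expected = [2.0, 1.0, 0.0, 0.0, 1.0, 1.0]
        assert got == pytest.approx(expected, abs=1e-9)


class TestFeatureVector:
    def test_length_is_six_times_iterations(self):
        assert nc.feature_vector("ACGTACGTAC", w=3, thresholds=10).shape == (60,)

    def test_thresholding_matches_hand_derivation(self):
        # "ATATAT": one edge of weight 3 -> visible for t=0,1,2; the graph
        # is edgeless (2 isolated nodes) from t=3 on
        v = nc.feature_vector("ATATAT", w=3, thresholds=5)
        for t in (0, 1, 2):
            assert v[t * 6] == pytest.approx(1.0)       # mean degree 2*1/2
            assert v[t * 6 + 5] == pytest.approx(0.5)   # edges/nodes
        assert v[18:30] == pytest.approx(np.zeros(12))

    def test_weight_one_edges_vanish_from_iteration_one(self):
        v = nc.feature_vector("ACGTCA", w=3, thresholds=3)
        assert v[6:] == pytest.approx(np.zeros(12))

    def test_threshold_edge_sets_are_nested(self, rng):
        import networkx as nx
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            g = nc.sequence_to_network(seq, w=3)
            prev = None
            for t in range(5):
                edges = {frozenset((u, v)) for u, v, d in g.edges(data=True)
                         if d["weight"] > t}
                if prev is not None:
                    assert edges <= prev
                prev = edges


class TestTrainClassifier:
    def test_separable_toy_reaches_perfect_cv(self):
        # positives: one heavy repeated adjacency; negatives: no edges at
        # weight > 1 -> separable on a single feature threshold
        pos = ["AT" * 20 for _ in range(12)]
        neg = ["ACGTTGCA" + "ACGT" * 8 for _ in range(12)]
        model = nc.train_classifier(pos, neg, cv_folds=3, seed=0, n_trees=1)
        assert model.cv_accuracy == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            nc.train_classifier([], ["ACGTACGT"], seed=0)

    def test_cv_accuracy_on_generator_defaults(self, default_bundle):
        model = nc.train_classifier(default_bundle.train_coding[:100],
                                    default_bundle.train_noncoding[:100],
                                    seed=0)
        assert model.cv_accuracy >= 0.90

    def test_deterministic_given_seed(self, tmp_path, default_bundle):
        pos = default_bundle.train_coding[:40]
        neg = default_bundle.train_noncoding[:40]
        m1 = nc.train_classifier(pos, neg, seed=7)
        m2 = nc.train_classifier(pos, neg, seed=7)
        probe = default_bundle.train_coding[40:60]
        assert m1.predict(probe) == m2.predict(probe)
        p1, p2 = tmp_path / "a.pkl", tmp_path / "b.pkl"
        m1.save(p1)
        m2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert nc.CodingModel.load(p1).predict(probe) == m1.predict(probe)

    def test_training_order_permutation_invariant_for_tree(self, default_bundle):
        pos = default_bundle.train_coding[:30]
        neg = default_bundle.train_noncoding[:30]
        m1 = nc.train_classifier(pos, neg, seed=0, n_trees=1)
        m2 = nc.train_classifier(pos[::-1], neg[::-1], seed=0, n_trees=1)
        probe = default_bundle.train_coding[30:50] + \
            default_bundle.train_noncoding[30:50]
        assert m1.predict(probe) == m2.predict(probe)


def _rmrj(seq, joff=None):
    joff = joff if joff is not None else len(seq) // 2
    return RMRJ("c", 0, len(seq), 4, seq, joff)


class TestClassifyRmrjs:
    def test_training_positive_memorized_as_coding(self):
        pos = ["AT" * 20]
        neg = ["ACGTTGCAGGTCAATCGGATCCGTAGGCTTAACGGTACGT"]
        model = nc.train_classifier(pos, neg, seed=0, n_trees=1)
        records, translated = nc.classify_rmrjs([_rmrj(pos[0])], model)
        assert records[0][1] == nc.LABEL_CODING
        assert translated == ["c"]

    def test_empty_rmrj_list(self, default_bundle):
        model = nc.train_classifier(default_bundle.train_coding[:20],
                                    default_bundle.train_noncoding[:20], seed=0)
        assert nc.classify_rmrjs([], model) == ([], [])

    def test_rmrj_shorter_than_word_labelled_noncoding(self, caplog):
        pos = ["AT" * 20]
        neg = ["ACGTTGCAGGTCAATCGGATCCGTAGGCTTAACGGTACGT"]
        model = nc.train_classifier(pos, neg, seed=0, n_trees=1)
        with caplog.at_level("WARNING"):
            records, translated = nc.classify_rmrjs([_rmrj("ACG", 1)], model)
        assert records[0][1] == nc.LABEL_NONCODING
        assert translated == []

    def test_planted_junction_windows_mostly_coding(self, default_bundle, rng):
        model = nc.train_classifier(default_bundle.train_coding,
                                    default_bundle.train_noncoding, seed=0,
                                    n_trees=100)
        wins = []
        for _ in range(50):
            mono, _ = simdata.plant_translated_circ(
                rng, int(rng.integers(260, 800)), int(rng.integers(20, 90)) * 3)
            L = len(mono)
            lo, hi = int(rng.integers(20, 34)), int(rng.integers(20, 34))
            wins.append(_rmrj((mono * 2)[L - lo:L + hi], lo))
        _, translated = nc.classify_rmrjs(wins, model)
        assert len(translated) >= 45  # >= 90% of planted windows
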