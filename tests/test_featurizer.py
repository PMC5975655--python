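import numpy as np
import pytest

from sematyp.featurizer import (
    build_training_set,
    column_labels,
    entity_type_vector,
    feature_length,
    featurize_path,
    relation_vector,
)
from sematyp.pathfinder import Path, enumerate_constrained_paths, extend_path
from sematyp.semkg import build_graph
from sematyp.vocab import SemanticVocabulary

from conftest import preds_for_edge, random_graph_preds


class TestEntityTypeVector:
    def test_multi_typed_entity(self, edge_fixture_graph, vocab):
        vec = entity_type_vector(edge_fixture_graph, "hydrocortisone", vocab)
        assert vec[vocab.type_index("horm")] >= 2
        assert vec[vocab.type_index("phsu")] >= 1
        assert vec.sum() == vec[vocab.type_index("horm")] + vec[vocab.type_index("phsu")]

    def test_single_mention_one_hot(self, vocab):
        g = build_graph(preds_for_edge("x", "dsyn", "TREATS", "y", "phsu", ["1"]))
        vec = entity_type_vector(g, "x", vocab)
        expected = np.zeros(vocab.n_types, dtype=int)
        expected[vocab.type_index("dsyn")] = 1
        np.testing.assert_array_equal(vec, expected)

    def test_unknown_entity_raises(self, edge_fixture_graph, vocab):
        with pytest.raises(KeyError):
            entity_type_vector(edge_fixture_graph, "nope", vocab)

    def test_matches_recount_over_raw_slots(self, vocab):
        rng = np.random.default_rng(21)
        preds = random_graph_preds(rng, 6, 9, vocab)
        g = build_graph(preds)
        for ent in sorted(g.entities):
            vec = entity_type_vector(g, ent, vocab)
            recount = np.zeros(vocab.n_types, dtype=int)
            for p in preds:
                if p.subject_id == ent:
                    recount[vocab.type_index(p.subject_type)] += 1
                if p.object_id == ent:
                    recount[vocab.type_index(p.object_type)] += 1
            np.testing.assert_array_equal(vec, recount)


class TestRelationVector:
    def test_multi_relation_pair(self, edge_fixture_graph, vocab):
        vec = relation_vector(edge_fixture_graph, "hydrocortisone", "sleep_slow_wave", vocab)
        assert vec[vocab.relation_index("AFFECTS")] == 2
        assert vec[vocab.relation_index("CAUSES")] == 1
        assert vec[vocab.relation_index("TREATS")] == 1

    def test_direction_pooled(self, edge_fixture_graph, vocab):
        a = relation_vector(edge_fixture_graph, "hydrocortisone", "sleep_slow_wave", vocab)
        b = relation_vector(edge_fixture_graph, "sleep_slow_wave", "hydrocortisone", vocab)
        np.testing.assert_array_equal(a, b)

    def test_absent_pair_zero(self, edge_fixture_graph, vocab):
        vec = relation_vector(edge_fixture_graph, "hydrocortisone", "nothing", vocab)
        assert not vec.any()


class TestFeaturizePath:
    def test_headline_dimension(self, full_vocab, triangle_graph):
        """A length-2 therapy path padded to length 4 under the full
        vocabulary yields the canonical 873-entry vector (133*5 + 52*4)."""
        path = Path(("drugA", "targetB", "diseaseC"), target_position=1)
        x = featurize_path(triangle_graph, path, full_vocab, max_len=4)
        assert x.shape == (873,)

    def test_minimal_vocabulary_all_ones(self):
        v = SemanticVocabulary(("t",), ("R",))
        preds = preds_for_edge("a", "t", "R", "b", "t", ["1"])
        preds += preds_for_edge("b", "t", "R", "c", "t", ["2"])
        g = build_graph(preds)
        path = Path(("a", "b", "c"), target_position=1)
        x = featurize_path(g, path, v, max_len=2)
        # interleaved layout [T_E(a), T_R(a,b), T_E(b), T_R(b,c), T_E(c)]
        # with graph-global occurrence counts: b appears in two predications
        np.testing.assert_array_equal(x, [1, 1, 2, 1, 1])

    def test_extension_copies_pre_target_relation_slot(self, vocab, triangle_graph):
        path = Path(("drugA", "targetB", "diseaseC"), target_position=1)
        x = featurize_path(triangle_graph, path, vocab, max_len=4)
        K, M = vocab.n_types, vocab.n_relations
        ext = extend_path(path, 4)
        assert ext.nodes == ("drugA", "targetB", "targetB", "targetB", "diseaseC")
        # assemble by hand from the sub-operations on the extended sequence
        expected = []
        pre_target = relation_vector(triangle_graph, "drugA", "targetB", vocab)
        for i, node in enumerate(ext.nodes):
            expected.append(entity_type_vector(triangle_graph, node, vocab))
            if i < 4:
                a, b = ext.nodes[i], ext.nodes[i + 1]
                expected.append(
                    pre_target if a == b else relation_vector(triangle_graph, a, b, vocab)
                )
        np.testing.assert_array_equal(x, np.concatenate(expected))

    @pytest.mark.parametrize("k,m,max_len", [(1, 1, 2), (4, 3, 3), (133, 52, 4), (7, 9, 5)])
    def test_dimension_law(self, k, m, max_len):
        assert feature_length(
            SemanticVocabulary(
                tuple(f"t{i}" for i in range(k)), tuple(f"R{j}" for j in range(m))
            ),
            max_len,
        ) == k * (max_len + 1) + m * max_len

    def test_slot_conservation(self, vocab):
        rng = np.random.default_rng(31)
        preds = random_graph_preds(rng, 7, 12, vocab)
        g = build_graph(preds)
        nodes = sorted(g.entities)
        # find some length-3 path through the graph
        pset = None
        for d in nodes:
            for s in nodes:
                if d >= s:
                    continue
                for t in nodes:
                    if t in (d, s):
                        continue
                    found = enumerate_constrained_paths(g, d, s, t, 4)
                    if len(found):
                        pset = found
                        break
                if pset:
                    break
            if pset:
                break
        assert pset, "fixture should contain at least one constrained path"
        path = pset.paths[0]
        x = featurize_path(g, path, vocab, 4)
        K, M = vocab.n_types, vocab.n_relations
        ext = extend_path(path, 4)
        offset = 0
        for i, node in enumerate(ext.nodes):
            ent_slot = x[offset : offset + K]
            assert ent_slot.sum() == sum(g.type_counts[node].values())
            offset += K
            if i < 4:
                offset += M

    def test_vocab_permutation_equivariance(self, vocab, triangle_graph):
        rng = np.random.default_rng(4)
        tperm = rng.permutation(vocab.n_types)
        rperm = rng.permutation(vocab.n_relations)
        permuted = SemanticVocabulary(
            tuple(vocab.entity_types[i] for i in tperm),
            tuple(vocab.relation_types[j] for j in rperm),
        )
        path = Path(("drugA", "targetB", "diseaseC"), target_position=1)
        x = featurize_path(triangle_graph, path, vocab, 4)
        xp = featurize_path(triangle_graph, path, permuted, 4)
        K, M = vocab.n_types, vocab.n_relations
        offset = 0
        for i in range(5):
            np.testing.assert_array_equal(
                xp[offset : offset + K], x[offset : offset + K][tperm]
            )
            offset += K
            if i < 4:
                np.testing.assert_array_equal(
                    xp[offset : offset + M], x[offset : offset + M][rperm]
                )
                offset += M

    def test_column_labels_cover_every_position(self, vocab):
        assert len(column_labels(vocab, 4)) == feature_length(vocab, 4)

    def test_log1p_transform_option(self, vocab, triangle_graph):
        path = Path(("drugA", "targetB", "diseaseC"), target_position=1)
        raw = featurize_path(triangle_graph, path, vocab, 4)
        damped = featurize_path(triangle_graph, path, vocab, 4, transform="log1p")
        np.testing.assert_allclose(damped, np.log1p(raw))

    def test_training_matrix_export_round_trip(self, vocab, triangle_graph, tmp_path):
        import json

        from sematyp.featurizer import save_training_matrix

        examples, _ = build_training_set(
            triangle_graph, [("drugA", "targetB", "diseaseC")], [], vocab, 4
        )
        prefix = str(tmp_path / "train")
        save_training_matrix(examples, prefix, vocab, 4)
        lines = (tmp_path / "train.tsv").read_text().strip().splitlines()
        sidecar = json.loads((tmp_path / "train.columns.json").read_text())
        assert len(lines) == 1 + len(examples)
        assert lines[0].split("\t")[1:] == sidecar["columns"]
        first = lines[1].split("\t")
        assert first[0] == "1"
        np.testing.assert_array_equal(
            np.array(first[1:], dtype=int), examples[0].x
        )


class TestBuildTrainingSet:
    def test_single_path_positive(self, triangle_graph, vocab):
        examples, counts = build_training_set(
            triangle_graph, [("drugA", "targetB", "diseaseC")], [], vocab, 4
        )
        assert len(examples) == 1
        assert examples[0].y == 1
        assert counts[("drugA", "targetB", "diseaseC")] == 1

    def test_pathless_triple_contributes_nothing(self, triangle_graph, vocab):
        examples, counts = build_training_set(
            triangle_graph, [("drugA", "diseaseC", "targetB")], [], vocab, 4
        )
        assert examples == []
        assert counts[("drugA", "diseaseC", "targetB")] == 0

    def test_counts_match_enumeration(self, vocab):
        rng = np.random.default_rng(8)
        preds = random_graph_preds(rng, 8, 14, vocab)
        g = build_graph(preds)
        nodes = sorted(g.entities)
        triples = [tuple(rng.choice(nodes, size=3, replace=False)) for _ in range(5)]
        triples = [(d, t, s) for d, t, s in triples]
        examples, counts = build_training_set(g, triples, [], vocab, 4)
        assert len(examples) == sum(counts.values())
        for (d, t, s), c in counts.items():
            assert c == len(enumerate_constrained_paths(g, d, s, t, 4))
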