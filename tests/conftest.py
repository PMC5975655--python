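"""Shared fixtures: tiny vocabularies, hand-built graphs, random fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sematyp.semkg import Predication, build_graph
from sematyp.vocab import SemanticVocabulary, default_vocabulary

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocab() -> SemanticVocabulary:
    """Small vocabulary: 4 entity types, 3 relations."""
    return SemanticVocabulary(
        ("dsyn", "phsu", "horm", "topp"),
        ("TREATS", "AFFECTS", "CAUSES"),
    )


@pytest.fixture(scope="session")
def full_vocab() -> SemanticVocabulary:
    return default_vocabulary()


def preds_for_edge(a, ta, rel, b, tb, pmids):
    """One predication per pmid for a single (a, rel, b) key."""
    return [Predication(a, ta, rel, b, tb, str(p)) for p in pmids]


@pytest.fixture()
def edge_fixture_preds():
    """A multi-relation node pair in the style of a literature edge:
    hydrocortisone - 'sleep, slow wave' with three relations, one of them
    extracted from two abstracts, plus the entity typed differently across
    predications (horm vs phsu)."""
    preds = []
    preds += preds_for_edge(
        "hydrocortisone", "horm", "AFFECTS", "sleep_slow_wave", "dsyn",
        ["15714228", "3657191"],
    )
    preds += preds_for_edge(
        "hydrocortisone", "horm", "CAUSES", "sleep_slow_wave", "dsyn", ["3725299"]
    )
    preds += preds_for_edge(
        "hydrocortisone", "phsu", "TREATS", "sleep_slow_wave", "dsyn", ["4495256"]
    )
    return preds


@pytest.fixture()
def edge_fixture_graph(edge_fixture_preds):
    return build_graph(edge_fixture_preds)


@pytest.fixture()
def triangle_graph():
    """drug - target - disease with single edges (the minimal length-2 case)."""
    preds = []
    preds += preds_for_edge("drugA", "phsu", "TREATS", "targetB", "horm", ["1", "2"])
    preds += preds_for_edge("targetB", "horm", "AFFECTS", "diseaseC", "dsyn", ["3", "4"])
    return build_graph(preds)


def random_graph_preds(rng: np.random.Generator, n_nodes: int, n_pairs: int, vocab):
    """Random multigraph predications over generic node names."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    preds = []
    pmid = 0
    pairs = set()
    attempts = 0
    while len(pairs) < n_pairs and attempts < 50 * n_pairs:
        attempts += 1
        a, b = rng.choice(n_nodes, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in pairs:
            continue
        pairs.add(key)
        for _ in range(int(rng.integers(1, 3))):
            rel = vocab.relation_types[int(rng.integers(vocab.n_relations))]
            for _ in range(int(rng.integers(1, 4))):
                pmid += 1
                preds.append(
                    Predication(
                        nodes[int(a)],
                        vocab.entity_types[int(rng.integers(vocab.n_types))],
                        rel,
                        nodes[int(b)],
                        vocab.entity_types[int(rng.integers(vocab.n_types))],
                        str(pmid),
                    )
                )
    return preds
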