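"""Semantic-type path features.

A path drug - e_1 - ... - disease is turned into a flat count vector by
interleaving, slot by slot, the entity semantic-type occurrence vector T_E
(length K) of each node with the relation occurrence vector T_R (length M)
of each adjacent node pair.  A path of length l therefore yields a vector
of length K*(l+1) + M*l; shorter paths are first padded to the model
length by target reduplication, the inserted relation slots copying the
pre-target relation slot.

T_E is graph-global: it counts every retained predication slot in which
the entity appears with each type, not only those on the path's edges.
Counts are raw occurrence numbers; no scaling is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pathfinder import Path, enumerate_constrained_paths, extend_path
from .semkg import KnowledgeGraph
from .vocab import SemanticVocabulary

__all__ = [
    "TrainingExample",
    "entity_type_vector",
    "relation_vector",
    "feature_length",
    "featurize_path",
    "build_training_set",
]


@dataclass(frozen=True)
class TrainingExample:
    """One (feature vector, label) pair with its originating triple and path."""

    x: np.ndarray
    y: int
    drug: str
    target: str
    disease: str
    path_nodes: tuple[str, ...]


def feature_length(vocab: SemanticVocabulary, max_len: int) -> int:
    """K*(max_len+1) + M*max_len."""
    return vocab.n_types * (max_len + 1) + vocab.n_relations * max_len


def entity_type_vector(
    graph: KnowledgeGraph, entity: str, vocab: SemanticVocabulary
) -> np.ndarray:
    """T_E: occurrence count of each semantic type for ``entity`` over all
    retained predications in the graph."""
    if entity not in graph:
        raise KeyError(f"unknown entity {entity!r}")
    vec = np.zeros(vocab.n_types, dtype=np.int64)
    for label, count in graph.type_counts[entity].items():
        vec[vocab.type_index(label)] = count
    return vec


def relation_vector(
    graph: KnowledgeGraph, a: str, b: str, vocab: SemanticVocabulary
) -> np.ndarray:
    """T_R: occurrence count of each relation between a and b, both stored
    directions pooled; zero vector when the pair has no edge."""
    vec = np.zeros(vocab.n_relations, dtype=np.int64)
    for label, (count, _pmids) in graph.relations_between(a, b).items():
        vec[vocab.relation_index(label)] = count
    return vec


def featurize_path(
    graph: KnowledgeGraph,
    path: Path,
    vocab: SemanticVocabulary,
    max_len: int,
    transform: str | None = None,
) -> np.ndarray:
    """Interleaved T_E / T_R concatenation over the path extended to max_len.

    Layout: [T_E(e_0), T_R(e_0,e_1), T_E(e_1), ..., T_R(e_{L-1},e_L), T_E(e_L)]
    with L = max_len.  Inserted target-target relation slots copy the
    relation slot immediately preceding the original target.  Values are
    raw occurrence counts by default; ``transform="log1p"`` applies
    log(1 + count) for workflows that prefer damped magnitudes.
    """
    if transform not in (None, "log1p"):
        raise ValueError("transform must be None or 'log1p'")
    ext = extend_path(path, max_len)
    K, M = vocab.n_types, vocab.n_relations
    out = np.zeros(feature_length(vocab, max_len), dtype=np.int64)
    # pre-target relation slot of the *original* path, reused for padding
    tp = path.target_position
    pre_target_pair = (path.nodes[tp - 1], path.nodes[tp])
    offset = 0
    for i, node in enumerate(ext.nodes):
        out[offset : offset + K] = entity_type_vector(graph, node, vocab)
        offset += K
        if i < max_len:
            a, b = ext.nodes[i], ext.nodes[i + 1]
            if a == b:  # inserted duplicate-target slot
                a, b = pre_target_pair
            out[offset : offset + M] = relation_vector(graph, a, b, vocab)
            offset += M
    if transform == "log1p":
        return np.log1p(out.astype(np.float64))
    return out


def build_training_set(
    graph: KnowledgeGraph,
    positives: Sequence[tuple[str, str, str]],
    negatives: Sequence[tuple[str, str, str]],
    vocab: SemanticVocabulary,
    max_len: int,
    max_paths: int | None = None,
) -> tuple[list[TrainingExample], dict[tuple[str, str, str], int]]:
    """One labeled example per connecting path of each (drug, target, disease).

    Gold triples yield label-1 rows, corrupted triples label-0 rows;
    triples with no connecting path contribute nothing.  Also returns the
    per-triple path counts.
    """
    examples: list[TrainingExample] = []
    path_counts: dict[tuple[str, str, str], int] = {}
    for label, triples in ((1, positives), (0, negatives)):
        for drug, target, disease in triples:
            kwargs = {} if max_paths is None else {"max_paths": max_paths}
            pset = enumerate_constrained_paths(
                graph, drug, disease, target, max_len, **kwargs
            )
            path_counts[(drug, target, disease)] = len(pset)
            for path in pset:
                examples.append(
                    TrainingExample(
                        x=featurize_path(graph, path, vocab, max_len),
                        y=label,
                        drug=drug,
                        target=target,
                        disease=disease,
                        path_nodes=path.nodes,
                    )
                )
    return examples, path_counts


def examples_to_matrix(
    examples: Sequence[TrainingExample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y) float arrays for model fitting."""
    X = np.stack([ex.x for ex in examples]).astype(np.float64)
    y = np.array([ex.y for ex in examples], dtype=np.float64)
    return X, y


def save_training_matrix(
    examples: Sequence[TrainingExample],
    prefix: str,
    vocab: SemanticVocabulary,
    max_len: int,
) -> None:
    """Write examples as <prefix>.tsv (label + feature columns) with a
    <prefix>.columns.json sidecar naming every feature position."""
    import json
    from pathlib import Path as FilePath

    labels = column_labels(vocab, max_len)
    with open(f"{prefix}.tsv", "w", encoding="utf-8") as fh:
        fh.write("label\t" + "\t".join(labels) + "\n")
        for ex in examples:
            fh.write(str(ex.y) + "\t" + "\t".join(str(int(v)) for v in ex.x) + "\n")
    FilePath(f"{prefix}.columns.json").write_text(
        json.dumps({"columns": labels}), encoding="utf-8"
    )


def column_labels(vocab: SemanticVocabulary, max_len: int) -> list[str]:
    """Human-readable name for every feature position (slot + label)."""
    labels: list[str] = []
    for i in range(max_len + 1):
        labels.extend(f"e{i}:{t}" for t in vocab.entity_types)
        if i < max_len:
            labels.extend(f"r{i}:{r}" for r in vocab.relation_types)
    return labels
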