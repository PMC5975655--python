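"""Construction of the semantic knowledge graph from predication records.

A predication is a subject-relation-object assertion extracted from a
biomedical abstract, e.g. ``Hemofiltration |topp TREATS Patients |podg``
with the PubMed id of the source abstract.  Records whose
(subject, relation, object) key was extracted only once are discarded as
likely extraction noise; the survivors are accumulated into an undirected
multigraph whose nodes carry per-semantic-type occurrence counts and whose
node pairs carry per-relation occurrence counts plus pmid provenance.
"""

from __future__ import annotations

import json
import logging
from collections import Counter

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .vocab import SemanticVocabulary

__all__ = [
    "Predication",
    "KnowledgeGraph",
    "parse_predication_file",
    "write_predication_file",
    "filter_predications",
    "build_graph",
    "graph_summary",
]

logger = logging.getLogger(__name__)

N_COLUMNS = 6


@dataclass(frozen=True)
class Predication:
    """One subject-relation-object record with semantic types and provenance."""

    subject_id: str
    subject_type: str
    relation: str
    object_id: str
    object_type: str
    pmid: str

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity used by the occurrence filter: types and pmid ignored."""
        return (self.subject_id, self.relation, self.object_id)


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered node pair."""
    return (a, b) if a <= b else (b, a)


class KnowledgeGraph:
    """Undirected multigraph over entities with typed, counted relations.

    Nodes are opaque entity identifiers.  Each node stores a Counter of
    semantic-type occurrences (one increment per predication slot in which
    the entity appeared with that type).  Each unordered node pair stores,
    per relation label, an occurrence count and the set of source pmids.
    Subject->object direction is recorded separately so a directed
    traversal mode can be offered, but the default traversal is undirected.
    """

    def __init__(self) -> None:
        self.type_counts: dict[str, Counter] = {}
        self.pair_relations: dict[tuple[str, str], dict[str, list]] = {}
        self.adjacency: dict[str, set[str]] = {}
        self.directed_adjacency: dict[str, set[str]] = {}
        self.n_predications: int = 0
        self._csr_stamp: int = -1
        self._csr: tuple | None = None

    def csr_adjacency(self):
        """Cached (matrix, node order, index map) sparse view of the simple
        undirected graph; rebuilt lazily after mutations."""
        stamp = (self.n_predications, len(self.pair_relations))
        if self._csr is None or self._csr_stamp != stamp:
            from scipy.sparse import csr_matrix

            nodes = tuple(sorted(self.type_counts))
            index = {n: i for i, n in enumerate(nodes)}
            rows, cols = [], []
            for a, b in self.pair_relations:
                ia, ib = index[a], index[b]
                rows += (ia, ib)
                cols += (ib, ia)
            n = len(nodes)
            mat = csr_matrix(
                (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
            )
            self._csr = (mat, nodes, index)
            self._csr_stamp = stamp
        return self._csr

    # -- construction ----------------------------------------------------

    def add_predication(self, pred: Predication) -> None:
        for ent, typ in (
            (pred.subject_id, pred.subject_type),
            (pred.object_id, pred.object_type),
        ):
            self.type_counts.setdefault(ent, Counter())[typ] += 1
            self.adjacency.setdefault(ent, set())
            self.directed_adjacency.setdefault(ent, set())
        pair = _pair(pred.subject_id, pred.object_id)
        rels = self.pair_relations.setdefault(pair, {})
        entry = rels.setdefault(pred.relation, [0, set()])
        entry[0] += 1
        entry[1].add(pred.pmid)
        self.adjacency[pred.subject_id].add(pred.object_id)
        self.adjacency[pred.object_id].add(pred.subject_id)
        self.directed_adjacency[pred.subject_id].add(pred.object_id)
        self.n_predications += 1

    # -- queries ---------------------------------------------------------

    @property
    def entities(self) -> set[str]:
        return set(self.type_counts)

    def __contains__(self, entity: str) -> bool:
        return entity in self.type_counts

    def neighbors(self, entity: str, directed: bool = False) -> set[str]:
        adj = self.directed_adjacency if directed else self.adjacency
        return adj.get(entity, set())

    def relations_between(self, a: str, b: str) -> Mapping[str, list]:
        """Relation label -> [occurrence count, pmid set] for the pair (a, b)."""
        return self.pair_relations.get(_pair(a, b), {})

    def edge_weight(self, a: str, b: str) -> int:
        """Total number of predications between a and b (all relations)."""
        return sum(count for count, _ in self.relations_between(a, b).values())

    def iter_pairs(self) -> Iterator[tuple[tuple[str, str], dict[str, list]]]:
        return iter(self.pair_relations.items())

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": {
                ent: dict(counts) for ent, counts in sorted(self.type_counts.items())
            },
            "pairs": [
                {
                    "a": a,
                    "b": b,
                    "relations": {
                        rel: {"count": count, "pmids": sorted(pmids)}
                        for rel, (count, pmids) in sorted(rels.items())
                    },
                }
                for (a, b), rels in sorted(self.pair_relations.items())
            ],
            "n_predications": self.n_predications,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "KnowledgeGraph":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        graph = cls()
        for ent, counts in payload["nodes"].items():
            graph.type_counts[ent] = Counter(counts)
            graph.adjacency.setdefault(ent, set())
            graph.directed_adjacency.setdefault(ent, set())
        for item in payload["pairs"]:
            a, b = item["a"], item["b"]
            rels = {
                rel: [rec["count"], set(rec["pmids"])]
                for rel, rec in item["relations"].items()
            }
            graph.pair_relations[_pair(a, b)] = rels
            graph.adjacency[a].add(b)
            graph.adjacency[b].add(a)
        graph.n_predications = payload["n_predications"]
        return graph


# -- file I/O -------------------------------------------------------------


def parse_predication_file(
    path: str | Path,
    vocab: SemanticVocabulary,
    strict: bool = False,
) -> tuple[list[Predication], int]:
    """Read a 6-column predication TSV.

    Columns: subject_id, subject_type, relation, object_id, object_type,
    pmid.  Lines starting with '#' are comments.  Malformed lines and lines
    with labels missing from the vocabulary are skipped with a warning (or
    raise in strict mode).

    Returns
    -------
    (records, n_skipped)
        Records in file order and the number of skipped lines.
    """
    records: list[Predication] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            problem = None
            if len(parts) != N_COLUMNS:
                problem = f"expected {N_COLUMNS} columns, got {len(parts)}"
            else:
                subj, styp, rel, obj, otyp, pmid = (p.strip() for p in parts)
                if not subj or not obj:
                    problem = "empty subject or object identifier"
                elif not vocab.has_type(styp):
                    problem = f"unknown subject type {styp!r}"
                elif not vocab.has_type(otyp):
                    problem = f"unknown object type {otyp!r}"
                elif not vocab.has_relation(rel):
                    problem = f"unknown relation {rel!r}"
            if problem is not None:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {problem}")
                logger.warning("%s:%d: skipping line (%s)", path, lineno, problem)
                skipped += 1
                continue
            records.append(Predication(subj, styp, rel, obj, otyp, pmid))
    return records, skipped


def write_predication_file(path: str | Path, preds: Iterable[Predication]) -> None:
    """Write predications as a 6-column TSV (inverse of the parser)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in preds:
            fh.write(
                "\t".join(
                    (
                        p.subject_id,
                        p.subject_type,
                        p.relation,
                        p.object_id,
                        p.object_type,
                        p.pmid,
                    )
                )
                + "\n"
            )


# -- filtering and graph building -----------------------------------------


def filter_predications(preds: list[Predication]) -> list[Predication]:
    """Drop predications whose (subject, relation, object) key occurs once.

    Extraction from text is noisy; an assertion supported by a single
    extraction is discarded.  All records of a retained key are kept so
    occurrence counts and pmid provenance survive.
    """
    key_counts = Counter(p.key for p in preds)
    return [p for p in preds if key_counts[p.key] >= 2]


def build_graph(preds: Iterable[Predication]) -> KnowledgeGraph:
    """Accumulate (already filtered) predications into a KnowledgeGraph."""
    graph = KnowledgeGraph()
    for pred in preds:
        graph.add_predication(pred)
    return graph


def graph_summary(graph: KnowledgeGraph) -> dict:
    """Headline counts: entities, relation instances, observed label sets,
    and the ranked distribution of entity semantic types."""
    type_distribution: Counter = Counter()
    for counts in graph.type_counts.values():
        type_distribution.update(counts)
    relation_labels: set[str] = set()
    n_relation_instances = 0
    for rels in graph.pair_relations.values():
        relation_labels.update(rels)
        n_relation_instances += len(rels)
    return {
        "n_entities": len(graph.type_counts),
        "n_pairs": len(graph.pair_relations),
        "n_relation_instances": n_relation_instances,
        "n_predications": graph.n_predications,
        "n_entity_types_observed": len(type_distribution),
        "n_relation_types_observed": len(relation_labels),
        "type_distribution": type_distribution.most_common(),
    }
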