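"""Semantic vocabularies: ordered registries of entity-type and relation labels.

Entities extracted from biomedical text carry UMLS semantic-type
abbreviations ("dsyn" = Disease or Syndrome, "phsu" = Pharmacologic
Substance, ...) and predications carry relation labels ("TREATS",
"AFFECTS", ...).  Feature vectors are indexed by position in these
registries, so the order is significant and must survive serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

__all__ = ["SemanticVocabulary", "default_vocabulary"]


@dataclass(frozen=True)
class SemanticVocabulary:
    """Fixed, ordered label registries for entity types and relations.

    Parameters
    ----------
    entity_types
        Ordered entity-type labels; positions define feature indices 0..K-1.
    relation_types
        Ordered relation labels; positions define feature indices 0..M-1.
    """

    entity_types: tuple[str, ...]
    relation_types: tuple[str, ...]
    _type_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _relation_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_types", tuple(self.entity_types))
        object.__setattr__(self, "relation_types", tuple(self.relation_types))
        if len(set(self.entity_types)) != len(self.entity_types):
            raise ValueError("duplicate entity-type labels")
        if len(set(self.relation_types)) != len(self.relation_types):
            raise ValueError("duplicate relation labels")
        object.__setattr__(
            self, "_type_index", {t: i for i, t in enumerate(self.entity_types)}
        )
        object.__setattr__(
            self, "_relation_index", {r: i for i, r in enumerate(self.relation_types)}
        )

    @property
    def n_types(self) -> int:
        """K, the number of entity semantic types."""
        return len(self.entity_types)

    @property
    def n_relations(self) -> int:
        """M, the number of relation labels."""
        return len(self.relation_types)

    def type_index(self, label: str) -> int:
        return self._type_index[label]

    def relation_index(self, label: str) -> int:
        return self._relation_index[label]

    def has_type(self, label: str) -> bool:
        return label in self._type_index

    def has_relation(self, label: str) -> bool:
        return label in self._relation_index

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the vocabulary to a JSON file, preserving order."""
        payload = {
            "entity_types": list(self.entity_types),
            "relation_types": list(self.relation_types),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SemanticVocabulary":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(tuple(payload["entity_types"]), tuple(payload["relation_types"]))

    @classmethod
    def from_lists(
        cls, entity_types: Sequence[str], relation_types: Sequence[str]
    ) -> "SemanticVocabulary":
        return cls(tuple(entity_types), tuple(relation_types))


def default_vocabulary() -> SemanticVocabulary:
    """The vocabulary shipped with the package: 133 UMLS semantic-type
    abbreviations and 52 relation labels, matching the registries used to
    annotate large-scale predication extractions from the literature."""
    ref = resources.files("sematyp.data").joinpath("default_vocabulary.json")
    payload = json.loads(ref.read_text(encoding="utf-8"))
    return SemanticVocabulary(
        tuple(payload["entity_types"]), tuple(payload["relation_types"])
    )
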