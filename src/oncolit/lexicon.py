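"""Entity lexicons: identifiers, synonym lists and canonical embedding tokens.

A lexicon entry describes one entity (a cancer type, a compound, or a gene)
by the set of surface forms it may take in abstracts and by a single
``embedding_token`` used to replace every synonym before word-vector training
(e.g. all synonyms of liver cancer collapse to ``cancerlivercancer``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

ENTITY_CLASSES = ("cancer", "compound", "gene")


class LexiconError(ValueError):
    """Raised for structurally invalid lexicons or entries."""


@dataclass(frozen=True)
class LexiconEntry:
    """One entity with its synonym list.

    Parameters
    ----------
    entity_id
        Opaque identifier, unique within a lexicon.
    entity_class
        One of ``cancer``, ``compound`` or ``gene``.
    canonical_name
        Preferred surface form; must be among ``synonyms``.
    synonyms
        Non-empty tuple of surface forms matched in text.
    embedding_token
        Single lowercase whitespace-free token substituted for every synonym
        during text normalization; unique across the lexicon.
    """

    entity_id: str
    entity_class: str
    canonical_name: str
    synonyms: tuple[str, ...]
    embedding_token: str

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise LexiconError(
                f"entity_class must be one of {ENTITY_CLASSES}, got {self.entity_class!r}"
            )
        if not self.synonyms:
            raise LexiconError(f"{self.entity_id}: synonyms must be non-empty")
        if self.canonical_name not in self.synonyms:
            raise LexiconError(
                f"{self.entity_id}: canonical name {self.canonical_name!r} not in synonyms"
            )
        tok = self.embedding_token
        if not tok or tok != tok.lower() or any(ch.isspace() for ch in tok):
            raise LexiconError(
                f"{self.entity_id}: embedding token {tok!r} must be lowercase, "
                "non-empty and contain no whitespace"
            )


@dataclass
class EntityLexicon:
    """Collection of :class:`LexiconEntry`, indexed by entity id."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries: Iterable[LexiconEntry]) -> "EntityLexicon":
        lex = cls()
        for entry in entries:
            lex.add(entry)
        return lex

    def add(self, entry: LexiconEntry) -> None:
        if entry.entity_id in self.entries:
            raise LexiconError(f"duplicate entity id {entry.entity_id!r}")
        tokens = {e.embedding_token for e in self.entries.values()}
        if entry.embedding_token in tokens:
            raise LexiconError(
                f"embedding token {entry.embedding_token!r} already used by another entity"
            )
        self.entries[entry.entity_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entries

    def __getitem__(self, entity_id: str) -> LexiconEntry:
        try:
            return self.entries[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity {entity_id!r}") from None

    def ids(self, entity_class: str | None = None) -> list[str]:
        """Entity ids, optionally restricted to one class, in insertion order."""
        if entity_class is None:
            return list(self.entries)
        if entity_class not in ENTITY_CLASSES:
            raise LexiconError(f"unknown entity class {entity_class!r}")
        return [e.entity_id for e in self.entries.values() if e.entity_class == entity_class]

    def subset(self, entity_class: str) -> "EntityLexicon":
        return EntityLexicon.from_entries(
            e for e in self.entries.values() if e.entity_class == entity_class
        )

    def token_for(self, entity_id: str) -> str:
        return self[entity_id].embedding_token

    # -- TSV round trip ----------------------------------------------------
    # Columns: entity_id, class, canonical_name, pipe-separated synonyms,
    # embedding_token.

    def write_tsv(self, destination: str | Path) -> None:
        path = Path(destination)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["entity_id", "class", "canonical_name", "synonyms", "embedding_token"]
            )
            for e in self.entries.values():
                writer.writerow(
                    [e.entity_id, e.entity_class, e.canonical_name, "|".join(e.synonyms), e.embedding_token]
                )

    @classmethod
    def read_tsv(cls, source: str | Path) -> "EntityLexicon":
        path = Path(source)
        lex = cls()
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                return lex
            for row in reader:
                if not row:
                    continue
                if len(row) != 5:
                    raise LexiconError(f"{path}: expected 5 columns, got {len(row)}: {row!r}")
                entity_id, cls_name, canonical, syns, token = row
                lex.add(
                    LexiconEntry(
                        entity_id=entity_id,
                        entity_class=cls_name,
                        canonical_name=canonical,
                        synonyms=tuple(syns.split("|")),
                        embedding_token=token,
                    )
                )
        return lex
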