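"""Dictionary-based entity tagging and the entity->document index.

Matching follows PubMed-style synonym queries: a document matches an entity
iff any of the entity's synonyms occurs in its title or abstract.  Matches
are case-insensitive and anchored at token boundaries (a hit may not be
flanked by letters or digits); overlapping candidates are resolved
longest-match-first, left to right, so each character belongs to at most one
mention.  Two deliberate refinements:

* for every synonym containing hyphens, a variant with hyphens replaced by
  spaces is added automatically (compound names vary in hyphenation);
* short gene symbols (four characters or fewer) are matched
  case-sensitively to limit false positives from common words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .corpus import DocumentCollection
from .lexicon import EntityLexicon

_BOUNDARY_PREFIX = r"(?<![0-9A-Za-z])"
_BOUNDARY_SUFFIX = r"(?![0-9A-Za-z])"
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Mention:
    """One resolved entity mention in a document's title+abstract text."""

    entity_id: str
    char_start: int
    char_end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not self.char_start < self.char_end:
            raise ValueError("char_start must be < char_end")


def _variants(synonyms: Iterable[str], embedding_token: str) -> set[str]:
    out: set[str] = set()
    for syn in synonyms:
        syn = syn.strip()
        if not syn:
            continue
        out.add(syn)
        if "-" in syn:
            out.add(syn.replace("-", " "))
    # the embedding token is matchable so normalization is idempotent
    out.add(embedding_token)
    return out


class EntityMatcher:
    """Compiled matcher for one lexicon; reuse across documents.

    A single alternation regex with alternatives sorted by decreasing length
    implements the leftmost/longest-first resolution rule directly: the scan
    proceeds left to right and at each position the longest synonym anchored
    there wins.
    """

    def __init__(self, lexicon: EntityLexicon) -> None:
        self.lexicon = lexicon
        self._ci_lookup: dict[str, str] = {}  # normalized variant -> entity_id
        self._cs_lookup: dict[str, str] = {}  # exact variant -> entity_id
        alternatives: list[tuple[int, str]] = []
        for entry in lexicon:
            for variant in _variants(entry.synonyms, entry.embedding_token):
                pattern = re.escape(variant)
                # any whitespace run in the synonym matches any run in text
                pattern = _WS.sub(r"\\s+", pattern.replace("\\ ", " "))
                case_sensitive = entry.entity_class == "gene" and len(variant) <= 4
                key = _WS.sub(" ", variant)
                if case_sensitive:
                    self._cs_lookup.setdefault(key, entry.entity_id)
                    alternatives.append((len(variant), pattern))
                else:
                    self._ci_lookup.setdefault(key.casefold(), entry.entity_id)
                    alternatives.append((len(variant), f"(?i:{pattern})"))
        if alternatives:
            alternatives.sort(key=lambda t: (-t[0], t[1]))
            body = "|".join(p for _, p in alternatives)
            self._regex: re.Pattern[str] | None = re.compile(
                f"{_BOUNDARY_PREFIX}(?:{body}){_BOUNDARY_SUFFIX}"
            )
        else:
            self._regex = None

    def _resolve(self, matched: str) -> str | None:
        key = _WS.sub(" ", matched)
        entity = self._cs_lookup.get(key)
        if entity is None:
            entity = self._ci_lookup.get(key.casefold())
        return entity

    def match(self, text: str) -> list[Mention]:
        if not text or self._regex is None:
            return []
        mentions: list[Mention] = []
        for m in self._regex.finditer(text):
            entity = self._resolve(m.group(0))
            if entity is None:
                # a case-sensitive-only variant hit with wrong case via a
                # longer case-insensitive alternative cannot occur; skip
                # defensively if lookup fails
                continue
            mentions.append(
                Mention(
                    entity_id=entity,
                    char_start=m.start(),
                    char_end=m.end(),
                    matched_text=m.group(0),
                )
            )
        return mentions


def match_entities(text: str, lexicon: EntityLexicon | EntityMatcher) -> list[Mention]:
    """Tag one text; convenience wrapper around :class:`EntityMatcher`."""
    matcher = lexicon if isinstance(lexicon, EntityMatcher) else EntityMatcher(lexicon)
    return matcher.match(text)


@dataclass
class CorpusIndex:
    """Entity -> document-id sets over a corpus of known total size.

    ``doc_sets`` has one (possibly empty) entry per lexicon entity;
    ``gene_docs`` is the set of documents containing at least one gene
    mention, the universe used for gene over-representation profiles.
    """

    total_docs: int
    doc_sets: dict[str, set[str]] = field(default_factory=dict)
    gene_docs: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.total_docs < 0:
            raise ValueError("total_docs must be >= 0")

    @property
    def gene_doc_total(self) -> int:
        return len(self.gene_docs)

    def docs(self, entity_id: str) -> set[str]:
        try:
            return self.doc_sets[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity {entity_id!r}") from None

    def count(self, entity_id: str) -> int:
        return len(self.docs(entity_id))

    def overlap(self, entity_a: str, entity_b: str) -> int:
        return len(self.docs(entity_a) & self.docs(entity_b))


def build_index(
    documents: DocumentCollection,
    lexicon: EntityLexicon,
    matcher: EntityMatcher | None = None,
) -> CorpusIndex:
    """Tag every document and collect per-entity document sets.

    Entities with zero occurrences are kept with empty sets rather than
    dropped, so downstream contingency tables always have defined margins.
    """
    if matcher is None:
        matcher = EntityMatcher(lexicon)
    gene_ids = set(lexicon.ids("gene"))
    index = CorpusIndex(
        total_docs=len(documents),
        doc_sets={eid: set() for eid in lexicon.ids()},
        gene_ids=set(gene_ids),
    )
    for doc in documents:
        seen: set[str] = set()
        for mention in matcher.match(doc.text):
            seen.add(mention.entity_id)
        for eid in seen:
            index.doc_sets[eid].add(doc.doc_id)
            if eid in gene_ids:
                index.gene_docs.add(doc.doc_id)
    return index
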