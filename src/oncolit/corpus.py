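"""Abstract collections and their XML serialization.

Documents are stored in a minimal PubMed-article dialect::

    <PubmedArticleSet>
      <PubmedArticle>
        <PMID>123</PMID>
        <ArticleTitle>...</ArticleTitle>
        <AbstractText>...</AbstractText>
      </PubmedArticle>
      ...
    </PubmedArticleSet>

The reader and writer round-trip id, title and abstract losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree


class CorpusError(ValueError):
    """Raised for malformed corpora or corpus files."""


@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    title: str
    abstract: str

    @property
    def text(self) -> str:
        """Title and abstract concatenated, the unit all matching runs on."""
        return f"{self.title} {self.abstract}"


class DocumentCollection:
    """Ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[DocumentRecord] = ()) -> None:
        self._docs: list[DocumentRecord] = []
        self._by_id: dict[str, DocumentRecord] = {}
        for doc in documents:
            self.append(doc)

    def append(self, doc: DocumentRecord) -> None:
        if doc.doc_id in self._by_id:
            raise CorpusError(f"duplicate document id {doc.doc_id!r}")
        self._docs.append(doc)
        self._by_id[doc.doc_id] = doc

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self._docs)

    def __getitem__(self, key: int | str) -> DocumentRecord:
        if isinstance(key, str):
            try:
                return self._by_id[key]
            except KeyError:
                raise KeyError(f"unknown document {key!r}") from None
        return self._docs[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DocumentCollection):
            return NotImplemented
        return self._docs == other._docs

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self._docs]


def write_corpus_xml(documents: DocumentCollection, destination: str | Path) -> None:
    """Write a collection to the minimal PubMed-dialect XML file.

    An empty collection produces a valid file with an empty root element.
    """
    root = etree.Element("PubmedArticleSet")
    for doc in documents:
        art = etree.SubElement(root, "PubmedArticle")
        etree.SubElement(art, "PMID").text = doc.doc_id
        etree.SubElement(art, "ArticleTitle").text = doc.title
        etree.SubElement(art, "AbstractText").text = doc.abstract
    tree = etree.ElementTree(root)
    tree.write(
        str(destination), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


def read_corpus_xml(source: str | Path) -> DocumentCollection:
    """Read a collection written by :func:`write_corpus_xml`; order preserved.

    Raises :class:`CorpusError` on malformed XML (naming the offending
    element where possible), on articles missing a PMID, and on duplicate
    PMIDs.
    """
    path = Path(source)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "PubmedArticleSet":
        raise CorpusError(f"{path}: expected root element PubmedArticleSet, got {root.tag!r}")
    collection = DocumentCollection()
    for art in root.iterfind("PubmedArticle"):
        pmid = art.findtext("PMID")
        if pmid is None:
            raise CorpusError(f"{path}: PubmedArticle without PMID element")
        title = art.findtext("ArticleTitle") or ""
        abstract = art.findtext("AbstractText") or ""
        try:
            collection.append(DocumentRecord(doc_id=pmid, title=title, abstract=abstract))
        except CorpusError as exc:
            raise CorpusError(f"{path}: {exc}") from exc
    return collection
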