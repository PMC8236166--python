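"""Compound co-occurrence networks within one cancer type's publications.

For every unordered pair of compounds the 2x2 table is built inside the
cancer's document set (both / A only / B only / neither, with N equal to the
cancer's publication count) and scored with the one-sided Fisher test.
Edges whose -log10 p exceeds a threshold (default 50) form the co-occurrence
graph used for combination and repositioning queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx

from .enrichment import (
    DEFAULT_CAP,
    AssociationScore,
    ContingencyTable,
    EnrichmentError,
)
from .tagging import CorpusIndex


@dataclass(frozen=True)
class CooccurrenceEdge:
    """One unordered compound pair scored inside one cancer's corpus."""

    cancer_id: str
    compound_a: str
    compound_b: str
    table: ContingencyTable
    neg_log10_p: float  # exact, uncapped

    def __post_init__(self) -> None:
        if self.compound_a == self.compound_b:
            raise EnrichmentError("self-loop edge")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.compound_a, self.compound_b)


@dataclass
class CooccurrenceGraph:
    cancer_id: str
    threshold: float
    edges: list[CooccurrenceEdge] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.compound_a)
            seen.setdefault(e.compound_b)
        return list(seen)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(cancer_id=self.cancer_id, threshold=self.threshold)
        for e in self.edges:
            g.add_edge(
                e.compound_a,
                e.compound_b,
                neg_log10_p=e.neg_log10_p,
                n_both=e.table.a,
            )
        return g


def compound_cooccurrence(
    index: CorpusIndex,
    cancer: str,
    compounds: Sequence[str],
    universe: Literal["cancer", "global"] = "cancer",
) -> list[CooccurrenceEdge]:
    """Score every unordered compound pair within the cancer's documents.

    ``universe='cancer'`` restricts the table to the cancer's publications
    (the default); ``'global'`` uses the whole reference corpus instead,
    which materially changes p-values and is exposed for comparison only.
    Fewer than two compounds yields an empty list.
    """
    cancer_docs = index.docs(cancer)
    if universe == "cancer":
        if not cancer_docs:
            raise EnrichmentError(f"cancer {cancer!r} has an empty document set")
        n_universe = len(cancer_docs)
        doc_sets = {c: index.docs(c) & cancer_docs for c in compounds}
    elif universe == "global":
        n_universe = index.total_docs
        doc_sets = {c: index.docs(c) for c in compounds}
    else:
        raise EnrichmentError(f"unknown universe {universe!r}")
    edges: list[CooccurrenceEdge] = []
    ordered = list(compounds)
    for i, comp_a in enumerate(ordered):
        for comp_b in ordered[i + 1 :]:
            docs_a, docs_b = doc_sets[comp_a], doc_sets[comp_b]
            a = len(docs_a & docs_b)
            b = len(docs_a) - a
            c = len(docs_b) - a
            d = n_universe - a - b - c
            score = AssociationScore.from_table(
                comp_a, comp_b, ContingencyTable(a=a, b=b, c=c, d=d), cap=DEFAULT_CAP
            )
            edges.append(
                CooccurrenceEdge(
                    cancer_id=cancer,
                    compound_a=comp_a,
                    compound_b=comp_b,
                    table=score.table,
                    neg_log10_p=score.neg_log10_p_exact,
                )
            )
    return edges


def build_graph(
    edges: Sequence[CooccurrenceEdge], threshold: float = 50.0
) -> CooccurrenceGraph:
    """Retain edges with -log10 p strictly above the threshold.

    Compounds left without any passing edge are dropped (the node set is
    derived from the retained edges).
    """
    cancer_ids = {e.cancer_id for e in edges}
    if len(cancer_ids) > 1:
        raise EnrichmentError(f"edges span multiple cancers: {sorted(cancer_ids)}")
    cancer_id = next(iter(cancer_ids)) if cancer_ids else ""
    kept = [e for e in edges if e.neg_log10_p > threshold]
    return CooccurrenceGraph(cancer_id=cancer_id, threshold=threshold, edges=kept)


def top_partners(
    edges: Sequence[CooccurrenceEdge], compound: str, k: int | None = None
) -> list[tuple[str, float]]:
    """Partners of one compound ranked by descending significance.

    Ties in -log10 p are broken lexicographically by partner id, so the
    ranking is deterministic.
    """
    known = {e.compound_a for e in edges} | {e.compound_b for e in edges}
    if compound not in known:
        raise KeyError(f"unknown compound {compound!r}")
    partners = []
    for e in edges:
        if compound == e.compound_a:
            partners.append((e.compound_b, e.neg_log10_p))
        elif compound == e.compound_b:
            partners.append((e.compound_a, e.neg_log10_p))
    partners.sort(key=lambda t: (-t[1], t[0]))
    return partners if k is None else partners[:k]


def export_graph(
    graph: CooccurrenceGraph,
    destination: str | Path,
    format: Literal["edge_tsv", "graphml"] = "edge_tsv",
) -> None:
    """Write the graph as a 5-column edge TSV or as GraphML.

    Both formats round-trip losslessly through :func:`read_graph`.
    """
    path = Path(destination)
    if format == "edge_tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("cancer_id\tcompound_a\tcompound_b\tneg_log10_p\tn_both\n")
            for e in graph.edges:
                fh.write(
                    f"{e.cancer_id}\t{e.compound_a}\t{e.compound_b}\t"
                    f"{e.neg_log10_p!r}\t{e.table.a}\n"
                )
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    else:
        raise EnrichmentError(f"unknown format {format!r}")


def read_graph(
    source: str | Path, format: Literal["edge_tsv", "graphml"] = "edge_tsv"
) -> CooccurrenceGraph:
    """Read a graph written by :func:`export_graph`.

    Contingency cells other than the co-mention count are not serialized;
    they are restored as a minimal table carrying ``n_both``.
    """
    path = Path(source)
    if format == "edge_tsv":
        edges: list[CooccurrenceEdge] = []
        cancer_id = ""
        with path.open(encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("cancer_id"):
                raise EnrichmentError(f"{path}: missing edge TSV header")
            for line in fh:
                if not line.strip():
                    continue
                cancer_id, comp_a, comp_b, score, n_both = line.rstrip("\n").split("\t")
                edges.append(
                    CooccurrenceEdge(
                        cancer_id=cancer_id,
                        compound_a=comp_a,
                        compound_b=comp_b,
                        table=ContingencyTable(a=int(n_both), b=0, c=0, d=1),
                        neg_log10_p=float(score),
                    )
                )
        threshold = min((e.neg_log10_p for e in edges), default=0.0)
        return CooccurrenceGraph(cancer_id=cancer_id, threshold=threshold, edges=edges)
    if format == "graphml":
        g = nx.read_graphml(str(path))
        edges = [
            CooccurrenceEdge(
                cancer_id=str(g.graph.get("cancer_id", "")),
                compound_a=u,
                compound_b=v,
                table=ContingencyTable(a=int(data["n_both"]), b=0, c=0, d=1),
                neg_log10_p=float(data["neg_log10_p"]),
            )
            for u, v, data in g.edges(data=True)
        ]
        return CooccurrenceGraph(
            cancer_id=str(g.graph.get("cancer_id", "")),
            threshold=float(g.graph.get("threshold", 0.0)),
            edges=edges,
        )
    raise EnrichmentError(f"unknown format {format!r}")
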