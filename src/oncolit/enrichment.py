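"""Over-representation statistics: Fisher tests, profiles, matrices, clustering.

All association strengths are one-sided Fisher exact tests (upper
hypergeometric tail: probability of observing at least the seen overlap with
all table margins fixed).  Tail sums are evaluated in log space, so p-values
far below the smallest positive double (e.g. 1e-300 and beyond) still yield
exact finite -log10 scores; for display and matrix comparability scores are
truncated at a cap of 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

LN10 = np.log(10.0)
DEFAULT_CAP = 100.0


class EnrichmentError(ValueError):
    """Raised for invalid tables, matrices or parameters."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = target & context, b = target only, c = context only,
    d = neither; N = a+b+c+d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise EnrichmentError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise EnrichmentError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    """One-sided over-representation test result.

    ``neg_log10_p`` is exact and uncapped; ``p_value`` is ``10**-neg_log10_p``
    and underflows to 0.0 below ~1e-308, which is why the log-space score is
    the primary quantity.  ``odds_ratio`` is (a*d)/(b*c), +inf when b*c == 0.
    """

    p_value: float
    neg_log10_p: float
    odds_ratio: float

    @property
    def odds_ratio_infinite(self) -> bool:
        return np.isinf(self.odds_ratio)


def fisher_over_representation(table: ContingencyTable) -> FisherResult:
    """One-sided Fisher exact test, upper tail P(X >= a), margins fixed.

    The overlap X follows a hypergeometric law with population N, a+c
    context successes and a+b target draws.  The tail is summed with
    ``logsumexp`` over log-pmf terms so extreme significances stay finite.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0:
        # upper tail at zero is the whole distribution
        log_p = 0.0
    else:
        k_max = min(a + b, a + c)
        ks = np.arange(a, k_max + 1)
        log_terms = hypergeom.logpmf(ks, table.n, a + c, a + b)
        log_p = float(logsumexp(log_terms))
        log_p = min(log_p, 0.0)  # guard rounding above 1
    neg_log10 = max(0.0, -log_p / LN10)
    p = float(np.exp(log_p))
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p_value=p, neg_log10_p=neg_log10, odds_ratio=float(odds))


@dataclass(frozen=True)
class TruncatedScore:
    score: float
    truncated: bool


def neg_log10_truncated(
    p: float | None = None,
    cap: float = DEFAULT_CAP,
    *,
    neg_log10_p: float | None = None,
) -> TruncatedScore:
    """min(cap, -log10 p); accepts either p in (0,1] or a log-space score.

    ``p = 1`` maps to 0.  A p-value of exactly 0 (an underflowed double) is
    only meaningful with the log-space input, so it is rejected.
    """
    if neg_log10_p is None:
        if p is None:
            raise EnrichmentError("provide p or neg_log10_p")
        if not (0.0 < p <= 1.0):
            raise EnrichmentError(f"p must be in (0, 1], got {p!r} (use neg_log10_p for underflow)")
        neg_log10_p = -np.log10(p)
    if neg_log10_p < 0:
        raise EnrichmentError(f"neg_log10_p must be >= 0, got {neg_log10_p!r}")
    truncated = neg_log10_p > cap
    return TruncatedScore(score=float(min(cap, neg_log10_p)), truncated=truncated)


@dataclass(frozen=True)
class AssociationScore:
    """Scored association between two entities with its contingency table."""

    row_entity: str
    col_entity: str
    table: ContingencyTable
    p_value: float
    odds_ratio: float
    neg_log10_p: float  # capped
    truncated: bool
    neg_log10_p_exact: float  # uncapped log-space score

    @classmethod
    def from_table(
        cls,
        row_entity: str,
        col_entity: str,
        table: ContingencyTable,
        cap: float = DEFAULT_CAP,
    ) -> "AssociationScore":
        res = fisher_over_representation(table)
        trunc = neg_log10_truncated(neg_log10_p=res.neg_log10_p, cap=cap)
        return cls(
            row_entity=row_entity,
            col_entity=col_entity,
            table=table,
            p_value=res.p_value,
            odds_ratio=res.odds_ratio,
            neg_log10_p=trunc.score,
            truncated=trunc.truncated,
            neg_log10_p_exact=res.neg_log10_p,
        )


def publication_association(
    index, compound: str, cancer: str, cap: float = DEFAULT_CAP
) -> AssociationScore:
    """Over-representation of shared publications for one compound-cancer pair.

    a = documents mentioning both, b = compound-only, c = cancer-only,
    d = remainder of the reference corpus.
    """
    comp_docs = index.docs(compound)
    canc_docs = index.docs(cancer)
    a = len(comp_docs & canc_docs)
    b = len(comp_docs) - a
    c = len(canc_docs) - a
    d = index.total_docs - a - b - c
    table = ContingencyTable(a=a, b=b, c=c, d=d)
    return AssociationScore.from_table(compound, cancer, table, cap=cap)


# ---------------------------------------------------------------------------
# gene profiles


@dataclass
class GeneProfile:
    """Ranked list of genes over-represented in one entity's publications.

    The universe is restricted to gene-containing documents: the entity
    column totals are the entity's gene-containing documents, the reference
    column totals the reference corpus's.  Reference cells have the entity
    cells subtracted so the four cells are disjoint.  Rows are ranked by
    ascending p (descending exact -log10 score).
    """

    entity_id: str
    records: pd.DataFrame  # gene_id, doc_count_in_entity, doc_count_in_reference, p_value, odds_ratio, neg_log10_p
    gene_doc_total_entity: int
    gene_doc_total_reference: int

    def specific_genes(self, p_cutoff: float = 0.01, correction: str | None = None) -> set[str]:
        """Genes passing the significance cutoff.

        ``correction=None`` uses raw Fisher p-values (the default scoring
        reports uncorrected p); ``correction='bh'`` applies
        Benjamini-Hochberg before thresholding.
        """
        if self.records.empty:
            return set()
        pvals = self.records["p_value"].to_numpy()
        if correction is None:
            keep = pvals < p_cutoff
        elif correction == "bh":
            from statsmodels.stats.multitest import multipletests

            keep = multipletests(pvals, alpha=p_cutoff, method="fdr_bh")[0]
        else:
            raise EnrichmentError(f"unknown correction {correction!r}")
        return set(self.records.loc[keep, "gene_id"])


def gene_profile(
    index,
    entity: str,
    reference=None,
    gene_ids: Sequence[str] | None = None,
) -> GeneProfile:
    """Per-gene over-representation in one entity's publications.

    ``index`` provides the entity's document set and gene document sets;
    ``reference`` (default: ``index`` itself) provides the reference-corpus
    gene counts and the gene-containing-document totals.
    """
    if reference is None:
        reference = index
    if gene_ids is None:
        gene_ids = sorted(reference.gene_ids)
    entity_docs = index.docs(entity)
    entity_gene_docs = index.gene_docs & entity_docs
    n_entity = len(entity_gene_docs)
    n_reference = reference.gene_doc_total
    if n_entity == 0:
        warnings.warn(
            f"entity {entity!r} has no gene-containing documents; empty profile",
            stacklevel=2,
        )
        empty = pd.DataFrame(
            columns=[
                "gene_id",
                "doc_count_in_entity",
                "doc_count_in_reference",
                "p_value",
                "odds_ratio",
                "neg_log10_p",
            ]
        )
        return GeneProfile(entity, empty, 0, n_reference)
    rows = []
    for gene in gene_ids:
        in_entity = len(reference.docs(gene) & entity_docs)
        in_reference = len(reference.docs(gene))
        table = ContingencyTable(
            a=in_entity,
            b=in_reference - in_entity,
            c=n_entity - in_entity,
            d=n_reference - n_entity - (in_reference - in_entity),
        )
        res = fisher_over_representation(table)
        rows.append(
            {
                "gene_id": gene,
                "doc_count_in_entity": in_entity,
                "doc_count_in_reference": in_reference,
                "p_value": res.p_value,
                "odds_ratio": res.odds_ratio,
                "neg_log10_p": res.neg_log10_p,
            }
        )
    records = pd.DataFrame(rows)
    if not records.empty:
        records = records.sort_values(
            ["neg_log10_p", "gene_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return GeneProfile(entity, records, n_entity, n_reference)


def gene_overlap_association(
    profile_a: GeneProfile,
    profile_b: GeneProfile,
    universe_size: int,
    p_cutoff: float = 0.01,
    correction: str | None = None,
    cap: float = DEFAULT_CAP,
) -> AssociationScore:
    """Over-representation of shared specific genes between two profiles.

    The 2x2 table counts shared genes, A-only, B-only and the remaining gene
    universe (all genes found anywhere in the reference corpus).
    """
    if universe_size <= 0:
        raise EnrichmentError("empty gene universe")
    genes_a = profile_a.specific_genes(p_cutoff=p_cutoff, correction=correction)
    genes_b = profile_b.specific_genes(p_cutoff=p_cutoff, correction=correction)
    a = len(genes_a & genes_b)
    b = len(genes_a) - a
    c = len(genes_b) - a
    d = universe_size - a - b - c
    if d < 0:
        raise EnrichmentError(
            f"universe_size {universe_size} smaller than union of gene sets ({a + b + c})"
        )
    table = ContingencyTable(a=a, b=b, c=c, d=d)
    return AssociationScore.from_table(profile_a.entity_id, profile_b.entity_id, table, cap=cap)


# ---------------------------------------------------------------------------
# association matrices


@dataclass
class AssociationMatrix:
    """Complete compound x cancer score grid with a method tag.

    ``scores`` is a DataFrame with compound ids as rows and cancer ids as
    columns; cells are capped -log10 p (Fisher methods) or cosine
    similarity.  Missing cells (e.g. out-of-vocabulary embedding tokens)
    are NaN and listed in ``metadata['missing_cells']``.
    """

    scores: pd.DataFrame
    method: str
    metadata: dict = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cancers(self) -> list[str]:
        return list(self.scores.columns)

    def write_tsv(self, destination) -> None:
        import json
        from pathlib import Path

        path = Path(destination)
        self.scores.to_csv(path, sep="\t", index_label="compound_id")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"method": self.method, **_jsonable(self.metadata)}, indent=2, sort_keys=True)
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def association_matrix(
    index,
    compounds: Sequence[str],
    cancers: Sequence[str],
    method: Literal["publications", "genes"] = "publications",
    cap: float = DEFAULT_CAP,
    p_cutoff: float = 0.01,
    gene_universe_size: int | None = None,
) -> AssociationMatrix:
    """Full grid of capped -log10 Fisher scores for one method.

    ``publications`` scores the overlap of document sets;``genes`` scores the
    overlap of specific-gene profiles (cutoff ``p_cutoff``, universe size
    defaulting to the number of genes with at least one document).
    Per-cell failures are recorded under ``metadata['missing_cells']``
    instead of aborting the grid.
    """
    grid = pd.DataFrame(
        np.nan, index=list(compounds), columns=list(cancers), dtype=float
    )
    missing: list[tuple[str, str, str]] = []
    meta: dict = {"cap": cap}
    if method == "publications":
        for comp in compounds:
            for canc in cancers:
                try:
                    grid.loc[comp, canc] = publication_association(index, comp, canc, cap=cap).neg_log10_p
                except (KeyError, EnrichmentError) as exc:
                    missing.append((comp, canc, str(exc)))
    elif method == "genes":
        if gene_universe_size is None:
            gene_universe_size = sum(1 for g in index.gene_ids if index.doc_sets.get(g))
        profiles = {e: gene_profile(index, e) for e in list(compounds) + list(cancers)}
        meta["p_cutoff"] = p_cutoff
        meta["gene_universe_size"] = gene_universe_size
        for comp in compounds:
            for canc in cancers:
                try:
                    grid.loc[comp, canc] = gene_overlap_association(
                        profiles[comp], profiles[canc], gene_universe_size, p_cutoff=p_cutoff, cap=cap
                    ).neg_log10_p
                except (KeyError, EnrichmentError) as exc:
                    missing.append((comp, canc, str(exc)))
    else:
        raise EnrichmentError(f"unknown method {method!r}")
    meta["missing_cells"] = missing
    return AssociationMatrix(scores=grid, method=method, metadata=meta)


def cluster_matrix(
    matrix: AssociationMatrix,
    axis: Literal["rows", "columns"] = "rows",
    k: int = 2,
) -> np.ndarray:
    """Average-linkage hierarchical clustering of score rows or columns.

    Euclidean distances, cut to ``k`` flat clusters.  Labels are renumbered
    by first appearance in input order so permuting the inputs permutes the
    labels consistently.
    """
    if axis not in ("rows", "columns"):
        raise EnrichmentError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix.scores.to_numpy(dtype=float)
    if axis == "columns":
        data = data.T
    if k < 2:
        raise EnrichmentError("k must be >= 2")
    if k > data.shape[0]:
        raise EnrichmentError(f"k={k} exceeds axis length {data.shape[0]}")
    if np.isnan(data).any():
        raise EnrichmentError("matrix contains missing cells; fill or drop before clustering")
    link = linkage(data, method="average", metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    return labels


def compare_clusterings(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index (permutation model) between two partitions."""
    if len(labels_a) != len(labels_b):
        raise EnrichmentError(
            f"partitions cover different item sets ({len(labels_a)} vs {len(labels_b)} items)"
        )
    if len(labels_a) == 0:
        raise EnrichmentError("empty partitions")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def matrix_correlation(m1: AssociationMatrix, m2: AssociationMatrix) -> float:
    """Pearson correlation over matched cells of two aligned matrices."""
    if list(m1.scores.index) != list(m2.scores.index) or list(m1.scores.columns) != list(
        m2.scores.columns
    ):
        raise EnrichmentError("matrices must share row and column ids in order")
    x = m1.scores.to_numpy(dtype=float).ravel()
    y = m2.scores.to_numpy(dtype=float).ravel()
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise EnrichmentError("fewer than two matched cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EnrichmentError("correlation undefined for a constant matrix")
    return float(np.corrcoef(x, y)[0, 1])
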