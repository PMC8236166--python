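"""Fisher over-representation core: oracle equivalence, invariants, matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncolit.enrichment import (
    AssociationMatrix,
    ContingencyTable,
    EnrichmentError,
    association_matrix,
    cluster_matrix,
    compare_clusterings,
    fisher_over_representation,
    gene_overlap_association,
    gene_profile,
    matrix_correlation,
    neg_log10_truncated,
    publication_association,
)
from oncolit.tagging import CorpusIndex, build_index

from oracles import (
    ari_pair_counting,
    hypergeom_upper_tail_exact,
    pearson_by_hand,
)

cells = st.integers(min_value=0, max_value=12)


class TestFisher:
    @pytest.mark.parametrize(
        "table, check",
        [
            ((817, 54000, 94000, 2700000), lambda r: round(r.p_value, 2) == 1.00),
            ((5912, 3445, 90000, 2700000), lambda r: r.neg_log10_p > 300),
            ((10000, 68000, 300000, 29000000), lambda r: r.neg_log10_p > 300),
            ((0, 5, 7, 11), lambda r: r.p_value == 1.0),
        ],
    )
    def test_worked_tables(self, table, check):
        """Depleted genes give p = 1; extreme enrichments stay finite in log space."""
        assert check(fisher_over_representation(ContingencyTable(*table)))

    @pytest.mark.parametrize(
        "table",
        [(3, 1, 1, 5), (5, 0, 0, 5), (1, 1, 1, 1), (0, 0, 3, 3), (7, 2, 3, 11), (2, 8, 8, 2)],
    )
    def test_matches_exact_enumeration(self, table):
        expected = float(hypergeom_upper_tail_exact(*table))
        got = fisher_over_representation(ContingencyTable(*table)).p_value
        assert got == pytest.approx(expected, rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_oracle_equivalence_property(self, a, b, c, d):
        """Log-space tail sum equals exact rational enumeration on small tables."""
        if a + b + c + d == 0:
            return
        expected = float(hypergeom_upper_tail_exact(a, b, c, d))
        got = fisher_over_representation(ContingencyTable(a, b, c, d)).p_value
        assert got == pytest.approx(expected, rel=1e-11)

    def test_monotone_in_overlap_with_fixed_margins(self):
        """With margins fixed, p never increases as the overlap grows."""
        row1, col1, n = 10, 12, 40
        last = 1.1
        for a in range(0, min(row1, col1) + 1):
            b = row1 - a
            c = col1 - a
            d = n - a - b - c
            if min(b, c, d) < 0:
                continue
            p = fisher_over_representation(ContingencyTable(a, b, c, d)).p_value
            assert p <= last + 1e-12
            last = p

    def test_odds_ratio_zero_cell_is_flagged_infinite(self):
        res = fisher_over_representation(ContingencyTable(3, 0, 2, 5))
        assert np.isinf(res.odds_ratio) and res.odds_ratio_infinite

    def test_all_zero_table_rejected(self):
        with pytest.raises(EnrichmentError):
            ContingencyTable(0, 0, 0, 0)


class TestNegLog10:
    def test_p_one_maps_to_zero(self):
        assert neg_log10_truncated(1.0).score == 0.0

    def test_cap_and_flag(self):
        res = neg_log10_truncated(1e-150, cap=100)
        assert res.score == 100.0 and res.truncated

    def test_log_space_input(self):
        res = neg_log10_truncated(neg_log10_p=42.5)
        assert res.score == pytest.approx(42.5) and not res.truncated

    def test_invalid_p_rejected(self):
        with pytest.raises(EnrichmentError):
            neg_log10_truncated(0.0)
        with pytest.raises(EnrichmentError):
            neg_log10_truncated(1.5)


def _index_from_sets(n, **sets):
    return CorpusIndex(total_docs=n, doc_sets={k: set(v) for k, v in sets.items()})


class TestPublicationAssociation:
    def test_disjoint_sets_give_p_one(self):
        idx = _index_from_sets(100, drug={"d1", "d2"}, tumor={"d3", "d4"})
        score = publication_association(idx, "drug", "tumor")
        assert score.table.a == 0 and score.p_value == 1.0

    def test_matches_brute_force_counting(self, small_planted_corpus):
        """Index-based cells equal a per-document scan on a 50-doc slice."""
        from oncolit.corpus import DocumentCollection
        from oncolit.tagging import EntityMatcher

        config, docs, lexicon, _ = small_planted_corpus
        subset = DocumentCollection(list(docs)[:50])
        idx = build_index(subset, lexicon)
        comp, canc = config.compound_ids[0], config.cancer_ids[0]
        matcher = EntityMatcher(lexicon)
        both = comp_only = canc_only = neither = 0
        for doc in subset:
            ids = {m.entity_id for m in matcher.match(doc.text)}
            has_comp, has_canc = comp in ids, canc in ids
            both += has_comp and has_canc
            comp_only += has_comp and not has_canc
            canc_only += has_canc and not has_comp
            neither += not has_comp and not has_canc
        score = publication_association(idx, comp, canc)
        assert (score.table.a, score.table.b, score.table.c, score.table.d) == (
            both, comp_only, canc_only, neither,
        )
        expected_p = float(hypergeom_upper_tail_exact(both, comp_only, canc_only, neither))
        assert score.p_value == pytest.approx(expected_p, rel=1e-10)

    def test_symmetric_in_arguments(self, small_planted_corpus):
        config, docs, lexicon, _ = small_planted_corpus
        idx = build_index(docs, lexicon)
        comp, canc = config.compound_ids[1], config.cancer_ids[1]
        ab = publication_association(idx, comp, canc)
        ba = publication_association(idx, canc, comp)
        assert ab.p_value == ba.p_value
        assert (ab.table.a, ab.table.b, ab.table.c) == (ba.table.a, ba.table.c, ba.table.b)

    def test_unknown_entity_named_in_error(self, small_planted_corpus):
        _, docs, lexicon, _ = small_planted_corpus
        idx = build_index(docs, lexicon)
        with pytest.raises(KeyError, match="nonexistent"):
            publication_association(idx, "nonexistent", "cancer000")


class TestGeneProfile:
    def _toy_index(self):
        # 20 docs: entity docs 0-9; gene docs: specific gene in entity docs,
        # omnipresent gene everywhere
        docs_e = {f"d{i}" for i in range(10)}
        g_spec = {f"d{i}" for i in range(8)}
        g_omni = {f"d{i}" for i in range(0, 20, 2)}
        idx = CorpusIndex(
            total_docs=20,
            doc_sets={"ent": docs_e, "gs": g_spec, "go": g_omni},
            gene_docs=g_spec | g_omni,
            gene_ids={"gs", "go"},
        )
        return idx

    def test_specific_gene_ranks_first(self):
        idx = self._toy_index()
        profile = gene_profile(idx, "ent")
        assert list(profile.records["gene_id"])[0] == "gs"

    def test_underrepresented_gene_gets_p_one(self):
        # gene absent from the entity's docs but common in the reference
        docs_e = {"d0", "d1"}
        g_other = {"d5", "d6", "d7", "d8"}
        g_in = {"d0", "d1"}
        idx = CorpusIndex(
            total_docs=10,
            doc_sets={"ent": docs_e, "ga": g_other, "gb": g_in},
            gene_docs=g_other | g_in,
            gene_ids={"ga", "gb"},
        )
        profile = gene_profile(idx, "ent")
        absent = profile.records.set_index("gene_id").loc["ga"]
        assert absent["p_value"] == 1.0
        assert list(profile.records["gene_id"])[-1] == "ga"

    def test_counts_match_brute_force(self, small_planted_corpus):
        config, docs, lexicon, _ = small_planted_corpus
        from oncolit.corpus import DocumentCollection
        from oncolit.tagging import EntityMatcher

        subset = DocumentCollection(list(docs)[:200])
        idx = build_index(subset, lexicon)
        entity = config.cancer_ids[0]
        profile = gene_profile(idx, entity)
        matcher = EntityMatcher(lexicon)
        gene_ids = set(lexicon.ids("gene"))
        ent_docs = [d for d in subset if entity in {m.entity_id for m in matcher.match(d.text)}]
        for rec in profile.records.itertuples():
            brute = sum(
                1
                for d in ent_docs
                if rec.gene_id in {m.entity_id for m in matcher.match(d.text)}
            )
            assert rec.doc_count_in_entity == brute

    def test_entity_without_gene_docs_warns_and_is_empty(self):
        idx = CorpusIndex(
            total_docs=5,
            doc_sets={"ent": {"d0"}, "g": {"d3"}},
            gene_docs={"d3"},
            gene_ids={"g"},
        )
        with pytest.warns(UserWarning, match="no gene-containing"):
            profile = gene_profile(idx, "ent")
        assert profile.records.empty


class TestGeneOverlap:
    def _profile(self, entity, genes, p=1e-4):
        records = pd.DataFrame(
            {
                "gene_id": list(genes),
                "doc_count_in_entity": 5,
                "doc_count_in_reference": 10,
                "p_value": p,
                "odds_ratio": 10.0,
                "neg_log10_p": -np.log10(p),
            }
        )
        return __import__("oncolit.enrichment", fromlist=["GeneProfile"]).GeneProfile(
            entity, records, 50, 500
        )

    def test_identical_sets_beat_partial_overlap(self):
        full = gene_overlap_association(
            self._profile("a", "g1 g2 g3 g4 g5".split()),
            self._profile("b", "g1 g2 g3 g4 g5".split()),
            universe_size=1000,
        )
        partial = gene_overlap_association(
            self._profile("a", "g1 g2 g3 g4 g5".split()),
            self._profile("b", "g1 g2 g3 x y".split()),
            universe_size=1000,
        )
        assert full.p_value < partial.p_value

    def test_disjoint_sets_give_p_one(self):
        score = gene_overlap_association(
            self._profile("a", ["g1", "g2"]),
            self._profile("b", ["g3", "g4"]),
            universe_size=100,
        )
        assert score.p_value == 1.0

    def test_matches_hypergeometric_oracle(self):
        a_genes = [f"a{i}" for i in range(5)] + [f"s{i}" for i in range(5)]
        b_genes = [f"b{i}" for i in range(7)] + [f"s{i}" for i in range(5)]
        score = gene_overlap_association(
            self._profile("a", a_genes), self._profile("b", b_genes), universe_size=100
        )
        expected = float(hypergeom_upper_tail_exact(5, 5, 7, 83))
        assert score.p_value == pytest.approx(expected, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(EnrichmentError):
            gene_overlap_association(
                self._profile("a", ["g1"]), self._profile("b", ["g1"]), universe_size=0
            )


def _matrix(values, method="publications"):
    arr = np.asarray(values, dtype=float)
    return AssociationMatrix(
        scores=pd.DataFrame(
            arr,
            index=[f"r{i}" for i in range(arr.shape[0])],
            columns=[f"c{j}" for j in range(arr.shape[1])],
        ),
        method=method,
    )


class TestMatrixOperations:
    def test_grid_equals_individual_calls(self, small_planted_corpus):
        config, docs, lexicon, _ = small_planted_corpus
        idx = build_index(docs, lexicon)
        compounds = config.compound_ids[:2]
        cancers = config.cancer_ids[:2]
        mat = association_matrix(idx, compounds, cancers)
        for comp in compounds:
            for canc in cancers:
                expected = publication_association(idx, comp, canc).neg_log10_p
                assert mat.scores.loc[comp, canc] == pytest.approx(expected)

    def test_planted_cell_is_row_maximum(self, small_planted_corpus):
        config, docs, lexicon, truth = small_planted_corpus
        idx = build_index(docs, lexicon)
        mat = association_matrix(idx, config.compound_ids, config.cancer_ids)
        for comp, canc in truth.planted_pairs:
            assert mat.scores.loc[comp].idxmax() == canc

    def test_block_diagonal_clusters_recovered(self):
        mat = _matrix(
            [
                [90, 95, 1, 0],
                [85, 92, 2, 1],
                [1, 0, 88, 91],
                [0, 2, 93, 90],
            ]
        )
        labels = cluster_matrix(mat, axis="rows", k=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_identical_rows_share_label(self):
        mat = _matrix([[5, 5, 1], [5, 5, 1], [0, 9, 9]])
        labels = cluster_matrix(mat, axis="rows", k=2)
        assert labels[0] == labels[1]

    def test_row_permutation_permutes_labels(self):
        values = [[90, 1, 2], [88, 0, 1], [1, 70, 60], [2, 75, 65]]
        mat = _matrix(values)
        labels = cluster_matrix(mat, axis="rows", k=2)
        perm = [2, 0, 3, 1]
        mat_p = AssociationMatrix(scores=mat.scores.iloc[perm], method="publications")
        labels_p = cluster_matrix(mat_p, axis="rows", k=2)
        assert compare_clusterings(labels[perm], labels_p) == pytest.approx(1.0)

    def test_k_exceeding_axis_rejected(self):
        with pytest.raises(EnrichmentError):
            cluster_matrix(_matrix([[1, 2], [3, 4]]), k=3)


class TestClusteringComparison:
    def test_identical_partitions_score_one(self):
        assert compare_clusterings([1, 1, 2, 2], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_crossed_partition_matches_oracle(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert compare_clusterings(a, b) == pytest.approx(ari_pair_counting(a, b))
        assert compare_clusterings(a, b) == pytest.approx(-0.5)

    def test_one_cluster_vs_singletons_matches_closed_form(self):
        a, b = [1, 1, 1, 1], [1, 2, 3, 4]
        assert compare_clusterings(a, b) == pytest.approx(ari_pair_counting(a, b))
        assert compare_clusterings(a, b) == pytest.approx(0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(EnrichmentError):
            compare_clusterings([1, 2], [1, 2, 3])


class TestMatrixCorrelation:
    def test_affine_transform_gives_unit_correlation(self):
        m1 = _matrix([[1, 2], [3, 4]])
        m2 = _matrix([[3, 5], [7, 9]])  # 2*m1 + 1
        assert matrix_correlation(m1, m2) == pytest.approx(1.0)

    def test_negated_matrix_gives_minus_one(self):
        m1 = _matrix([[1, 2], [3, 4]])
        m2 = _matrix([[-1, -2], [-3, -4]])
        assert matrix_correlation(m1, m2) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        x = rng.random((5, 5))
        y = rng.random((5, 5))
        expected = pearson_by_hand(list(x.ravel()), list(y.ravel()))
        assert matrix_correlation(_matrix(x), _matrix(y)) == pytest.approx(expected)

    def test_constant_matrix_rejected(self):
        with pytest.raises(EnrichmentError):
            matrix_correlation(_matrix([[1, 1], [1, 1]]), _matrix([[1, 2], [3, 4]]))
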