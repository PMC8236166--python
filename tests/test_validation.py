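"""ROC, IC-50 aggregation and binning, stratification, survival comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncolit.enrichment import AssociationMatrix
from oncolit.validation import (
    BinScheme,
    COSINE_BINS,
    FISHER_BINS,
    ValidationError,
    aggregate_ic50,
    bin_associations,
    compare_ic50_by_bin,
    roc_auc,
    stratify_patients,
    survival_compare,
)

from oracles import auc_pair_counting


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_example_matches_pair_counting(self):
        scores, labels = [0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]
        assert roc_auc(scores, labels) == pytest.approx(0.75)
        assert roc_auc(scores, labels) == pytest.approx(auc_pair_counting(scores, labels))

    def test_exhaustive_small_inputs_match_oracle(self):
        """Midrank AUC equals pair counting for every labelling of length <= 6."""
        rng = np.random.default_rng(13)
        for n in range(2, 7):
            scores = list(np.round(rng.random(n), 1))  # rounding forces ties
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    assert roc_auc(scores, labels) == pytest.approx(
                        auc_pair_counting(scores, labels)
                    ), (scores, labels)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=12))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_negated_scores_complement(self, scores):
        labels = [i % 2 for i in range(len(scores))]
        auc = roc_auc(scores, labels)
        assert auc + roc_auc([-s for s in scores], labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


def _records(values_by_pair):
    rows = []
    for (comp, tumor), values in values_by_pair.items():
        for i, v in enumerate(values):
            rows.append(
                {"cell_line": f"{tumor}_cl{i}", "tumor_type": tumor, "compound_id": comp, "log_ic50": v}
            )
    return pd.DataFrame(rows)


class TestAggregateIC50:
    def test_single_cell_line_returns_value(self):
        agg = aggregate_ic50(_records({("d", "t"): [3.7]}), q=0.1)
        assert agg[("d", "t")] == 3.7

    def test_constant_values_return_constant(self):
        agg = aggregate_ic50(_records({("d", "t"): [2.0] * 8}))
        assert agg[("d", "t")] == 2.0

    def test_linear_interpolation_convention(self):
        agg = aggregate_ic50(_records({("d", "t"): list(range(1, 11))}), q=0.10)
        assert agg[("d", "t")] == pytest.approx(1.9)

    def test_monotone_under_addition_above_quantile(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        before = aggregate_ic50(_records({("d", "t"): base}))[("d", "t")]
        after = aggregate_ic50(_records({("d", "t"): base + [50.0]}))[("d", "t")]
        assert after >= before

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_ic50(_records({("d", "t"): [1.0]}), q=1.5)


def _matrix(cells, method="publications"):
    comps = sorted({c for c, _ in cells})
    cancers = sorted({k for _, k in cells})
    df = pd.DataFrame(np.nan, index=comps, columns=cancers, dtype=float)
    for (c, k), v in cells.items():
        df.loc[c, k] = v
    return AssociationMatrix(scores=df, method=method)


class TestBinning:
    @pytest.mark.parametrize(
        "score, expected",
        [(0.0, "low"), (0.99, "low"), (1.0, "unbinned"), (10.0, "unbinned"),
         (20.0, "high"), (79.9, "high"), (80.0, "very_high"), (100.0, "very_high")],
    )
    def test_fisher_bins(self, score, expected):
        assert FISHER_BINS.bin(score) == expected

    @pytest.mark.parametrize(
        "score, expected",
        [(0.05, "low"), (0.15, "unbinned"), (0.3, "high"), (0.6, "very_high")],
    )
    def test_cosine_bins(self, score, expected):
        assert COSINE_BINS.bin(score) == expected

    def test_default_scheme_follows_matrix_method(self):
        fisher = bin_associations(_matrix({("d", "t"): 85.0}))
        cosine = bin_associations(_matrix({("d", "t"): 0.65}, method="cosine"))
        assert fisher.loc[0, "bin"] == "very_high"
        assert cosine.loc[0, "bin"] == "very_high"

    def test_binning_is_a_partition(self):
        rng = np.random.default_rng(2)
        cells = {(f"d{i}", f"t{j}"): float(rng.uniform(0, 120)) for i in range(5) for j in range(4)}
        bins = bin_associations(_matrix(cells))
        assert set(bins["bin"]) <= {"low", "high", "very_high", "unbinned"}
        assert len(bins) == 20

    def test_overlapping_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            BinScheme(low_upper=30.0, high_lower=20.0, high_upper=80.0)


class TestCompareIC50ByBin:
    def test_identical_distributions_fold_near_one(self):
        cells = {(f"d{i}", "t"): (0.0 if i < 5 else 85.0) for i in range(10)}
        values = {(f"d{i}", "t"): [2.0, 2.1, 1.9] for i in range(10)}
        summary, folds = compare_ic50_by_bin(
            bin_associations(_matrix(cells)), aggregate_ic50(_records(values))
        )
        assert folds["low_vs_very_high"] == pytest.approx(1.0, abs=0.1)

    def test_single_pair_per_bin_gives_value_ratio(self):
        cells = {("d1", "t"): 0.0, ("d2", "t"): 90.0}
        values = {("d1", "t"): [3.0], ("d2", "t"): [1.0]}
        _, folds = compare_ic50_by_bin(
            bin_associations(_matrix(cells)), aggregate_ic50(_records(values))
        )
        assert folds["low_vs_very_high"] == pytest.approx(np.exp(2.0))

    def test_empty_overlap_rejected(self):
        cells = {("d1", "t"): 0.0}
        values = {("other", "t2"): [1.0]}
        with pytest.raises(ValidationError):
            compare_ic50_by_bin(
                bin_associations(_matrix(cells)), aggregate_ic50(_records(values))
            )


def _cohort(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "tumor_type", "drug_ids", "time_days", "event"]
    )


class TestStratification:
    def test_no_drug_patient_is_nodrug(self):
        mat = _matrix({("d1", "t1"): 50.0})
        cohort = _cohort([["p1", "t1", [], 100.0, True]])
        groups = stratify_patients(cohort, mat)
        assert groups.loc[0, "group"] == "noDrug"

    def test_cutoff_is_inclusive(self):
        mat = _matrix({("d1", "t1"): 20.0})
        cohort = _cohort([["p1", "t1", ["d1"], 100.0, True]])
        groups = stratify_patients(cohort, mat, support_cutoff=20.0)
        assert groups.loc[0, "group"] == "high"

    def test_maximum_score_over_drugs_decides(self):
        mat = _matrix({("d1", "t1"): 1.0, ("d2", "t1"): 90.0})
        cohort = _cohort([["p1", "t1", ["d1", "d2"], 50.0, True]])
        assert stratify_patients(cohort, mat).loc[0, "group"] == "high"

    def test_unknown_tumor_excluded_with_report(self):
        mat = _matrix({("d1", "t1"): 50.0})
        cohort = _cohort(
            [["p1", "t1", ["d1"], 10.0, True], ["p2", "tX", ["d1"], 10.0, True]]
        )
        groups = stratify_patients(cohort, mat)
        assert list(groups.patient_id) == ["p1"]
        assert groups.attrs["excluded"] == ["p2"]

    def test_unmapped_drug_reported_and_ignored(self):
        mat = _matrix({("d1", "t1"): 90.0})
        cohort = _cohort([["p1", "t1", ["dZ"], 10.0, True]])
        groups = stratify_patients(cohort, mat)
        assert groups.loc[0, "group"] == "low"
        assert groups.attrs["unmapped_drugs"] == ["dZ"]

    def test_synthetic_cohort_matches_truth_exactly(self, small_planted_corpus):
        from oncolit.synthetic import generate_survival

        config, _, _, truth = small_planted_corpus
        records = generate_survival(truth, config)
        mat = _matrix(
            {
                (c, k): (100.0 if (c, k) in truth.planted_pairs else 0.0)
                for c in truth.compound_ids
                for k in truth.cancer_ids
            }
        )
        groups = stratify_patients(records, mat, support_cutoff=20.0)
        expected = pd.Series(truth.survival_groups)
        got = groups.set_index("patient_id")["group"]
        assert (got == expected.loc[got.index]).all()


class TestSurvivalCompare:
    def _groups(self, hr, n=600, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            low = i % 2 == 1
            lam = (1 / 500) * (hr if low else 1.0)
            t = float(rng.exponential(1 / lam))
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "tumor_type": "t",
                    "group": "low" if low else "high",
                    "time_days": min(t, 1825.0),
                    "event": t <= 1825.0,
                }
            )
        return pd.DataFrame(rows)

    def test_identical_groups_hazard_near_one(self):
        res = survival_compare(self._groups(hr=1.0, n=800))
        assert 0.8 < res["hazard_ratio_low_vs_high"] < 1.25
        assert res["p_value"] > 0.05

    def test_known_hazard_ratio_recovered(self):
        res = survival_compare(self._groups(hr=2.0, n=2000))
        assert 1.7 <= res["hazard_ratio_low_vs_high"] <= 2.3
        assert res["p_value"] < 1e-6

    def test_curves_present_per_group(self):
        res = survival_compare(self._groups(hr=1.5, n=200))
        assert set(res["curves"]) == {"high", "low"}

    def test_no_events_rejected(self):
        groups = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "tumor_type": ["t", "t"],
                "group": ["high", "low"],
                "time_days": [10.0, 20.0],
                "event": [False, False],
            }
        )
        with pytest.raises(ValidationError, match="events"):
            survival_compare(groups)

    def test_single_patient_group_rejected(self):
        groups = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "tumor_type": ["t"] * 3,
                "group": ["high", "high", "low"],
                "time_days": [10.0, 30.0, 20.0],
                "event": [True, True, False],
            }
        )
        with pytest.raises(ValidationError, match="degenerate"):
            survival_compare(groups)
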