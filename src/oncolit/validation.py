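"""Validation of literature-derived association scores.

Three independent checks, mirroring the study design this package
implements:

* approval labels: rank-based ROC AUC of the scores against per-pair
  approved/not-approved labels;
* cell-line sensitivity: per (compound, tumor) IC-50 aggregated as the 10%
  quantile across the tumor's cell lines, compared between association
  bins (low / high / very high);
* patient survival: cohorts stratified by the literature support of their
  annotated drugs (noDrug / high / low) and compared with Kaplan-Meier
  curves and a Cox proportional-hazards model (likelihood-ratio p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enrichment import AssociationMatrix


class ValidationError(ValueError):
    """Raised for degenerate or inconsistent validation inputs."""


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC with midranks for ties (Mann-Whitney statistic).

    Requires at least one positive and one negative label.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("labels must contain both classes")
    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aggregate_ic50(records: pd.DataFrame, q: float = 0.10) -> pd.Series:
    """q-quantile of log IC-50 per (compound, tumor) across cell lines.

    Linear interpolation between order statistics (the numpy default), so a
    single cell line returns its own value for any q.  The low quantile
    deliberately summarizes the sensitive end of a tumor's cell-line panel
    while being more stable than the minimum.
    """
    if not (0.0 < q < 1.0):
        raise ValidationError(f"q must be in (0, 1), got {q}")
    required = {"tumor_type", "compound_id", "log_ic50"}
    if not required <= set(records.columns):
        raise ValidationError(f"records must have columns {sorted(required)}")
    return records.groupby(["compound_id", "tumor_type"])["log_ic50"].quantile(
        q, interpolation="linear"
    )


@dataclass(frozen=True)
class BinScheme:
    """Score bins for association strength.

    ``low`` is everything strictly below ``low_upper``; ``high`` is
    [high_lower, high_upper); ``very_high`` is >= high_upper (closed on the
    right bin).  Scores in the gaps (e.g. between low and high) are
    ``unbinned``.
    """

    low_upper: float
    high_lower: float
    high_upper: float
    method: str = ""

    def __post_init__(self) -> None:
        if not (self.low_upper <= self.high_lower < self.high_upper):
            raise ValidationError(
                f"cutoffs must satisfy low_upper <= high_lower < high_upper, got {self}"
            )

    def bin(self, score: float) -> str:
        if np.isnan(score):
            return "unbinned"
        if score < self.low_upper:
            return "low"
        if score >= self.high_upper:
            return "very_high"
        if score >= self.high_lower:
            return "high"
        return "unbinned"


FISHER_BINS = BinScheme(low_upper=1.0, high_lower=20.0, high_upper=80.0, method="fisher")
COSINE_BINS = BinScheme(low_upper=0.1, high_lower=0.2, high_upper=0.6, method="cosine")


def bin_associations(
    matrix: AssociationMatrix, cutoffs: BinScheme | None = None
) -> pd.DataFrame:
    """Assign every (compound, cancer) cell to low/high/very_high/unbinned.

    Default cutoffs depend on the matrix method: Fisher-based scores use
    -log10 p bins (low < 1, high in [20, 80), very high >= 80), cosine
    matrices use similarity bins (low < 0.1, high in [0.2, 0.6), very high
    >= 0.6).
    """
    if cutoffs is None:
        cutoffs = COSINE_BINS if matrix.method == "cosine" else FISHER_BINS
    rows = []
    for comp in matrix.compounds:
        for canc in matrix.cancers:
            score = float(matrix.scores.loc[comp, canc])
            rows.append(
                {
                    "compound_id": comp,
                    "cancer_id": canc,
                    "score": score,
                    "bin": cutoffs.bin(score),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["cutoffs"] = cutoffs
    out.attrs["method"] = matrix.method
    return out


def compare_ic50_by_bin(
    bins: pd.DataFrame, aggregated: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Summarize aggregated IC-50 per association bin.

    Returns a per-bin table (n, median and mean of log IC-50) and fold
    changes between bins on the natural concentration scale,
    ``exp(median_a - median_b)`` for each ordered bin pair with data; the
    headline number is ``low_vs_high``.  Empty bins are flagged by absence.
    """
    merged = bins.set_index(["compound_id", "cancer_id"]).join(
        aggregated.rename("ic50").rename_axis(["compound_id", "cancer_id"]), how="inner"
    )
    merged = merged.dropna(subset=["ic50"])
    if merged.empty:
        raise ValidationError("no (compound, cancer) pairs with both a bin and an IC-50 value")
    summary = (
        merged.groupby("bin")["ic50"].agg(n="size", median="median", mean="mean").reset_index()
    )
    medians = dict(zip(summary["bin"], summary["median"]))
    folds: dict[str, float] = {}
    for a in ("low", "high", "very_high"):
        for b in ("low", "high", "very_high"):
            if a != b and a in medians and b in medians:
                folds[f"{a}_vs_{b}"] = float(np.exp(medians[a] - medians[b]))
    return summary, folds


def stratify_patients(
    records: pd.DataFrame,
    matrix: AssociationMatrix,
    support_cutoff: float = 20.0,
) -> pd.DataFrame:
    """Assign each patient to noDrug / high / low literature support.

    A patient with no annotated drug is ``noDrug``; otherwise the patient
    is ``high`` iff the maximum association score among their drugs for
    their tumor type meets the cutoff (inclusive), else ``low``.  Patients
    whose tumor type is absent from the matrix are excluded and reported in
    ``result.attrs['excluded']``; annotated drugs missing from the matrix
    are reported in ``result.attrs['unmapped_drugs']`` and ignored for the
    maximum (a patient with only unmapped drugs is ``low``).
    """
    excluded: list[str] = []
    unmapped: set[str] = set()
    known_drugs = set(matrix.compounds)
    known_tumors = set(matrix.cancers)
    rows = []
    for rec in records.itertuples(index=False):
        if rec.tumor_type not in known_tumors:
            excluded.append(rec.patient_id)
            continue
        drugs = list(rec.drug_ids)
        if not drugs:
            group = "noDrug"
        else:
            scores = []
            for d in drugs:
                if d in known_drugs:
                    val = float(matrix.scores.loc[d, rec.tumor_type])
                    if not np.isnan(val):
                        scores.append(val)
                else:
                    unmapped.add(d)
            group = "high" if scores and max(scores) >= support_cutoff else "low"
        rows.append(
            {
                "patient_id": rec.patient_id,
                "tumor_type": rec.tumor_type,
                "group": group,
                "time_days": rec.time_days,
                "event": rec.event,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    out.attrs["unmapped_drugs"] = sorted(unmapped)
    out.attrs["support_cutoff"] = support_cutoff
    return out


def survival_compare(groups: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group and a high-vs-low Cox comparison.

    ``groups`` needs columns group, time_days, event.  The Cox model is fit
    on the high/low subset with a single indicator covariate (low = 1), so
    the reported hazard ratio is low-vs-high; the p-value is the
    likelihood-ratio test of that model.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import StatisticalResult  # noqa: F401  (re-exported type)

    required = {"group", "time_days", "event"}
    if not required <= set(groups.columns):
        raise ValidationError(f"groups must have columns {sorted(required)}")
    non_empty = [g for g, sub in groups.groupby("group") if len(sub)]
    if len(non_empty) < 2:
        raise ValidationError("need at least two non-empty groups")
    if not groups["event"].any():
        raise ValidationError("no events observed; survival comparison undefined")
    curves: dict[str, pd.DataFrame] = {}
    for name, sub in groups.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(sub["time_days"], event_observed=sub["event"], label=str(name))
        curves[str(name)] = km.survival_function_
    hl = groups[groups["group"].isin(["high", "low"])].copy()
    if hl["group"].nunique() < 2:
        raise ValidationError("both a high and a low group are required for the Cox comparison")
    for name, sub in hl.groupby("group"):
        if len(sub) < 2 or not sub["event"].any():
            raise ValidationError(
                f"group {name!r} is degenerate (needs >= 2 patients and >= 1 event)"
            )
    hl["low_support"] = (hl["group"] == "low").astype(float)
    cox = CoxPHFitter()
    cox.fit(hl[["time_days", "event", "low_support"]], duration_col="time_days", event_col="event")
    hazard_ratio = float(np.exp(cox.params_["low_support"]))
    lr = cox.log_likelihood_ratio_test()
    return {
        "curves": curves,
        "hazard_ratio_low_vs_high": hazard_ratio,
        "p_value": float(lr.p_value),
        "n_per_group": groups["group"].value_counts().to_dict(),
        "cox_model": cox,
    }


def approval_roc(
    matrix: AssociationMatrix, labels: Mapping[tuple[str, str], bool]
) -> tuple[float, pd.DataFrame]:
    """ROC AUC of matrix scores against approval labels.

    Only labelled pairs present in the matrix enter; returns the AUC and
    the per-pair score/label table used to compute it.
    """
    rows = []
    for (comp, canc), approved in labels.items():
        if comp in matrix.scores.index and canc in matrix.scores.columns:
            score = float(matrix.scores.loc[comp, canc])
            if not np.isnan(score):
                rows.append({"compound_id": comp, "cancer_id": canc, "score": score, "approved": bool(approved)})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValidationError("no labelled pairs overlap the matrix")
    auc = roc_auc(table["score"].to_numpy(), table["approved"].to_numpy())
    return auc, table
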