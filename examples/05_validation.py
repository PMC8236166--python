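"""Validate literature scores against approval, IC-50 and survival data.

One synthetic study: planted associations drive the literature scores, the
approval labels, a cell-line IC-50 table (planted pairs are 2 natural-log
units more sensitive) and patient survival (patients on unsupported drugs
have twice the hazard).  The three validations mirror that design: ROC of
the scores against approval labels, 10%-quantile IC-50 compared between
association bins, and a Cox comparison of high- vs low-support patients.
"""

from oncolit import (
    aggregate_ic50,
    association_matrix,
    bin_associations,
    build_index,
    compare_ic50_by_bin,
    generate_corpus,
    generate_ic50,
    generate_survival,
    stratify_patients,
    survival_compare,
)
from oncolit.synthetic import GeneratorConfig, cancer_id, compound_id
from oncolit.validation import approval_roc

effects = {(compound_id(i), cancer_id((i * 3) % 8)): 2.5 for i in range(12)}
config = GeneratorConfig(
    seed=5,
    n_reference_docs=20000,
    n_cancers=8,
    n_compounds=12,
    n_genes=10,
    n_patients=2000,
    association_effect=effects,
)
documents, lexicon, truth = generate_corpus(config)
index = build_index(documents, lexicon)
matrix = association_matrix(index, lexicon.ids("compound"), lexicon.ids("cancer"))

auc, table = approval_roc(matrix, truth.approval_labels)
print(f"approval ROC AUC over {len(table)} labelled pairs: {auc:.3f}")

ic50 = generate_ic50(truth, config)
summary, folds = compare_ic50_by_bin(bin_associations(matrix), aggregate_ic50(ic50, q=0.10))
print("\nIC-50 (10% quantile of log values) by association bin:")
print(summary.to_string(index=False))
print(f"fold change low vs very-high support: {folds['low_vs_very_high']:.2f}x")

survival = generate_survival(truth, config)
groups = stratify_patients(survival, matrix, support_cutoff=20.0)
result = survival_compare(groups)
print(f"\npatients per group: {result['n_per_group']}")
print(
    f"Cox hazard ratio low vs high support: {result['hazard_ratio_low_vs_high']:.2f} "
    f"(likelihood-ratio p = {result['p_value']:.2g})"
)
# Expected: AUC near 1 (scores separate approved from unapproved pairs),
# a ~4-7x IC-50 fold difference (exp(2) ~ 7.4 before binning noise), and a
# hazard ratio near the simulated 2.
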