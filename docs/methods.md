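# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices and the known limitations of `oncolit`.

## Association model

All associations are one-sided Fisher exact tests for over-representation:
given a 2×2 table (a, b, c, d) with N = a+b+c+d, the p-value is the upper
hypergeometric tail P(X ≥ a) with all margins fixed. One-sided is the only
variant consistent with the intended semantics: an omnipresent gene that is
*under*-represented in a cancer's publications must score p = 1 ("not
specific"), which a two-sided test would not deliver.

The tail is summed in log space (`scipy.stats.hypergeom.logpmf` +
`logsumexp`), so p-values below the smallest positive double remain exact
as −log10 p (e.g. the worked BRCA1 table gives −log10 p ≈ 6117.5). The
primary score is this exact log-space value; a display cap of 100 is
applied for matrices and binning so cells stay comparable. Odds ratios are
(a·d)/(b·c) with b·c = 0 reported as +∞ (no continuity correction).

Contingency construction per route:

* **Publication overlap** — a = documents mentioning both entities,
  b/c = each alone, d = corpus remainder.
* **Gene profiles** — the universe is restricted to gene-containing
  documents. For gene g and entity E: a = gene-bearing docs of E containing
  g, column totals are E's and the reference corpus's gene-bearing document
  counts, and reference cells have the entity cells subtracted so the four
  cells are disjoint. Profiles rank genes by ascending p. "Specific" genes
  default to raw p < 0.01, uncorrected — the scoring reports raw Fisher
  p-values throughout — with Benjamini–Hochberg available as an option.
* **Gene overlap** — shared / A-only / B-only specific genes against the
  remaining gene universe.
* **Co-occurrence** — compound pairs inside one cancer's document set, with
  N equal to that cancer's publication count (a global-universe variant is
  exposed for comparison because it materially changes p-values). Edges
  with −log10 p strictly above 50 form the graph.

Matrix post-processing: hierarchical clustering uses average linkage on
Euclidean distances (labels renumbered by first appearance, so permuting
inputs permutes labels consistently); partitions are compared with the
adjusted Rand index; matrices with matching grids are compared by Pearson
correlation over cells.

## Entity tagging

Matching is literal dictionary matching of synonyms, case-insensitive and
anchored at token boundaries (no letter/digit flanks), with overlaps
resolved longest-match-first, left to right. Two refinements: synonyms
containing hyphens also match with hyphens replaced by spaces, and gene
synonyms of at most four characters are matched case-sensitively to limit
false positives from common words. Server-side query expansion (MeSH-style
term mapping) is deliberately not emulated: all downstream statistics
depend only on document counts, and literal matching keeps the tagger
auditable. Title and abstract are concatenated for matching.

## Word embeddings

Text normalization replaces every synonym span (resolved exactly as in
tagging) with the entity's canonical embedding token, lowercases the rest
and splits on non-alphanumeric boundaries, preserving internal hyphens.
Normalization is idempotent because embedding tokens match themselves.

Training is a compact skip-gram word2vec with negative sampling written on
numpy. Defaults: minimum word frequency 1, vector length 200, window 500
tokens — interpreted as "the window spans the whole abstract", so each
abstract is one training sequence and every in-abstract token pair is a
context pair. Architecture choices left open by that parameterization are
fixed as: skip-gram, 5 negative samples drawn from the unigram distribution
raised to 3/4, 5 epochs, frequent-word subsampling at threshold 10⁻³.

Two implementation-specific choices matter:

* **Batched averaged updates.** Each sequence's pairs are processed as one
  batch; every parameter row receives the *mean* of its pair gradients
  rather than the sum. This bounds the step size of frequent tokens by the
  learning rate and is what makes whole-abstract windows trainable without
  divergence. Because averaging shrinks the effective step relative to
  canonical per-pair SGD, the default learning rate is 0.1 (linearly
  decaying) rather than the conventional 0.025; with the conventional rate
  the averaged variant under-trains and the space degenerates toward a
  single direction.
* **Pair subsampling.** A wide window over an n-token abstract yields
  O(n²) pairs; per epoch at most `pairs_per_sequence` (default 600) of them
  are sampled uniformly, an unbiased estimate of the same objective.

With a fixed seed, training is single-threaded and bit-reproducible.
Similarity is the standard cosine of stored vectors; the reported bins
follow the similarity scale (low < 0.1, high 0.2–0.6, very high ≥ 0.6).
(One observed inconsistency in reported cosine cutoffs — 0.2 vs 0.3 as the
lower "high" bound — is resolved in favour of 0.2/0.6; both are
configurable through `BinScheme`.)

## Validation procedures

* **Approval ROC** — rank-based AUC with midranks for ties (equivalent to
  the Mann–Whitney statistic) of association scores against per-pair
  approved/not-approved labels.
* **IC-50** — per (compound, tumor), the 10% quantile of log IC-50 across
  the tumor's cell lines, with linear interpolation between order
  statistics; the low quantile summarizes the sensitive end of the panel
  while being more stable than the minimum. Aggregated values are compared
  between association bins; fold changes are exp(median difference) on the
  natural concentration scale. Fisher bins are right-open except the top
  bin ([20, 80), ≥ 80); scores in the gaps (e.g. [1, 20)) are "unbinned"
  and excluded.
* **Survival** — patients with no annotated drug are `noDrug`; otherwise a
  patient is `high` iff the *maximum* association score among their drugs
  for their tumor meets the support cutoff (inclusive), else `low`. The
  maximum rule encodes the assumption that a single strongly supported drug
  dominates the prognosis. The cutoff itself (default −log10 p ≥ 20, the
  lower bound of the "high" bin) is a free parameter; it is echoed in the
  output. Curves are Kaplan–Meier; the high-vs-low comparison is a Cox
  model on a single indicator covariate with the likelihood-ratio p-value
  (via `lifelines`). Degenerate groups (fewer than two patients, or no
  events) are rejected explicitly.

## Synthetic data generator

The generator emulates the statistical skeleton of a large abstract-mining
study at desk scale; its defaults are the conditions the test suite and the
acceptance script run at.

**Document model.** Each abstract is 3–8 filler sentences of 6–12 words
plus a filler title. Entity mentions are inserted as literal synonym
strings (one synonym chosen uniformly per mention) at uniform sentence
positions. Filler text is *topical*: documents draw one of 8 topics and mix
topic-specific pseudo-vocabulary with common filler words (probability 0.5
per word), and documents about a cancer use that cancer's home topic with
probability 0.7. Topics never influence which entities are mentioned — they
only shape the surrounding vocabulary — so all count-based statistics are
unaffected. The topical structure exists because real abstract corpora are
topically coherent, and a corpus with i.i.d. filler has an essentially
rank-one co-occurrence matrix on which embedding similarity carries no
usable signal; with topics, co-mentioned entities share topical contexts
and the embedding route behaves as it does on real text.

**Entity model.** Cancers are independent Bernoulli mentions at the
baseline rate (default 0.05/document). Each compound's log-odds is the
baseline logit plus the planted effect of every cancer present in the
document (so with zero effects, compounds and cancers are exactly
independent), plus optional compound–compound co-mention effects applied
from lower- to higher-indexed compounds. The expected co-mention count of a
planted pair has the closed form N · p · σ(logit(p) + effect), exposed as
`expected_comention_count` and used by the generator-recovery tests. Genes
appear only in gene-bearing documents (default fraction 0.2): two
omnipresent genes at rate 0.5, others at 0.08, with configurable
entity-specific boosts.

**Coupled validation data.** Approval labels: planted pairs are approved
(an optional noise rate can flip them), plus an equal number of explicit
non-planted negatives. IC-50: normal log-values (σ = 1) whose mean drops by
`ic50_shift` (default 2 natural-log units) for planted pairs; ≥ 3 cell
lines per tumor enforced, default 10. Survival: exponential times with the
baseline hazard 1/500 per day, multiplied by `survival_hazard_ratio`
(default 2) for patients whose drug is not planted for their tumor;
administrative censoring at a 5-year horizon; 30% of patients carry no
drug. The generator records per-patient truth groups so stratification can
be checked exactly.

**Determinism.** One `numpy` Generator seeded from the config seed drives
corpus generation; IC-50 and survival use seed sequences ([1, seed],
[2, seed]) so the three outputs are independently reproducible. A fixed
seed yields byte-identical corpora, tables and records.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: Zipfian word frequencies beyond the two-tier
filler/topic structure, abbreviations and hedged or negated mentions (the
tagger's literal matching is exact on synthetic text but approximate on
real abstracts), MeSH-style query expansion, citation structure and
publication dates, per-document mention multiplicity, and realistic
cell-line or clinical covariate structure.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make the
statistical claims sharp while staying light: 20 000-document corpora for
calibration (500 entity pairs) and recovery (96 pairs, 12 planted at
log-odds 2.5), 8 000 documents for co-occurrence recovery, 600-document
corpora across five seeds for the embedding contrast, and 2 000 simulated
patients for Cox recovery. The Fisher core is verified against exact
rational enumeration on all 14 950 tables with N ≤ 22 plus
property-based sweeps.

## Known limitations

* Dictionary NER cannot disambiguate polysemous names or detect entities
  absent from the lexicon; recall on real text depends entirely on synonym
  coverage.
* The embedding trainer is designed for corpora in the 10³–10⁵ abstract
  range; it is single-threaded and not intended for multi-million-document
  training runs.
* Gene-overlap associations depend on the specific-gene cutoff (raw
  p < 0.01 by default); with very small gene universes the test is
  coarsely discrete.
* The Cox comparison uses a single group indicator; no covariate
  adjustment is implemented.
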