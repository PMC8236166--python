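"""Synthetic abstract corpora with planted compound-cancer-gene structure.

The generator emulates the statistical skeleton of a PubMed-scale mining
study at desk scale: a reference corpus of filler-sentence abstracts in
which cancer types and compounds are mentioned independently at a baseline
rate, except for planted compound-cancer pairs whose co-mention probability
is raised by a configurable log-odds effect; a minority of documents
(default 20%) carry gene mentions, with both omnipresent genes and genes
enriched in specific entity contexts.  Coupled to the corpus are approval
labels, cell-line IC-50 tables and patient survival records whose signal
derives from the same planted pairs, so every downstream statistic can be
checked against ground truth.

Entity mentions are inserted as literal synonym strings (one synonym chosen
uniformly per mention) at uniform positions in 3-8 filler sentences, which
is exactly the granularity the dictionary tagger and the abstract-wide
embedding window consume.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import DocumentCollection, DocumentRecord
from .lexicon import EntityLexicon, LexiconEntry


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


def cancer_id(i: int) -> str:
    return f"cancer{i:03d}"


def compound_id(i: int) -> str:
    return f"comp{i:03d}"


def gene_id(i: int) -> str:
    return f"gene{i:03d}"


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the defaults the tests run at.

    ``association_effect`` maps (compound_id, cancer_id) to a log-odds boost
    applied to the compound's mention probability in documents mentioning
    that cancer; pairs with positive effect are the planted ground truth.
    ``comention_effect`` plays the same role for compound-compound pairs
    (the basis of planted co-occurrence edges).  ``gene_specificity`` maps a
    gene id to (entity ids, multiplicative boost) raising its mention rate
    in documents of those entities.
    """

    seed: int
    n_reference_docs: int = 20000
    n_cancers: int = 4
    n_compounds: int = 6
    n_genes: int = 30
    baseline_mention_prob: float = 0.05
    association_effect: dict[tuple[str, str], float] = field(default_factory=dict)
    comention_effect: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_doc_fraction: float = 0.2
    gene_mention_prob: float = 0.08
    n_omnipresent_genes: int = 2
    omnipresent_gene_prob: float = 0.5
    gene_specificity: dict[str, tuple[frozenset[str], float]] = field(default_factory=dict)
    synonyms_per_entity: int = 3
    n_topics: int = 8
    topic_word_prob: float = 0.5
    topic_affinity: float = 0.7
    # IC-50 table
    ic50_shift: float = 2.0
    ic50_base_mean: float = 3.0
    ic50_sigma: float = 1.0
    cell_lines_per_tumor: int = 10
    # survival records
    n_patients: int = 2000
    no_drug_fraction: float = 0.3
    survival_hazard_ratio: float = 2.0
    baseline_hazard_per_day: float = 1.0 / 500.0
    censor_horizon_days: float = 1825.0
    # approval labels
    approval_negatives_per_positive: int = 1
    approval_noise: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        for name in ("n_reference_docs", "n_cancers", "n_compounds", "n_genes",
                     "synonyms_per_entity", "cell_lines_per_tumor", "n_patients"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_topics < 1:
            raise ConfigError("n_topics must be >= 1")
        for name in ("baseline_mention_prob", "gene_doc_fraction", "gene_mention_prob",
                     "omnipresent_gene_prob", "no_drug_fraction", "approval_noise",
                     "topic_word_prob", "topic_affinity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for mapping in (self.association_effect, self.comention_effect):
            for key, eff in mapping.items():
                if not math.isfinite(eff):
                    raise ConfigError(f"effect for {key} must be finite")
        if self.cell_lines_per_tumor < 3:
            raise ConfigError("cell_lines_per_tumor must be >= 3")
        if self.survival_hazard_ratio <= 0 or self.baseline_hazard_per_day <= 0:
            raise ConfigError("hazards must be > 0")

    @property
    def cancer_ids(self) -> list[str]:
        return [cancer_id(i) for i in range(self.n_cancers)]

    @property
    def compound_ids(self) -> list[str]:
        return [compound_id(i) for i in range(self.n_compounds)]

    @property
    def gene_ids(self) -> list[str]:
        return [gene_id(i) for i in range(self.n_genes)]

    @property
    def planted_pairs(self) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.association_effect.items() if v > 0}

    def to_json(self, destination: str | Path) -> None:
        data = asdict(self)
        data["association_effect"] = [[a, b, e] for (a, b), e in self.association_effect.items()]
        data["comention_effect"] = [[a, b, e] for (a, b), e in self.comention_effect.items()]
        data["gene_specificity"] = [
            [g, sorted(ents), boost] for g, (ents, boost) in self.gene_specificity.items()
        ]
        Path(destination).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, source: str | Path) -> "GeneratorConfig":
        data = json.loads(Path(source).read_text())
        if "seed" not in data:
            raise ConfigError("config file must declare a seed")
        data["association_effect"] = {(a, b): e for a, b, e in data.get("association_effect", [])}
        data["comention_effect"] = {(a, b): e for a, b, e in data.get("comention_effect", [])}
        data["gene_specificity"] = {
            g: (frozenset(ents), boost) for g, ents, boost in data.get("gene_specificity", [])
        }
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Planted ground truth plus realized quantities of one generated corpus."""

    planted_pairs: dict[tuple[str, str], float]
    approval_labels: dict[tuple[str, str], bool]
    ic50_truth: dict[tuple[str, str], float]
    survival_truth: dict[str, float] = field(default_factory=dict)
    survival_groups: dict[str, str] = field(default_factory=dict)
    realized_doc_counts: dict[str, int] = field(default_factory=dict)
    realized_pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    gene_bearing_docs: int = 0
    cancer_ids: list[str] = field(default_factory=list)
    compound_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.planted_pairs.values()):
            raise ConfigError("planted pairs must have positive effect")

    def to_json(self, destination: str | Path) -> None:
        data = {
            "planted_pairs": [[a, b, e] for (a, b), e in self.planted_pairs.items()],
            "approval_labels": [[a, b, v] for (a, b), v in self.approval_labels.items()],
            "ic50_truth": [[a, b, v] for (a, b), v in self.ic50_truth.items()],
            "survival_truth": self.survival_truth,
            "survival_groups": self.survival_groups,
            "realized_doc_counts": self.realized_doc_counts,
            "realized_pair_counts": [[a, b, v] for (a, b), v in self.realized_pair_counts.items()],
            "gene_bearing_docs": self.gene_bearing_docs,
            "cancer_ids": self.cancer_ids,
            "compound_ids": self.compound_ids,
            "gene_ids": self.gene_ids,
        }
        Path(destination).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(source).read_text())
        return cls(
            planted_pairs={(a, b): e for a, b, e in data["planted_pairs"]},
            approval_labels={(a, b): bool(v) for a, b, v in data["approval_labels"]},
            ic50_truth={(a, b): v for a, b, v in data["ic50_truth"]},
            survival_truth=data.get("survival_truth", {}),
            survival_groups=data.get("survival_groups", {}),
            realized_doc_counts=data.get("realized_doc_counts", {}),
            realized_pair_counts={(a, b): v for a, b, v in data.get("realized_pair_counts", [])},
            gene_bearing_docs=data.get("gene_bearing_docs", 0),
            cancer_ids=data.get("cancer_ids", []),
            compound_ids=data.get("compound_ids", []),
            gene_ids=data.get("gene_ids", []),
        )


# ---------------------------------------------------------------------------
# name pools

_SYL1 = ("zan", "vor", "mek", "tal", "rin", "bex", "cro", "dul", "fen", "gor",
         "hax", "jil", "kov", "lum", "nop", "pex", "quil", "ruv", "sot", "wib")
_SYL2 = ("ar", "en", "ib", "ol", "ub", "ex", "ia", "or", "um", "yn", "av", "ez", "ik", "os", "ut")
_SYL3 = ("da", "fo", "gu", "ki", "lo", "mi", "na", "po", "ra", "su", "te", "vu", "wo", "xa", "ze")

_FILLER = (
    "the", "of", "and", "in", "we", "study", "patients", "results", "treatment",
    "analysis", "observed", "clinical", "effect", "dose", "response", "cells",
    "growth", "significant", "compared", "control", "after", "during", "with",
    "between", "increase", "decrease", "expression", "therapy", "data", "model",
    "method", "group", "outcome", "report", "case", "evidence", "role", "level",
    "activity", "function", "combined", "reduced", "observed", "survival",
    "median", "overall", "cohort", "assay", "phase", "trial",
)


# vowel-initial pseudo terms for topic-specific vocabulary; disjoint by
# construction from entity name stems, which are consonant-initial
_TOPIC_SYL1 = ("ab", "ed", "ig", "ol", "ud", "em", "ir", "os", "an", "ex")
_TOPIC_SYL2 = ("ter", "min", "cul", "dos", "rel", "pon", "sat", "ver", "lit",
               "gen", "mod", "fac", "tur", "bas", "nor", "pla", "sec", "vit",
               "cor", "lan")


def _topic_vocabulary() -> list[str]:
    return ["".join(t) for t in itertools.product(_TOPIC_SYL1, _TOPIC_SYL2)]


def _stems() -> list[str]:
    return ["".join(t) for t in itertools.product(_SYL1, _SYL2, _SYL3)]


def _cancer_synonyms(stem: str) -> list[str]:
    return [
        f"{stem} cancer",
        f"cancer of the {stem}",
        f"{stem} carcinoma",
        f"{stem}oma",
        f"malignant {stem} tumor",
    ]


def _compound_synonyms(stem: str) -> list[str]:
    return [
        f"{stem}inib",
        f"{stem}-42",
        f"{stem}amycin",
        f"{stem} hydrochloride",
        f"nsc-{stem}",
    ]


def _gene_synonyms(stem: str) -> list[str]:
    return [
        f"{stem}k1",
        f"{stem} kinase 1",
        f"{stem}-related protein",
        f"{stem}k1 gene",
        f"protein {stem}k1",
    ]


def build_lexicon(config: GeneratorConfig) -> EntityLexicon:
    """Deterministic synthetic lexicon for the configured entity counts."""
    stems = _stems()
    n_needed = config.n_cancers + config.n_compounds + config.n_genes
    if n_needed > len(stems):
        raise ConfigError(
            f"entity counts ({n_needed}) exceed the available name pool ({len(stems)})"
        )
    if config.synonyms_per_entity > 5:
        raise ConfigError("at most 5 synonyms per entity are available")
    k = config.synonyms_per_entity
    entries: list[LexiconEntry] = []
    cursor = 0
    for i in range(config.n_cancers):
        stem = stems[cursor]
        cursor += 1
        syns = _cancer_synonyms(stem)[:k]
        entries.append(
            LexiconEntry(cancer_id(i), "cancer", syns[0], tuple(syns), f"cancer{stem}cancer")
        )
    for i in range(config.n_compounds):
        stem = stems[cursor]
        cursor += 1
        syns = _compound_synonyms(stem)[:k]
        entries.append(LexiconEntry(compound_id(i), "compound", syns[0], tuple(syns), syns[0]))
    for i in range(config.n_genes):
        stem = stems[cursor]
        cursor += 1
        syns = _gene_synonyms(stem)[:k]
        entries.append(LexiconEntry(gene_id(i), "gene", syns[0], tuple(syns), syns[0]))
    return EntityLexicon.from_entries(entries)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def expected_comention_count(config: GeneratorConfig, compound: str, cancer: str) -> float:
    """Closed-form expected co-mention count under the generator's own model.

    The cancer is mentioned with the baseline probability p; given the
    cancer, the compound's mention probability is the logistic transform of
    logit(p) plus the pair's planted effect (other cancers' effects on the
    same compound are ignored, which is exact when at most one cancer
    carries an effect for the compound and accurate to O(p^2) otherwise).
    """
    p = config.baseline_mention_prob
    effect = config.association_effect.get((compound, cancer), 0.0)
    return config.n_reference_docs * p * float(_sigmoid(np.array(_logit(p) + effect)))


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[DocumentCollection, EntityLexicon, SyntheticTruth]:
    """Generate the corpus, its lexicon and the planted ground truth.

    Sampling model per document: cancers are independent Bernoulli draws at
    the baseline rate; each compound's log-odds is the baseline logit plus
    planted effects of the cancers present in the document plus co-mention
    effects of lower-indexed compounds already present; genes appear only in
    gene-bearing documents (fraction ``gene_doc_fraction``), omnipresent
    genes at a high rate everywhere, specific genes boosted when one of
    their entities is present.
    """
    lexicon = build_lexicon(config)
    cancers, compounds, genes = config.cancer_ids, config.compound_ids, config.gene_ids
    valid = set(cancers) | set(compounds) | set(genes)
    for comp, canc in config.association_effect:
        if comp not in set(compounds) or canc not in set(cancers):
            raise ConfigError(f"association_effect references unknown pair ({comp}, {canc})")
    for a, b in config.comention_effect:
        if a not in set(compounds) or b not in set(compounds) or a == b:
            raise ConfigError(f"comention_effect references invalid pair ({a}, {b})")
    for g, (ents, _boost) in config.gene_specificity.items():
        if g not in set(genes) or not set(ents) <= valid:
            raise ConfigError(f"gene_specificity references unknown ids for {g}")

    rng = np.random.default_rng(config.seed)
    n_docs = config.n_reference_docs
    p = config.baseline_mention_prob
    base_logit = _logit(p) if 0 < p < 1 else -np.inf

    cancer_present = rng.random((n_docs, config.n_cancers)) < p

    effect = np.zeros((config.n_compounds, config.n_cancers))
    comp_pos = {c: i for i, c in enumerate(compounds)}
    canc_pos = {c: i for i, c in enumerate(cancers)}
    for (comp, canc), e in config.association_effect.items():
        effect[comp_pos[comp], canc_pos[canc]] = e

    compound_present = np.zeros((n_docs, config.n_compounds), dtype=bool)
    comention = [[] for _ in range(config.n_compounds)]  # incoming (source_idx, effect)
    for (a, b), e in config.comention_effect.items():
        i, j = comp_pos[a], comp_pos[b]
        lo, hi = (i, j) if i < j else (j, i)
        comention[hi].append((lo, e))
    for j in range(config.n_compounds):
        logits = base_logit + cancer_present @ effect[j]
        for src, e in comention[j]:
            logits = logits + e * compound_present[:, src]
        compound_present[:, j] = rng.random(n_docs) < _sigmoid(logits)

    gene_bearing = rng.random(n_docs) < config.gene_doc_fraction
    gene_present = np.zeros((n_docs, config.n_genes), dtype=bool)
    entity_present = {
        **{c: cancer_present[:, i] for i, c in enumerate(cancers)},
        **{c: compound_present[:, i] for i, c in enumerate(compounds)},
    }
    for gi, g in enumerate(genes):
        base = config.omnipresent_gene_prob if gi < config.n_omnipresent_genes else config.gene_mention_prob
        probs = np.full(n_docs, base)
        if g in config.gene_specificity:
            ents, boost = config.gene_specificity[g]
            trigger = np.zeros(n_docs, dtype=bool)
            for e in ents:
                if e in entity_present:
                    trigger |= entity_present[e]
            probs = np.where(trigger, np.minimum(0.95, base * boost), probs)
        gene_present[:, gi] = gene_bearing & (rng.random(n_docs) < probs)

    # --- document text assembly -------------------------------------------
    entry_synonyms = {e.entity_id: list(e.synonyms) for e in lexicon}
    all_ids = cancers + compounds + genes
    presence = np.concatenate([cancer_present, compound_present, gene_present], axis=1)
    filler = np.array(_FILLER)
    # abstracts are topical: each document draws one topic and mixes its
    # topic-specific vocabulary with common filler words, giving the corpus
    # the non-uniform co-occurrence structure real abstracts have
    topic_vocab = np.array(_topic_vocabulary())
    words_per_topic = len(topic_vocab) // config.n_topics
    if words_per_topic < 1:
        raise ConfigError(
            f"n_topics ({config.n_topics}) exceeds the topic vocabulary ({len(topic_vocab)} words)"
        )
    topic_words = [
        topic_vocab[t * words_per_topic : (t + 1) * words_per_topic]
        for t in range(config.n_topics)
    ]
    documents = DocumentCollection()
    for d in range(n_docs):
        # documents about a cancer type use that cancer's home-topic
        # vocabulary with probability topic_affinity; filler topics carry
        # no information about compounds, whose mentions stay independent
        present_cancers = np.flatnonzero(cancer_present[d])
        if present_cancers.size and rng.random() < config.topic_affinity:
            anchor = int(present_cancers[int(rng.integers(0, present_cancers.size))])
            topic = anchor % config.n_topics
        else:
            topic = int(rng.integers(0, config.n_topics))
        n_sent = int(rng.integers(3, 9))
        lengths = rng.integers(6, 13, size=n_sent + 1)  # +1 for the title
        n_words = int(lengths.sum())
        common = filler[rng.integers(0, len(filler), size=n_words)]
        specific = topic_words[topic][rng.integers(0, words_per_topic, size=n_words)]
        words = np.where(rng.random(n_words) < config.topic_word_prob, specific, common)
        sentences: list[list[str]] = []
        off = 0
        for ln in lengths:
            sentences.append(list(words[off : off + int(ln)]))
            off += int(ln)
        title_words = sentences.pop()
        present_ids = [all_ids[i] for i in np.flatnonzero(presence[d])]
        for eid in present_ids:
            syns = entry_synonyms[eid]
            syn = syns[int(rng.integers(0, len(syns)))]
            s = int(rng.integers(0, n_sent))
            pos = int(rng.integers(0, len(sentences[s]) + 1))
            sentences[s].insert(pos, syn)
        abstract = ". ".join(" ".join(s) for s in sentences) + "."
        title = " ".join(title_words).capitalize() + "."
        documents.append(DocumentRecord(doc_id=f"PMID{d:07d}", title=title, abstract=abstract))

    # --- truth --------------------------------------------------------------
    realized_counts = {eid: int(presence[:, i].sum()) for i, eid in enumerate(all_ids)}
    realized_pairs: dict[tuple[str, str], int] = {}
    for ci, comp in enumerate(compounds):
        for ki, canc in enumerate(cancers):
            realized_pairs[(comp, canc)] = int(
                (compound_present[:, ci] & cancer_present[:, ki]).sum()
            )
    planted = config.planted_pairs
    approvals: dict[tuple[str, str], bool] = {}
    for pair in sorted(planted):
        approvals[pair] = bool(rng.random() >= config.approval_noise)
    non_planted = sorted(
        (comp, canc) for comp in compounds for canc in cancers if (comp, canc) not in planted
    )
    n_neg = min(len(non_planted), config.approval_negatives_per_positive * max(1, len(planted)))
    if planted and n_neg:
        chosen = rng.choice(len(non_planted), size=n_neg, replace=False)
        for idx in sorted(int(i) for i in chosen):
            approvals[non_planted[idx]] = False
    ic50_truth = {
        (comp, canc): config.ic50_base_mean - (config.ic50_shift if (comp, canc) in planted else 0.0)
        for comp in compounds
        for canc in cancers
    }
    truth = SyntheticTruth(
        planted_pairs=dict(planted),
        approval_labels=approvals,
        ic50_truth=ic50_truth,
        realized_doc_counts=realized_counts,
        realized_pair_counts=realized_pairs,
        gene_bearing_docs=int((gene_present.any(axis=1)).sum()),
        cancer_ids=cancers,
        compound_ids=compounds,
        gene_ids=genes,
    )
    return documents, lexicon, truth


def generate_ic50(truth: SyntheticTruth, config: GeneratorConfig) -> pd.DataFrame:
    """IC-50 table: one row per (cell line, compound), natural-log scale.

    Each tumor type contributes ``cell_lines_per_tumor`` cell lines; the
    log IC-50 is normal with standard deviation ``ic50_sigma`` around the
    truth mean, which is lowered by ``ic50_shift`` for planted pairs.
    """
    rng = np.random.default_rng([1, config.seed])
    rows = []
    for canc in truth.cancer_ids:
        for k in range(config.cell_lines_per_tumor):
            cell = f"{canc}_cl{k:02d}"
            for comp in truth.compound_ids:
                mean = truth.ic50_truth[(comp, canc)]
                rows.append(
                    {
                        "cell_line": cell,
                        "tumor_type": canc,
                        "compound_id": comp,
                        "log_ic50": float(rng.normal(mean, config.ic50_sigma)),
                    }
                )
    return pd.DataFrame(rows)


def generate_survival(truth: SyntheticTruth, config: GeneratorConfig) -> pd.DataFrame:
    """Survival records coupled to the planted associations.

    Patients get a uniform tumor type; a fraction receives no drug, the
    rest one uniformly chosen compound.  Times are exponential with the
    baseline hazard, multiplied by ``survival_hazard_ratio`` for patients
    whose drug is not planted for their tumor (low literature support), and
    administratively censored at the horizon.  The per-patient truth group
    (noDrug / high / low) is recorded in ``truth.survival_groups``.
    """
    if config.censor_horizon_days <= 0:
        raise ConfigError("censor_horizon_days must be > 0: every patient would be censored at time 0")
    rng = np.random.default_rng([2, config.seed])
    rows = []
    truth.survival_groups = {}
    for i in range(config.n_patients):
        pid = f"pt{i:05d}"
        tumor = truth.cancer_ids[int(rng.integers(0, len(truth.cancer_ids)))]
        if rng.random() < config.no_drug_fraction:
            drugs: list[str] = []
            group = "noDrug"
            hazard = config.baseline_hazard_per_day
        else:
            drug = truth.compound_ids[int(rng.integers(0, len(truth.compound_ids)))]
            drugs = [drug]
            if (drug, tumor) in truth.planted_pairs:
                group = "high"
                hazard = config.baseline_hazard_per_day
            else:
                group = "low"
                hazard = config.baseline_hazard_per_day * config.survival_hazard_ratio
        t = float(rng.exponential(1.0 / hazard))
        event = t <= config.censor_horizon_days
        rows.append(
            {
                "patient_id": pid,
                "tumor_type": tumor,
                "drug_ids": drugs,
                "time_days": min(t, config.censor_horizon_days),
                "event": bool(event),
            }
        )
        truth.survival_groups[pid] = group
    truth.survival_truth = {
        "hazard_ratio_low_vs_high": config.survival_hazard_ratio,
        "baseline_hazard_per_day": config.baseline_hazard_per_day,
        "censor_horizon_days": config.censor_horizon_days,
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text table round trips


def write_ic50_tsv(table: pd.DataFrame, destination: str | Path) -> None:
    table.to_csv(destination, sep="\t", index=False)


def read_ic50_tsv(source: str | Path) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t")


def write_survival_tsv(records: pd.DataFrame, destination: str | Path) -> None:
    out = records.copy()
    out["drug_ids"] = out["drug_ids"].map(";".join)
    out["event"] = out["event"].astype(int)
    out.to_csv(destination, sep="\t", index=False)


def read_survival_tsv(source: str | Path) -> pd.DataFrame:
    records = pd.read_csv(source, sep="\t", keep_default_na=False)
    records["drug_ids"] = records["drug_ids"].map(lambda s: s.split(";") if s else [])
    records["event"] = records["event"].astype(bool)
    return records


def write_approval_tsv(labels: Mapping[tuple[str, str], bool], destination: str | Path) -> None:
    with Path(destination).open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tcancer_id\tapproved\n")
        for (comp, canc), v in sorted(labels.items()):
            fh.write(f"{comp}\t{canc}\t{int(v)}\n")


def read_approval_tsv(source: str | Path) -> dict[tuple[str, str], bool]:
    labels: dict[tuple[str, str], bool] = {}
    with Path(source).open(encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            comp, canc, v = line.rstrip("\n").split("\t")
            labels[(comp, canc)] = bool(int(v))
    return labels
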