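"""End-to-end orchestration: generate -> index -> associate -> cooccur -> embed -> validate.

Every run writes its artifacts as plain-text tables, each accompanied by a
JSON sidecar echoing the configuration, the seed and the package version,
so reruns with identical configuration are reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from ._version import __version__ as _version
from .cooccurrence import build_graph, compound_cooccurrence, export_graph
from .corpus import read_corpus_xml, write_corpus_xml
from .embeddings import EmbeddingConfig, normalize_text, similarity_matrix, train_embeddings
from .enrichment import association_matrix
from .lexicon import EntityLexicon
from .synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_ic50,
    generate_survival,
    write_approval_tsv,
    write_ic50_tsv,
    write_survival_tsv,
)
from .tagging import EntityMatcher, build_index
from .validation import (
    aggregate_ic50,
    approval_roc,
    bin_associations,
    compare_ic50_by_bin,
    stratify_patients,
    survival_compare,
)

logger = logging.getLogger("oncolit")

ALL_STAGES = ("generate", "index", "associate", "cooccur", "embed", "validate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Paths, thresholds and method choices of one pipeline run."""

    output_dir: str
    seed: int
    generator: GeneratorConfig | None = None
    corpus_path: str | None = None
    lexicon_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    cap: float = 100.0
    cooccurrence_threshold: float = 50.0
    support_cutoff: float = 20.0
    ic50_quantile: float = 0.10
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def echo(self) -> dict:
        data = dataclasses.asdict(self)
        if self.generator is not None:
            gen = data["generator"]
            gen["association_effect"] = [[a, b, e] for (a, b), e in self.generator.association_effect.items()]
            gen["comention_effect"] = [[a, b, e] for (a, b), e in self.generator.comention_effect.items()]
            gen["gene_specificity"] = [
                [g, sorted(ents), boost] for g, (ents, boost) in self.generator.gene_specificity.items()
            ]
        data["version"] = _version
        return data


def _sidecar(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"config": config.echo(), "seed": config.seed, "version": _version}
    if extra:
        payload.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run report.

    The report lists every written artifact with its row count, per-stage
    timings and the configuration echo.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"artifacts": {}, "timings": {}, "config": config.echo()}

    state: dict = {}

    def _record(name: str, path: Path, rows: int, extra: dict | None = None) -> None:
        report["artifacts"][name] = {"path": str(path), "rows": rows}
        _sidecar(path, config, extra)

    for stage in config.stages:
        t0 = time.monotonic()
        try:
            if stage == "generate":
                if config.generator is None:
                    raise PipelineError("stage generate: no generator configuration supplied")
                gen = config.generator
                docs, lexicon, truth = generate_corpus(gen)
                ic50 = generate_ic50(truth, gen)
                survival = generate_survival(truth, gen)
                corpus_path = out / "corpus.xml"
                write_corpus_xml(docs, corpus_path)
                lexicon.write_tsv(out / "lexicon.tsv")
                truth.to_json(out / "truth.json")
                write_ic50_tsv(ic50, out / "ic50.tsv")
                write_survival_tsv(survival, out / "survival.tsv")
                write_approval_tsv(truth.approval_labels, out / "approval.tsv")
                state.update(docs=docs, lexicon=lexicon, truth=truth, ic50=ic50, survival=survival)
                _record("corpus", corpus_path, len(docs))
                _record("lexicon", out / "lexicon.tsv", len(lexicon))
                _record("ic50", out / "ic50.tsv", len(ic50))
                _record("survival", out / "survival.tsv", len(survival))
                _record("approval", out / "approval.tsv", len(truth.approval_labels))
            elif stage == "index":
                if "docs" not in state:
                    if config.corpus_path is None or config.lexicon_path is None:
                        raise PipelineError(
                            "stage index: corpus_path and lexicon_path required without generate"
                        )
                    state["docs"] = read_corpus_xml(config.corpus_path)
                    state["lexicon"] = EntityLexicon.read_tsv(config.lexicon_path)
                state["matcher"] = EntityMatcher(state["lexicon"])
                state["index"] = build_index(state["docs"], state["lexicon"], state["matcher"])
            elif stage == "associate":
                index, lexicon = state["index"], state["lexicon"]
                matrix = association_matrix(
                    index, lexicon.ids("compound"), lexicon.ids("cancer"),
                    method="publications", cap=config.cap,
                )
                matrix.write_tsv(out / "associations_publications.tsv")
                state["matrix"] = matrix
                _record("associations_publications", out / "associations_publications.tsv", len(matrix.compounds))
            elif stage == "cooccur":
                index, lexicon = state["index"], state["lexicon"]
                compounds = lexicon.ids("compound")
                n_edges = 0
                for cancer in lexicon.ids("cancer"):
                    if not index.docs(cancer):
                        logger.warning("cooccur: cancer %s has no documents, skipped", cancer)
                        continue
                    edges = compound_cooccurrence(index, cancer, compounds)
                    graph = build_graph(edges, threshold=config.cooccurrence_threshold)
                    path = out / f"cooccurrence_{cancer}.tsv"
                    export_graph(graph, path, format="edge_tsv")
                    _record(
                        f"cooccurrence_{cancer}", path, len(graph.edges),
                        {"threshold": config.cooccurrence_threshold},
                    )
                    n_edges += len(graph.edges)
                state["cooccurrence_edges"] = n_edges
            elif stage == "embed":
                docs, lexicon = state["docs"], state["lexicon"]
                matcher = state.get("matcher") or EntityMatcher(lexicon)
                sequences = [normalize_text(d.text, matcher) for d in docs]
                model = train_embeddings(sequences, config.embedding)
                model.save_text(out / "embeddings.w2v.txt")
                sim = similarity_matrix(
                    model, lexicon.ids("compound"), lexicon.ids("cancer"), lexicon=lexicon
                )
                sim.write_tsv(out / "associations_cosine.tsv")
                state["model"], state["cosine_matrix"] = model, sim
                _record("embeddings", out / "embeddings.w2v.txt", len(model.vocabulary))
                _record("associations_cosine", out / "associations_cosine.tsv", len(sim.compounds))
            elif stage == "validate":
                matrix = state["matrix"]
                truth = state.get("truth")
                results: dict = {}
                if truth is not None and truth.approval_labels:
                    auc, roc_table = approval_roc(matrix, truth.approval_labels)
                    roc_table.to_csv(out / "roc_pairs.tsv", sep="\t", index=False)
                    _record("roc_pairs", out / "roc_pairs.tsv", len(roc_table))
                    results["approval_auc"] = auc
                if "ic50" in state:
                    agg = aggregate_ic50(state["ic50"], q=config.ic50_quantile)
                    bins = bin_associations(matrix)
                    summary, folds = compare_ic50_by_bin(bins, agg)
                    summary.to_csv(out / "ic50_by_bin.tsv", sep="\t", index=False)
                    _record("ic50_by_bin", out / "ic50_by_bin.tsv", len(summary))
                    results["ic50_fold_changes"] = folds
                if "survival" in state:
                    groups = stratify_patients(state["survival"], matrix, config.support_cutoff)
                    comparison = survival_compare(groups)
                    results["survival"] = {
                        "hazard_ratio_low_vs_high": comparison["hazard_ratio_low_vs_high"],
                        "p_value": comparison["p_value"],
                        "n_per_group": comparison["n_per_group"],
                    }
                (out / "validation.json").write_text(
                    json.dumps(results, indent=2, sort_keys=True, default=str)
                )
                _record("validation", out / "validation.json", len(results))
                report["validation"] = results
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:  # surface the failing stage
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        report["timings"][stage] = time.monotonic() - t0
        logger.info("stage %s finished in %.2fs", stage, report["timings"][stage])

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
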