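"""Entity-normalized word embeddings and cosine-similarity scoring.

Abstracts are first normalized: every synonym span is replaced by its
entity's canonical embedding token (e.g. all synonyms of liver cancer
become ``cancerlivercancer``), remaining text is lowercased and split on
non-alphanumeric boundaries with internal hyphens preserved.  A compact
skip-gram word2vec model with negative sampling is then trained on the
token sequences.  Defaults follow the mining setup this package implements:
minimal word frequency 1 (keep every token), vector length 200 and a
window of 500 tokens, wide enough to span a whole abstract, so every token
pair inside one abstract is a training context.

Compound-cancer similarity is the cosine of the two entity-token vectors.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import AssociationMatrix
from .lexicon import EntityLexicon
from .tagging import EntityMatcher

_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


class EmbeddingError(ValueError):
    """Raised for invalid configurations, vocabularies or tokens."""


def normalize_text(text: str, lexicon: EntityLexicon | EntityMatcher) -> list[str]:
    """Tokenize with entity normalization.

    Synonym spans (longest-match, resolved as in entity tagging) are
    replaced by the entity's embedding token; everything else is lowercased
    and split into alphanumeric tokens, keeping internal hyphens.  The
    function is idempotent on its own output because embedding tokens match
    themselves.
    """
    matcher = lexicon if isinstance(lexicon, EntityMatcher) else EntityMatcher(lexicon)
    tokens: list[str] = []
    cursor = 0
    for mention in matcher.match(text):
        tokens.extend(_TOKEN_RE.findall(text[cursor : mention.char_start].lower()))
        tokens.append(matcher.lexicon[mention.entity_id].embedding_token)
        cursor = mention.char_end
    tokens.extend(_TOKEN_RE.findall(text[cursor:].lower()))
    return tokens


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters for skip-gram training with negative sampling."""

    min_word_frequency: int = 1
    vector_dim: int = 200
    window_size: int = 500
    epochs: int = 5
    architecture: str = "skipgram"
    negative_samples: int = 5
    learning_rate: float = 0.1
    min_learning_rate: float = 1e-4
    pairs_per_sequence: int = 600
    subsample_threshold: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vector_dim <= 0:
            raise EmbeddingError("vector_dim must be > 0")
        if self.window_size <= 0:
            raise EmbeddingError("window_size must be > 0")
        if self.architecture != "skipgram":
            raise EmbeddingError(f"unsupported architecture {self.architecture!r}")
        if self.min_word_frequency < 1 or self.epochs < 1 or self.negative_samples < 0:
            raise EmbeddingError("invalid training parameters")
        if self.pairs_per_sequence < 1:
            raise EmbeddingError("pairs_per_sequence must be >= 1")
        if self.subsample_threshold < 0:
            raise EmbeddingError("subsample_threshold must be >= 0 (0 disables)")


@dataclass
class EmbeddingModel:
    """Trained vectors with their vocabulary and a config echo."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (n_tokens, vector_dim)
    config: EmbeddingConfig

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocabulary[token]]
        except KeyError:
            raise EmbeddingError(f"token {token!r} not in vocabulary") from None

    # -- persistence: word2vec text format + JSON config echo --------------

    def save_text(self, destination: str | Path) -> None:
        path = Path(destination)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.config.vector_dim}\n")
            for token, idx in self.vocabulary.items():
                vec = " ".join(repr(float(x)) for x in self.vectors[idx])
                fh.write(f"{token} {vec}\n")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(asdict(self.config), indent=2, sort_keys=True)
        )

    @classmethod
    def load_text(cls, source: str | Path) -> "EmbeddingModel":
        path = Path(source)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = (
            EmbeddingConfig(**json.loads(sidecar.read_text()))
            if sidecar.exists()
            else EmbeddingConfig()
        )
        vocabulary: dict[str, int] = {}
        rows: list[np.ndarray] = []
        with path.open(encoding="utf-8") as fh:
            n_tokens, dim = map(int, fh.readline().split())
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                token, values = parts[0], parts[1:]
                if len(values) != dim:
                    raise EmbeddingError(f"{path}: bad vector length for {token!r}")
                vocabulary[token] = len(rows)
                rows.append(np.array([float(v) for v in values]))
        if len(rows) != n_tokens:
            raise EmbeddingError(f"{path}: header declares {n_tokens} tokens, found {len(rows)}")
        if config.vector_dim != dim:
            config = replace(config, vector_dim=dim)
        return cls(vocabulary=vocabulary, vectors=np.vstack(rows) if rows else np.zeros((0, dim)), config=config)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _scatter_step(weights: np.ndarray, idx: np.ndarray, grad: np.ndarray) -> None:
    """Apply the mean gradient per row index (in place).

    Rows hit by many pairs of the same sequence receive the average of
    their pair gradients rather than the sum; this keeps the step size of
    frequent tokens bounded by the learning rate and is what makes whole
    abstracts processable as one batch without divergence.
    """
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    uniq, starts, counts = np.unique(idx_sorted, return_index=True, return_counts=True)
    sums = np.add.reduceat(grad[order], starts, axis=0)
    weights[uniq] -= sums / counts[:, None]


def train_embeddings(
    sequences: Iterable[Sequence[str]], config: EmbeddingConfig | None = None
) -> EmbeddingModel:
    """Train skip-gram vectors with negative sampling.

    Plain SGD on the standard objective: for each (center, context) pair
    within the window, push the pair's score up and the scores of
    ``negative_samples`` noise tokens (drawn from the unigram distribution
    raised to 3/4) down.  The learning rate decays linearly over all
    processed sequences.  With a fixed seed the run is single-threaded and
    bit-reproducible.
    """
    if config is None:
        config = EmbeddingConfig()
    seqs = [list(s) for s in sequences if s]
    counts: dict[str, int] = {}
    for s in seqs:
        for tok in s:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(
        (t for t, c in counts.items() if c >= config.min_word_frequency),
        key=lambda t: (-counts[t], t),
    )
    if not vocab_tokens:
        raise EmbeddingError("empty vocabulary after frequency filtering")
    vocabulary = {t: i for i, t in enumerate(vocab_tokens)}
    n_vocab, dim = len(vocabulary), config.vector_dim

    rng = np.random.default_rng(config.seed)
    w_in = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((n_vocab, dim), dtype=np.float32)

    freq = np.array([counts[t] for t in vocab_tokens], dtype=float) ** 0.75
    noise_p = freq / freq.sum()

    encoded = [
        np.array([vocabulary[t] for t in s if t in vocabulary], dtype=np.int64)
        for s in seqs
    ]
    encoded = [s for s in encoded if s.size >= 2]
    # frequent-word subsampling: occurrences of a token with corpus
    # frequency f are kept with probability sqrt(t/f) + t/f, which thins
    # ubiquitous words and keeps rare entity tokens intact
    total_tokens = float(sum(counts[t] for t in vocab_tokens))
    if config.subsample_threshold > 0:
        f = np.array([counts[t] for t in vocab_tokens]) / total_tokens
        ratio = config.subsample_threshold / f
        keep_prob = np.minimum(1.0, np.sqrt(ratio) + ratio)
    else:
        keep_prob = np.ones(n_vocab)
    total_steps = max(1, config.epochs * len(encoded))
    step = 0
    k = config.negative_samples
    for _epoch in range(config.epochs):
        for full_seq in encoded:
            seq = full_seq[rng.random(full_seq.size) < keep_prob[full_seq]]
            if seq.size < 2:
                step += 1
                continue
            lr = max(
                config.min_learning_rate,
                config.learning_rate * (1.0 - step / total_steps),
            )
            step += 1
            n = seq.size
            # all in-window ordered (center, context) pairs of the sequence
            if n - 1 <= config.window_size:
                ctr = np.repeat(seq, n - 1)
                ctx = np.concatenate([np.delete(seq, i) for i in range(n)])
            else:
                pairs_c, pairs_o = [], []
                for i in range(n):
                    lo, hi = max(0, i - config.window_size), min(n, i + config.window_size + 1)
                    idx = np.r_[lo:i, i + 1 : hi]
                    pairs_c.append(np.full(idx.size, seq[i]))
                    pairs_o.append(seq[idx])
                ctr = np.concatenate(pairs_c)
                ctx = np.concatenate(pairs_o)
            if ctr.size > config.pairs_per_sequence:
                # a wide window over a long abstract yields O(n^2) pairs;
                # train on a uniform per-epoch subsample to bound the cost
                sel = rng.choice(ctr.size, size=config.pairs_per_sequence, replace=False)
                ctr, ctx = ctr[sel], ctx[sel]
            n_pairs = ctr.size
            v = w_in[ctr]  # (P, d)
            # positive update
            u = w_out[ctx]
            g_pos = ((_sigmoid(np.einsum("ij,ij->i", v, u)) - 1.0) * lr).astype(np.float32)  # (P,)
            grad_in = g_pos[:, None] * u
            out_idx = ctx
            out_grad = g_pos[:, None] * v
            # negative updates
            if k > 0:
                neg = rng.choice(n_vocab, size=(n_pairs, k), p=noise_p)
                u_neg = w_out[neg]  # (P, k, d)
                g_neg = (_sigmoid(np.einsum("ij,ikj->ik", v, u_neg)) * lr).astype(np.float32)  # (P, k)
                grad_in += np.einsum("ik,ikj->ij", g_neg, u_neg)
                out_idx = np.concatenate([ctx, neg.ravel()])
                out_grad = np.concatenate(
                    [out_grad, (g_neg[..., None] * v[:, None, :]).reshape(-1, dim)]
                )
            _scatter_step(w_out, out_idx, out_grad)
            _scatter_step(w_in, ctr, grad_in)
    return EmbeddingModel(vocabulary=vocabulary, vectors=w_in, config=config)


def cosine_similarity(model: EmbeddingModel, token_a: str, token_b: str) -> float:
    """Cosine of the two token vectors, in [-1, 1]."""
    va, vb = model.vector(token_a), model.vector(token_b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise EmbeddingError("zero-norm vector; cosine undefined")
    return float(np.dot(va, vb) / (na * nb))


def similarity_matrix(
    model: EmbeddingModel,
    compounds: Sequence[str],
    cancers: Sequence[str],
    lexicon: EntityLexicon | None = None,
) -> AssociationMatrix:
    """Full compound x cancer cosine grid (method tag ``cosine``).

    ``compounds``/``cancers`` are embedding tokens, or entity ids when a
    lexicon is supplied.  Cells whose token is missing from the vocabulary
    are NaN and listed under ``metadata['missing_cells']``.
    """
    if lexicon is not None:
        row_tokens = {c: lexicon.token_for(c) for c in compounds}
        col_tokens = {c: lexicon.token_for(c) for c in cancers}
    else:
        row_tokens = {c: c for c in compounds}
        col_tokens = {c: c for c in cancers}
    grid = pd.DataFrame(np.nan, index=list(compounds), columns=list(cancers), dtype=float)
    missing: list[tuple[str, str, str]] = []
    for comp in compounds:
        for canc in cancers:
            try:
                grid.loc[comp, canc] = cosine_similarity(model, row_tokens[comp], col_tokens[canc])
            except EmbeddingError as exc:
                missing.append((comp, canc, str(exc)))
    return AssociationMatrix(
        scores=grid, method="cosine", metadata={"missing_cells": missing}
    )


def nearest_words(model: EmbeddingModel, token: str, k: int) -> list[tuple[str, float]]:
    """Top-k vocabulary tokens by cosine to the query, excluding the query.

    Ties are broken lexicographically; k beyond the vocabulary returns all
    other tokens without padding.
    """
    query = model.vector(token)
    nq = np.linalg.norm(query)
    if nq == 0:
        raise EmbeddingError("zero-norm query vector")
    if k <= 0:
        return []
    norms = np.linalg.norm(model.vectors, axis=1)
    norms[norms == 0] = np.nan
    sims = model.vectors @ query / (norms * nq)
    scored = [
        (tok, float(sims[idx]))
        for tok, idx in model.vocabulary.items()
        if tok != token and np.isfinite(sims[idx])
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]
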