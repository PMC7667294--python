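"""Token embedding tables and sentence vectors.

Sentence vectors are the element-wise mean of token vectors, the
representation consumed by the corpus classifiers.  The table is a
pluggable input (text format, ``token<TAB>floats``); two in-package sources
exist for working without pretrained vectors:

* deterministic hashed embeddings — every token maps to a fixed random
  unit-scaled vector derived from a stable hash of its spelling, i.e. a
  random projection of the bag of words;
* a small PPMI + truncated-SVD trainer for tiny corpora.

Out-of-vocabulary tokens map to the zero vector (deterministic policy).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from sklearn.decomposition import TruncatedSVD

from .models import Sentence
from .text import Tokenizer, default_tokenizer

logger = logging.getLogger(__name__)

DEFAULT_DIM = 200


class EmbeddingTable:
    """token → fixed-dimension vector, with a zero-vector OOV policy."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int | None = None):
        if not vectors and dim is None:
            raise ValueError("need at least one vector or an explicit dim")
        self.dim = dim if dim is not None else len(next(iter(vectors.values())))
        self.vectors: dict[str, np.ndarray] = {}
        for token, vec in vectors.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector for {token!r} has dim {vec.shape}, expected ({self.dim},)"
                )
            self.vectors[token] = vec
        self._zero = np.zeros(self.dim)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self._zero)


def embed_sentence(
    sentence: Sentence | str,
    table: EmbeddingTable,
    tokenizer: Tokenizer = default_tokenizer,
) -> np.ndarray:
    """Mean of token vectors; empty or all-OOV sentences give the zero vector."""
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    tokens = tokenizer(text)
    if not tokens:
        logger.warning("embedding empty sentence %r -> zero vector", text)
        return np.zeros(table.dim)
    return np.mean([table.vector(t) for t in tokens], axis=0)


def embed_sentences(
    sentences: Iterable[Sentence | str],
    table: EmbeddingTable,
    tokenizer: Tokenizer = default_tokenizer,
) -> np.ndarray:
    return np.array([embed_sentence(s, table, tokenizer) for s in sentences])


def read_embedding_table(source: str | Path | TextIO) -> EmbeddingTable:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_embedding_table(fh)
    vectors = {}
    for line in source:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            continue
        vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EmbeddingTable(vectors)


def write_embedding_table(table: EmbeddingTable, dest: str | Path | TextIO) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            write_embedding_table(table, fh)
        return
    for token in sorted(table.vectors):
        vals = "\t".join(f"{x:.6g}" for x in table.vectors[token])
        dest.write(f"{token}\t{vals}\n")


def _token_seed(token: str, seed: int) -> int:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def hashed_embeddings(
    tokens: Iterable[str], dim: int = DEFAULT_DIM, seed: int = 0
) -> EmbeddingTable:
    """Deterministic random vectors keyed on token spelling.

    Stable across runs and processes (hash-derived, not order-derived), so a
    model trained against the table can be reused without persisting it.
    """
    vectors = {}
    scale = 1.0 / np.sqrt(dim)
    for token in set(tokens):
        rng = np.random.default_rng(_token_seed(token, seed))
        vectors[token] = rng.normal(0.0, scale, size=dim)
    return EmbeddingTable(vectors, dim=dim)


def vocabulary(
    sentences: Iterable[Sentence | str], tokenizer: Tokenizer = default_tokenizer
) -> set[str]:
    vocab: set[str] = set()
    for s in sentences:
        text = s.text if isinstance(s, Sentence) else s
        vocab.update(tokenizer(text))
    return vocab


def train_embeddings(
    sentences: Iterable[Sentence | str],
    dim: int = DEFAULT_DIM,
    window: int = 4,
    min_count: int = 1,
    seed: int = 0,
    tokenizer: Tokenizer = default_tokenizer,
) -> EmbeddingTable:
    """Count-based embeddings for tiny corpora: PPMI co-occurrence + SVD."""
    token_lists = []
    counts: dict[str, int] = {}
    for s in sentences:
        text = s.text if isinstance(s, Sentence) else s
        toks = tokenizer(text)
        token_lists.append(toks)
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary")
    index = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    cooc = np.zeros((n, n))
    for toks in token_lists:
        ids = [index[t] for t in toks if t in index]
        for i, a in enumerate(ids):
            for b in ids[max(0, i - window) : i]:
                cooc[a, b] += 1
                cooc[b, a] += 1
    total = cooc.sum() or 1.0
    row = cooc.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(dim, n - 1) if n > 1 else 1
    svd = TruncatedSVD(n_components=k, random_state=seed)
    reduced = svd.fit_transform(ppmi)
    if k < dim:  # pad so the table honors the requested dimension
        reduced = np.hstack([reduced, np.zeros((n, dim - k))])
    return EmbeddingTable({t: reduced[index[t]] for t in vocab}, dim=dim)
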