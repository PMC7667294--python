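"""Sentence-sequence classifiers for the six corpus categories.

Two contract-identical models consume a sub-paragraph as a sequence of
sentence vectors and emit one category per sentence via CRF decoding:

* :class:`BiLSTMCRF` — a bidirectional LSTM over the sentence-vector
  sequence with a linear-chain CRF output layer, trained end-to-end by
  exact CRF negative log-likelihood with Adam (implemented in numpy; the
  sequences here are short, so this is fast on a CPU);
* :class:`NaiveBayesCRF` — Gaussian naive-Bayes per-sentence emissions
  smoothed by a bigram transition matrix estimated from the training
  labels, decoded with Viterbi.  With ``use_transitions=False`` it reduces
  to the plain per-sentence classifier.

Both are deterministic given the seed in :class:`TrainingConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.naive_bayes import GaussianNB

from . import crf
from .embeddings import EmbeddingTable, embed_sentence
from .models import CATEGORIES, Category, SubParagraph
from .text import Tokenizer, default_tokenizer

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
N_CLASSES = len(CATEGORIES)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    num_epochs: int = 50
    dropout_rate: float = 0.1
    learning_rate: float = 0.001
    max_sequence_length: int = 100
    num_units: int = 200
    optimizer: str = "adam"
    embedding_dim: int = 200
    seed: int = 0


# ---------------------------------------------------------------------------
# numpy LSTM layer


class _LSTM:
    """Single-direction LSTM with exact backpropagation through time."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        D, H = input_dim, hidden
        limit = np.sqrt(6.0 / (D + 4 * H))
        self.W = rng.uniform(-limit, limit, size=(4 * H, D))
        limit = np.sqrt(6.0 / (H + 4 * H))
        self.U = rng.uniform(-limit, limit, size=(4 * H, H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.H = H

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b}

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        T = X.shape[0]
        H = self.H
        h = np.zeros(H)
        c = np.zeros(H)
        out = np.empty((T, H))
        cache = []
        for t in range(T):
            z = self.W @ X[t] + self.U @ h + self.b
            i = self._sigmoid(z[:H])
            f = self._sigmoid(z[H : 2 * H])
            o = self._sigmoid(z[2 * H : 3 * H])
            g = np.tanh(z[3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((X[t], h, c, i, f, o, g, tc))
            h, c = h_new, c_new
            out[t] = h
        return out, cache

    def backward(
        self, dH_out: np.ndarray, cache: list
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        T = dH_out.shape[0]
        H = self.H
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((T, self.W.shape[1]))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, o, g, tc = cache[t]
            dh = dH_out[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g * g),
                ]
            )
            dW += np.outer(dz, x)
            dU += np.outer(dz, h_prev)
            db += dz
            dX[t] = self.W.T @ dz
            dh_next = self.U.T @ dz
            dc_next = dc * f
        return dX, {"W": dW, "U": dU, "b": db}


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# models


class BiLSTMCRF:
    """Bidirectional LSTM + linear-chain CRF sentence-sequence classifier."""

    def __init__(self, config: TrainingConfig):
        self.config = config
        self._rng = np.random.default_rng(config.seed)
        D, H = config.embedding_dim, config.num_units
        self.fwd = _LSTM(D, H, self._rng)
        self.bwd = _LSTM(D, H, self._rng)
        limit = np.sqrt(6.0 / (2 * H + N_CLASSES))
        self.Wp = self._rng.uniform(-limit, limit, size=(2 * H, N_CLASSES))
        self.bp = np.zeros(N_CLASSES)
        self.start = np.zeros(N_CLASSES)
        self.trans = np.zeros((N_CLASSES, N_CLASSES))

    # parameter plumbing -------------------------------------------------
    def _params(self) -> dict[str, np.ndarray]:
        out = {"Wp": self.Wp, "bp": self.bp, "start": self.start, "trans": self.trans}
        for name, layer in (("f", self.fwd), ("b", self.bwd)):
            for k, v in layer.params().items():
                out[f"{name}.{k}"] = v
        return out

    def _emissions(self, X: np.ndarray) -> tuple[np.ndarray, tuple]:
        hf, cf = self.fwd.forward(X)
        hb_rev, cb = self.bwd.forward(X[::-1])
        hb = hb_rev[::-1]
        h2 = np.hstack([hf, hb])
        e = h2 @ self.Wp + self.bp
        return e, (X, h2, cf, cb)

    def _loss_and_grads(
        self, X: np.ndarray, tags: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        e, (X_, h2, cf, cb) = self._emissions(X)
        nll, dE, dstart, dtrans = crf.nll_and_gradients(e, tags, self.start, self.trans)
        dWp = h2.T @ dE
        dbp = dE.sum(axis=0)
        dh2 = dE @ self.Wp.T
        H = self.config.num_units
        _, gf = self.fwd.backward(dh2[:, :H], cf)
        _, gb = self.bwd.backward(dh2[::-1, H:], cb)
        grads = {"Wp": dWp, "bp": dbp, "start": dstart, "trans": dtrans}
        for k, v in gf.items():
            grads[f"f.{k}"] = v
        for k, v in gb.items():
            grads[f"b.{k}"] = v
        return nll, grads

    def fit(self, sequences: list[np.ndarray], labels: list[np.ndarray]) -> "BiLSTMCRF":
        cfg = self.config
        opt = _Adam(cfg.learning_rate)
        n = len(sequences)
        if n == 0:
            raise ValueError("no training sequences")
        order = np.arange(n)
        keep = 1.0 - cfg.dropout_rate
        for _ in range(cfg.num_epochs):
            self._rng.shuffle(order)
            for lo in range(0, n, cfg.batch_size):
                batch = order[lo : lo + cfg.batch_size]
                acc: dict[str, np.ndarray] = {}
                for idx in batch:
                    X = sequences[idx]
                    if cfg.dropout_rate > 0:
                        mask = self._rng.random(X.shape) < keep
                        X = X * mask / keep
                    _, grads = self._loss_and_grads(X, labels[idx])
                    for k, g in grads.items():
                        acc[k] = acc.get(k, 0.0) + g
                for k in acc:
                    acc[k] /= len(batch)
                opt.step(self._params(), acc)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        e, _ = self._emissions(X)
        return crf.viterbi_decode(e, self.start, self.trans)


class NaiveBayesCRF:
    """Per-sentence Gaussian naive Bayes + CRF-style transition smoothing."""

    def __init__(self, config: TrainingConfig | None = None, use_transitions: bool = True):
        self.config = config or TrainingConfig()
        self.use_transitions = use_transitions
        self.nb = GaussianNB()
        self.start = np.zeros(N_CLASSES)
        self.trans = np.zeros((N_CLASSES, N_CLASSES))
        self._classes: np.ndarray | None = None

    def fit(self, sequences: list[np.ndarray], labels: list[np.ndarray]) -> "NaiveBayesCRF":
        if not sequences:
            raise ValueError("no training sequences")
        X = np.vstack(sequences)
        y = np.concatenate(labels)
        self.nb.fit(X, y)
        self._classes = self.nb.classes_
        # Laplace-smoothed bigram/start log-probabilities
        start_counts = np.ones(N_CLASSES)
        trans_counts = np.ones((N_CLASSES, N_CLASSES))
        for seq in labels:
            start_counts[seq[0]] += 1
            for a, b in zip(seq[:-1], seq[1:]):
                trans_counts[a, b] += 1
        self.start = np.log(start_counts / start_counts.sum())
        self.trans = np.log(trans_counts / trans_counts.sum(axis=1, keepdims=True))
        return self

    def _emissions(self, X: np.ndarray) -> np.ndarray:
        logp = self.nb.predict_log_proba(X)
        e = np.full((X.shape[0], N_CLASSES), -1e9)
        for col, cls in enumerate(self._classes):
            e[:, int(cls)] = logp[:, col]
        return e

    def predict(self, X: np.ndarray) -> np.ndarray:
        e = self._emissions(X)
        if not self.use_transitions:
            return np.argmax(e, axis=1)
        return crf.viterbi_decode(e, self.start, self.trans)


# ---------------------------------------------------------------------------
# contract layer over sub-paragraphs


@dataclass
class CorpusModel:
    """Trained sentence-category model bound to its embedding table."""

    model: BiLSTMCRF | NaiveBayesCRF
    table: EmbeddingTable
    tokenizer: Tokenizer = default_tokenizer
    max_sequence_length: int = 100

    def predict_categories(self, sub: SubParagraph) -> list[Category]:
        if not sub.sentences:
            return []
        X = np.array([embed_sentence(s, self.table, self.tokenizer) for s in sub.sentences])
        tags: list[int] = []
        # sequences beyond the length cap are classified in consecutive chunks
        for lo in range(0, X.shape[0], self.max_sequence_length):
            tags.extend(self.model.predict(X[lo : lo + self.max_sequence_length]).tolist())
        return [CATEGORIES[t] for t in tags]


def _encode_training_data(
    labeled_subs: list[SubParagraph],
    table: EmbeddingTable,
    tokenizer: Tokenizer,
    max_len: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    sequences, labels = [], []
    for sub in labeled_subs:
        if not sub.sentences:
            continue
        tags = []
        for s in sub.sentences:
            if s.category is None:
                raise ValueError(
                    f"unlabeled sentence in training data (report {sub.source_report_id!r})"
                )
            tags.append(_CAT_INDEX[Category(s.category)])
        X = np.array([embed_sentence(s, table, tokenizer) for s in sub.sentences])
        sequences.append(X[:max_len])
        labels.append(np.array(tags[:max_len], dtype=np.intp))
    return sequences, labels


def train_corpus_classifier(
    labeled_subs: list[SubParagraph],
    config: TrainingConfig,
    table: EmbeddingTable,
    model_type: str = "bilstm_crf",
    tokenizer: Tokenizer = default_tokenizer,
) -> CorpusModel:
    """Train a sentence-category model on labeled sub-paragraphs.

    ``model_type``: ``"bilstm_crf"`` (neural sequence model), ``"nb_crf"``
    (naive-Bayes emissions + transition smoothing) or ``"nb"`` (plain
    per-sentence baseline).
    """
    if table.dim != config.embedding_dim:
        config = replace(config, embedding_dim=table.dim)
    sequences, labels = _encode_training_data(
        labeled_subs, table, tokenizer, config.max_sequence_length
    )
    if model_type == "bilstm_crf":
        model: BiLSTMCRF | NaiveBayesCRF = BiLSTMCRF(config).fit(sequences, labels)
    elif model_type == "nb_crf":
        model = NaiveBayesCRF(config).fit(sequences, labels)
    elif model_type == "nb":
        model = NaiveBayesCRF(config, use_transitions=False).fit(sequences, labels)
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    return CorpusModel(
        model=model,
        table=table,
        tokenizer=tokenizer,
        max_sequence_length=config.max_sequence_length,
    )


def classify_corpus(subs: list[SubParagraph], model: CorpusModel) -> list[SubParagraph]:
    """Assign every sentence one of the six categories, in place."""
    for sub in subs:
        for sentence, cat in zip(sub.sentences, model.predict_categories(sub)):
            sentence.category = cat
    return subs
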